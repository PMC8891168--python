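"""Domain types and unit conventions for the energy-determined plasticity model.

Units are fixed across the package and never converted implicitly:

* membrane potential ``V_m`` — mV (absolute scale; resting potential ≈ −69 mV)
* membrane current density ``I_m`` — pA/μm², positive = depolarizing
* time — seconds
* potential energy ``P`` and energy supply ``S`` — fJ/μm²

The numeric product ``V_m · I_m`` is then a power density in fW/μm² with no
conversion factor (mV · pA/μm² = fW/μm²), and its time integral over seconds
is an energy density in fJ/μm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "PlasticityParams",
    "Sample",
    "TraceSet",
    "EnergyState",
    "validate_params",
    "classify_sample",
    "SUBTHRESHOLD",
    "SUPRATHRESHOLD",
]

SUBTHRESHOLD = "subthreshold"
SUPRATHRESHOLD = "suprathreshold"

#: config-file key for each parameter field (flat YAML/JSON mapping)
_CONFIG_KEYS = {
    "A": "A",
    "A_r": "A_r",
    "V_th": "V_th_mV",
    "R": "R",
    "tau": "tau_s",
    "S0": "S0",
    "A_scale": "A_scale",
    "dt": "dt_s",
}


@dataclass(frozen=True)
class PlasticityParams:
    """The six model constants plus the time-compression factor and step.

    Attributes
    ----------
    A:
        Amplitude coefficient, μm²/fJ.  Linear map from potential energy to
        the dimensionless synaptic weight (the learning rate of the rule).
    A_r:
        Baseline coefficient in (0, 1).  The baseline potential energy is
        ``A_r`` times the subthreshold potential energy.
    V_th:
        Threshold potential, mV.  Splits accumulated energy into the
        subthreshold (V_m < V_th) and suprathreshold (V_m ≥ V_th) parts.
    R:
        Energy supply rate, fJ/(μm²·s).
    tau:
        Time constant of the energy supply, s.
    S0:
        Minimum energy supply (resting-state supply), fJ/μm².
    A_scale:
        Time-compression factor ≥ 1 applied to every plasticity-state
        derivative, supply dynamics included.  1 for most protocols; 12
        (= 60/5) for the pairing protocols, where 5 simulated pairings stand
        in for the 60 pairings of the experimental protocol.
    dt:
        Integration step of the plasticity engine, s.
    """

    A: float = 0.02
    A_r: float = 0.2
    V_th: float = -60.0
    R: float = 175.0
    tau: float = 2.0
    S0: float = 25.0
    A_scale: float = 1.0
    dt: float = 1e-4

    def with_scale(self, A_scale: float) -> "PlasticityParams":
        return replace(self, A_scale=float(A_scale))

    def to_config(self) -> dict:
        """Flat key-value mapping using the serialized key names."""
        return {key: getattr(self, attr) for attr, key in _CONFIG_KEYS.items()}

    @classmethod
    def from_config(cls, cfg: Mapping) -> "PlasticityParams":
        kwargs = {attr: float(cfg[key]) for attr, key in _CONFIG_KEYS.items() if key in cfg}
        return validate_params(cls(**kwargs))


def validate_params(params: PlasticityParams) -> PlasticityParams:
    """Check every parameter invariant; return ``params`` unchanged if valid.

    Raises
    ------
    ValueError
        Naming the first violated invariant.
    """
    checks = [
        (params.A > 0, f"A must be > 0, got {params.A}"),
        (0 < params.A_r < 1, f"A_r must lie in the open interval (0, 1), got {params.A_r}"),
        (np.isfinite(params.V_th), f"V_th must be finite, got {params.V_th}"),
        (params.R >= 0, f"R must be >= 0, got {params.R}"),
        (params.tau > 0, f"tau must be > 0, got {params.tau}"),
        (params.S0 > 0, f"S0 must be > 0, got {params.S0}"),
        (params.A_scale >= 1, f"A_scale must be >= 1, got {params.A_scale}"),
        (params.dt > 0, f"dt must be > 0, got {params.dt}"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ValueError(msg)
    return params


def classify_sample(V_m: float, V_th: float) -> str:
    """Label a membrane-potential sample relative to the threshold.

    Exactly one label applies: ``subthreshold`` iff ``V_m < V_th`` and
    ``suprathreshold`` iff ``V_m >= V_th`` (a tie counts as suprathreshold,
    so the partition never double-counts the boundary).
    """
    if not (np.isfinite(V_m) and np.isfinite(V_th)):
        raise ValueError("classify_sample requires finite V_m and V_th")
    return SUBTHRESHOLD if V_m < V_th else SUPRATHRESHOLD


@dataclass(frozen=True)
class Sample:
    """One time point of a compartment trace.

    ``t`` in s, ``V_m`` in mV (absolute), ``I_m`` in pA/μm² with positive
    values depolarizing.
    """

    t: float
    V_m: float
    I_m: float

    def __post_init__(self):
        if not (np.isfinite(self.V_m) and np.isfinite(self.I_m) and np.isfinite(self.t)):
            raise ValueError(f"non-finite sample: t={self.t}, V_m={self.V_m}, I_m={self.I_m}")


@dataclass
class TraceSet:
    """Uniformly sampled per-compartment membrane traces.

    Arrays ``V_m`` and ``I_m`` have shape ``(n_compartments, n_samples)`` and
    share the strictly increasing time grid ``t`` (shape ``(n_samples,)``).
    ``distance`` holds each compartment's path distance from the soma in μm
    and ``branch`` its branch identifier (-1 for the soma or for synthetic
    single-compartment traces).
    """

    t: np.ndarray
    compartments: list
    V_m: np.ndarray
    I_m: np.ndarray
    distance: np.ndarray | None = None
    branch: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V_m = np.atleast_2d(np.asarray(self.V_m, dtype=float))
        self.I_m = np.atleast_2d(np.asarray(self.I_m, dtype=float))
        n_comp, n_samp = self.V_m.shape
        if self.I_m.shape != (n_comp, n_samp):
            raise ValueError(f"V_m {self.V_m.shape} and I_m {self.I_m.shape} shapes differ")
        if len(self.compartments) != n_comp:
            raise ValueError("compartment list length does not match trace rows")
        if self.t.shape != (n_samp,):
            raise ValueError("time grid length does not match trace columns")
        if n_samp > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError(
                    f"time grid is not uniform: step range [{steps.min():g}, {steps.max():g}]"
                )
        if self.distance is None:
            self.distance = np.zeros(n_comp)
        if self.branch is None:
            self.branch = np.full(n_comp, -1, dtype=int)
        self.distance = np.asarray(self.distance, dtype=float)
        self.branch = np.asarray(self.branch, dtype=int)

    @property
    def dt(self) -> float:
        """Sampling step in s."""
        if len(self.t) < 2:
            raise ValueError("trace has fewer than two samples; dt undefined")
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return self.V_m.shape[1]

    def index_of(self, compartment) -> int:
        try:
            return self.compartments.index(compartment)
        except ValueError:
            raise KeyError(f"unknown compartment {compartment!r}") from None

    def select(self, compartments) -> "TraceSet":
        """Sub-trace restricted to the given compartments, order preserved."""
        idx = [self.index_of(c) for c in compartments]
        return TraceSet(
            t=self.t,
            compartments=[self.compartments[i] for i in idx],
            V_m=self.V_m[idx],
            I_m=self.I_m[idx],
            distance=self.distance[idx],
            branch=self.branch[idx],
        )


@dataclass
class EnergyState:
    """Running per-synapse quantities of the plasticity engine.

    Constrained quantities (``P``, ``P_bas``, ``P_sup``, ``W``) carry the
    supply-limited dynamics; the ``*_u`` fields are the unconstrained shadows
    integrated with the sign factor fixed at +1.  ``S_damp``/``S_lin`` are the
    damping factor and linear accumulator whose product plus ``S0`` is the
    instantaneous supply ``S``.  Energies in fJ/μm²; ``W`` dimensionless.
    """

    P: float = 0.0
    P_bas: float = 0.0
    P_sup: float = 0.0
    S_damp: float = 1.0
    S_lin: float = 0.0
    W: float = 0.5
    P_u: float = 0.0
    P_bas_u: float = 0.0
    P_sup_u: float = 0.0
    W_u: float = 0.5

    def supply(self, params: PlasticityParams) -> float:
        """Instantaneous energy supply S = S_damp · S_lin + S0, fJ/μm²."""
        return self.S_damp * self.S_lin + params.S0

    def p_max(self, params: PlasticityParams) -> float:
        """Supply-limited target P_max = S · sign(P)."""
        return self.supply(params) * np.sign(self.P)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.P, self.P_bas, self.P_sup, self.S_damp, self.S_lin,
             self.W, self.P_u, self.P_bas_u, self.P_sup_u, self.W_u]
        )
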