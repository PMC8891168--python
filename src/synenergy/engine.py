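"""Forward-Euler integration of the supply-constrained potential-energy rule.

The engine advances, per synapse, the potential energy ``P`` accumulated as
the time integral of ``V_m · I_m``, its subthreshold/suprathreshold split,
the synaptic weight ``W``, and the energy supply ``S``:

    dS_damp/dt = -S_damp / τ              (S_damp(0) = 1)
    dS_lin/dt  =  R                       (S_lin(0) = 0)
    S          =  S_damp · S_lin + S0     ( = R·t·exp(-t/τ) + S0 )

    dP/dt      = V_m · I_m · sign(S - |P|)
    dP_bas/dt  = A_r · V_m · I_m · Θ(V_th - V_m) · sign(S - |P|)
    dP_sup/dt  = V_m · I_m · Θ(V_m - V_th) · sign(S - |P|)
    dW/dt      = A · V_m · I_m · Φ(V_m - V_th) · sign(S - |P|)

with Φ = A_r below threshold and −1 at/above, sign(0) = 0 (which freezes the
energy state for that step), and every derivative multiplied by the
time-compression factor ``A_scale``.  Unconstrained shadow variables follow
the same equations with the sign factor fixed at +1.

When ``|P|`` exceeds the supply, the sign factor flips and the explicit Euler
trajectory chatters along the boundary ``|P| = S``: this chattering is the
mechanism that adjusts P to the supply-limited value P_max = S·sign(P), so no
smoothing or adaptive stepping is applied across the discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .core import EnergyState, PlasticityParams, Sample, TraceSet, validate_params

__all__ = ["EngineOutput", "supply_closed_form", "step", "run"]


def supply_closed_form(t, params: PlasticityParams):
    """Energy supply S(t) = R·t·e^(−t/τ) + S0 in fJ/μm².

    ``t`` is the time since stimulation onset in s (scalar or array).  The
    supply starts and ends at the resting value S0 and peaks at t = τ.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("supply_closed_form requires t >= 0")
    out = params.R * t * np.exp(-t / params.tau) + params.S0
    return float(out) if out.ndim == 0 else out


def step(state: EnergyState, sample: Sample, params: PlasticityParams) -> EnergyState:
    """One explicit Euler step of all eight state variables.

    Order of operations within the step: the supply variables advance first
    and the updated supply is combined with the *start-of-step* ``P`` in the
    sign factor; energies and weight then advance together.
    """
    dt, asc = params.dt, params.A_scale
    v, i = sample.V_m, sample.I_m

    s_damp = state.S_damp - asc * (state.S_damp / params.tau) * dt
    s_lin = state.S_lin + asc * params.R * dt
    supply = s_damp * s_lin + params.S0

    sgn = np.sign(supply - abs(state.P))
    power = asc * v * i * dt
    sub = v < params.V_th  # strict/inclusive partition; tie is suprathreshold
    phi = params.A_r if sub else -1.0

    dP = power * sgn
    return replace(
        state,
        S_damp=s_damp,
        S_lin=s_lin,
        P=state.P + dP,
        P_bas=state.P_bas + (params.A_r * dP if sub else 0.0),
        P_sup=state.P_sup + (0.0 if sub else dP),
        W=state.W + params.A * phi * power * sgn,
        P_u=state.P_u + power,
        P_bas_u=state.P_bas_u + (params.A_r * power if sub else 0.0),
        P_sup_u=state.P_sup_u + (0.0 if sub else power),
        W_u=state.W_u + params.A * phi * power,
    )


@njit(cache=True)
def _integrate_kernel(V, I, dt, A, A_r, V_th, R, tau, S0, asc, state0, stride, n_rec):
    """Euler loop over (n_syn, n_steps) traces; records every ``stride`` steps."""
    n_syn, n_steps = V.shape
    st = state0.copy()  # columns: P, P_bas, P_sup, W, P_u, P_bas_u, P_sup_u, W_u per synapse
    s_damp = 1.0
    s_lin = 0.0
    rec = np.empty((n_rec, n_syn, 8))
    rec_S = np.empty(n_rec)
    rec_t_idx = np.empty(n_rec, dtype=np.int64)
    r = 0
    for k in range(n_steps):
        s_damp -= asc * (s_damp / tau) * dt
        s_lin += asc * R * dt
        supply = s_damp * s_lin + S0
        for j in range(n_syn):
            v = V[j, k]
            cur = I[j, k]
            power = asc * v * cur * dt
            diff = supply - abs(st[j, 0])
            sgn = 0.0
            if diff > 0.0:
                sgn = 1.0
            elif diff < 0.0:
                sgn = -1.0
            sub = v < V_th
            phi = A_r if sub else -1.0
            dP = power * sgn
            st[j, 0] += dP
            if sub:
                st[j, 1] += A_r * dP
                st[j, 5] += A_r * power
            else:
                st[j, 2] += dP
                st[j, 6] += power
            st[j, 3] += A * phi * power * sgn
            st[j, 4] += power
            st[j, 7] += A * phi * power
        if stride > 0 and (k + 1) % stride == 0:
            for j in range(n_syn):
                for q in range(8):
                    rec[r, j, q] = st[j, q]
            rec_S[r] = supply
            rec_t_idx[r] = k
            r += 1
    return st, s_damp, s_lin, rec[:r], rec_S[:r], rec_t_idx[:r]


@dataclass
class EngineOutput:
    """Trajectories and end-of-stimulation snapshot of an engine run.

    ``final`` maps synapse name → :class:`EnergyState` after the last sample.
    ``t``/``P``/... hold the recorded trajectories (shape ``(n_rec,)`` for the
    shared time grid and supply, ``(n_syn, n_rec)`` per synapse otherwise);
    empty arrays when recording was disabled.
    """

    synapses: list
    final: dict
    params: PlasticityParams
    t: np.ndarray
    S: np.ndarray
    P: np.ndarray
    P_bas: np.ndarray
    P_sup: np.ndarray
    W: np.ndarray
    P_u: np.ndarray
    P_bas_u: np.ndarray
    P_sup_u: np.ndarray
    W_u: np.ndarray

    @property
    def P_max(self) -> np.ndarray:
        """Supply-limited target trajectory S(t) · sign(P(t)) per synapse."""
        return self.S[None, :] * np.sign(self.P)

    def final_state(self, synapse) -> EnergyState:
        return self.final[synapse]

    def to_frame(self):
        """Long-format trajectory table (synapse, t_s, P, ..., W_u)."""
        import pandas as pd

        frames = []
        for j, name in enumerate(self.synapses):
            frames.append(
                pd.DataFrame(
                    {
                        "synapse": name,
                        "t_s": self.t,
                        "P": self.P[j],
                        "P_bas": self.P_bas[j],
                        "P_sup": self.P_sup[j],
                        "S": self.S,
                        "W": self.W[j],
                        "P_u": self.P_u[j],
                        "P_bas_u": self.P_bas_u[j],
                        "P_sup_u": self.P_sup_u[j],
                        "W_u": self.W_u[j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run(
    trace: TraceSet,
    params: PlasticityParams,
    synapse_map: dict | None = None,
    record: int | None = 1,
) -> EngineOutput:
    """Integrate the plasticity equations over a full trace.

    Parameters
    ----------
    trace:
        Uniformly sampled per-compartment trace; the engine step equals the
        trace step.
    synapse_map:
        Mapping compartment → synapse name (or list of names, for several
        synapses on one compartment); one independent :class:`EnergyState`
        is maintained per synapse.  Defaults to one synapse per compartment,
        named after it.
    record:
        Record the trajectory every ``record`` steps (1 = every step); None
        records only the end-of-stimulation snapshot.

    Returns
    -------
    EngineOutput
        Trajectories plus the end-of-stimulation snapshot (the state after
        the last sample of the trace).
    """
    validate_params(params)
    if synapse_map is None:
        synapse_map = {c: c for c in trace.compartments}
    comps, names = [], []
    for comp, syn in synapse_map.items():
        if comp not in trace.compartments:
            raise ValueError(f"synapse_map references unknown compartment {comp!r}")
        for name in (syn if isinstance(syn, (list, tuple)) else [syn]):
            comps.append(comp)
            names.append(name)
    idx = [trace.index_of(c) for c in comps]
    V = np.ascontiguousarray(trace.V_m[idx])
    I = np.ascontiguousarray(trace.I_m[idx])
    if not (np.isfinite(V).all() and np.isfinite(I).all()):
        raise ValueError("trace contains non-finite samples")

    dt = trace.dt if trace.n_samples > 1 else params.dt
    state0 = np.zeros((len(names), 8))
    state0[:, 3] = 0.5  # W
    state0[:, 7] = 0.5  # W_u
    stride = 0 if record is None else int(record)
    n_rec = 0 if stride == 0 else trace.n_samples // stride
    st, s_damp, s_lin, rec, rec_S, rec_idx = _integrate_kernel(
        V, I, dt, params.A, params.A_r, params.V_th, params.R, params.tau,
        params.S0, params.A_scale, state0, stride, n_rec,
    )

    final = {
        name: EnergyState(
            P=st[j, 0], P_bas=st[j, 1], P_sup=st[j, 2], W=st[j, 3],
            P_u=st[j, 4], P_bas_u=st[j, 5], P_sup_u=st[j, 6], W_u=st[j, 7],
            S_damp=s_damp, S_lin=s_lin,
        )
        for j, name in enumerate(names)
    }
    # recorded state is the value *after* step k, i.e. at time t[k] + dt
    t_rec = trace.t[rec_idx] + dt if len(rec_idx) else np.empty(0)
    tr = rec.transpose(1, 0, 2) if len(rec) else np.empty((len(names), 0, 8))
    return EngineOutput(
        synapses=names,
        final=final,
        params=params,
        t=t_rec,
        S=rec_S,
        P=tr[:, :, 0],
        P_bas=tr[:, :, 1],
        P_sup=tr[:, :, 2],
        W=tr[:, :, 3],
        P_u=tr[:, :, 4],
        P_bas_u=tr[:, :, 5],
        P_sup_u=tr[:, :, 6],
        W_u=tr[:, :, 7],
    )
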