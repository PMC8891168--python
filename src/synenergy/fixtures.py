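"""Synthetic piecewise-constant traces and independent oracles.

These make the plasticity engine fully testable without the neuron
simulator: a trace built from constant (V_m, I_m) segments has closed-form
unconstrained energy sums, and a deliberately naive re-integration loop
(no vectorization, no code shared with the engine, closed-form supply)
provides an independent check in the constrained regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import EnergyState, PlasticityParams, TraceSet

__all__ = [
    "Segment",
    "piecewise_trace",
    "closed_form_unconstrained",
    "reference_integrator",
    "constrained_battery",
]


@dataclass(frozen=True)
class Segment:
    """A constant stretch of membrane state: duration s, V_m mV, I_m pA/μm²."""

    duration: float
    V_m: float
    I_m: float


def piecewise_trace(segments, dt: float, compartment: str = "fix0") -> TraceSet:
    """Single-compartment trace concatenating constant segments on the dt grid.

    Each segment's duration must be a positive multiple of ``dt``.  Sample k
    holds the value of the segment covering the half-open interval
    [k·dt, (k+1)·dt), so a sample on a segment boundary belongs to the later
    segment.
    """
    if not segments:
        raise ValueError("piecewise_trace requires at least one segment")
    counts = []
    for seg in segments:
        n = seg.duration / dt
        if seg.duration <= 0 or abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"segment duration {seg.duration} s is not a positive multiple of dt={dt} s"
            )
        counts.append(int(round(n)))
    V = np.concatenate([np.full(n, seg.V_m) for n, seg in zip(counts, segments)])
    I = np.concatenate([np.full(n, seg.I_m) for n, seg in zip(counts, segments)])
    t = np.arange(len(V)) * dt
    return TraceSet(t=t, compartments=[compartment], V_m=V[None, :], I_m=I[None, :])


def closed_form_unconstrained(segments, params: PlasticityParams):
    """Segment-sum oracle for the unconstrained regime.

    Valid only when |P| stays below the supply throughout (caller's
    responsibility, checkable via :func:`synenergy.engine.supply_closed_form`).
    Returns ``(P, P_bas, P_sup, dW)`` where P = Σ V·I·T over segments,
    P_bas sums A_r·V·I·T over the subthreshold segments, P_sup sums V·I·T
    over the suprathreshold ones, and dW = A·(P_bas − P_sup).
    """
    P = P_bas = P_sup = 0.0
    for seg in segments:
        e = params.A_scale * seg.V_m * seg.I_m * seg.duration
        P += e
        if seg.V_m < params.V_th:
            P_bas += params.A_r * e
        else:
            P_sup += e
    return P, P_bas, P_sup, params.A * (P_bas - P_sup)


def reference_integrator(trace: TraceSet, params: PlasticityParams, refine: int = 10):
    """Naive re-integration of the plasticity equations at dt/refine.

    Independent oracle: a plain Python loop over every fine substep with the
    supply evaluated from its closed form S(t) = R·t·e^(−t/τ) + S0 on the
    A_scale-compressed clock (rather than from the Euler supply equations).
    Returns a dict mapping compartment → end-of-trace :class:`EnergyState`.
    """
    if refine < 2:
        raise ValueError("refine must be >= 2")
    dt = trace.dt / refine
    out = {}
    for row, comp in enumerate(trace.compartments):
        P = P_bas = P_sup = 0.0
        Pu = Pbu = Psu = 0.0
        W = Wu = 0.5
        for k in range(trace.n_samples):
            v = float(trace.V_m[row, k])
            cur = float(trace.I_m[row, k])
            for f in range(refine):
                t_end = (k * refine + f + 1) * dt
                tc = params.A_scale * t_end
                supply = params.R * tc * math.exp(-tc / params.tau) + params.S0
                diff = supply - abs(P)
                sgn = 1.0 if diff > 0 else (-1.0 if diff < 0 else 0.0)
                power = params.A_scale * v * cur * dt
                if v < params.V_th:
                    P_bas += params.A_r * power * sgn
                    Pbu += params.A_r * power
                    W += params.A * params.A_r * power * sgn
                    Wu += params.A * params.A_r * power
                else:
                    P_sup += power * sgn
                    Psu += power
                    W -= params.A * power * sgn
                    Wu -= params.A * power
                P += power * sgn
                Pu += power
        tc = params.A_scale * trace.n_samples * trace.dt
        out[comp] = EnergyState(
            P=P, P_bas=P_bas, P_sup=P_sup, W=W,
            P_u=Pu, P_bas_u=Pbu, P_sup_u=Psu, W_u=Wu,
            S_damp=math.exp(-tc / params.tau), S_lin=params.R * tc,
        )
    return out


def constrained_battery(dt: float = 1e-4):
    """Fixture set whose unconstrained |P| exceeds the supply at some point.

    Returns a list of (name, segments) pairs used by the supply-boundary
    tests; the canonical member is the constant subthreshold segment
    (−65 mV, +11 pA/μm², 0.1 s) whose unconstrained energy reaches
    −71.5 fJ/μm² while the supply stays below 42 fJ/μm².  The power V·I
    keeps one sign within each fixture: the boundary-tracking chatter of the
    sign factor holds |P| at the supply only while the drive keeps pushing
    outward (the regime the stimulation protocols operate in).
    """
    return [
        ("sub_depol", [Segment(0.1, -65.0, 11.0)]),
        ("sub_strong", [Segment(0.2, -70.0, 15.0)]),
        ("supra_repol", [Segment(0.15, 20.0, -25.0)]),
        ("sub_outward", [Segment(0.15, -65.0, -9.0)]),  # positive-P side
        ("mixed", [Segment(0.05, -65.0, 11.0), Segment(0.05, -20.0, 30.0),
                   Segment(0.05, -65.0, 8.0)]),
    ]
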