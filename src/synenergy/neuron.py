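"""Reduced branched pyramidal-neuron simulator.

A spherical soma plus a small number of unbranched thin basal dendrites,
each discretized into equal cylindrical compartments.  Active conductances
are a standard spiking sodium/potassium pair (Traub-style kinetics) at full
density in the soma and at a reduced density in the dendrites, so that a
somatic action potential backpropagates with distance-dependent attenuation.
A fixed potassium leak is solved per compartment at build time so that every
compartment rests at the target resting potential (−69 mV) while the ohmic
leak reversal stays at E_L = −60 mV.

The cable equations are integrated with a semi-implicit scheme: channel
gates advance by exponential Euler, then the voltage system (axial coupling
plus total membrane conductance) is solved implicitly by Hines elimination
on the dendritic tree.  The simulator emits, per compartment, the membrane
potential V_m (mV) and the membrane current density I_m (pA/μm², positive =
depolarizing), where I_m sums the ionic and synaptic transmembrane currents;
capacitive, axial and electrode currents are excluded, so I_m measures the
dissipative flux through the membrane that pumps must restore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import TraceSet

__all__ = [
    "Morphology",
    "ChannelConfig",
    "SynapseConfig",
    "NeuronModel",
    "build_neuron",
    "run_sim",
]

# unit conversions: densities in mS/cm² → 0.01 nS/μm²; Cm in μF/cm² → 0.01 pF/μm²
_DENS = 0.01
_CM = 0.01


@dataclass(frozen=True)
class Morphology:
    """Soma sphere plus identical unbranched basal dendrites.

    ``n_branches`` basal dendrites, each of ``comps_per_branch`` cylindrical
    compartments of ``comp_length``×``comp_diam`` μm, attached directly to a
    soma of diameter ``soma_diam`` μm.
    """

    n_branches: int = 4
    comps_per_branch: int = 20
    comp_length: float = 10.0
    comp_diam: float = 1.0
    soma_diam: float = 20.0

    def validate(self) -> "Morphology":
        if self.n_branches < 1:
            raise ValueError("morphology needs at least one branch")
        if self.comps_per_branch < 7:
            raise ValueError("need >= 7 compartments per branch (7-site binning)")
        if min(self.comp_length, self.comp_diam, self.soma_diam) <= 0:
            raise ValueError("geometry lengths must be positive")
        return self

    @property
    def n_compartments(self) -> int:
        return 1 + self.n_branches * self.comps_per_branch


@dataclass(frozen=True)
class ChannelConfig:
    """Membrane channels and passive properties.

    Conductance densities in mS/cm²; reversal potentials in mV.  The
    dendritic Na/K densities are ``dendrite_scale`` times the somatic ones.
    ``V_rest`` is the calibration target: a potassium leak density is solved
    per compartment at build time so the zero-input steady state sits there.
    ``terminal_leak`` (nS) is an absorbing boundary at each branch tip — a
    conductance reversing at ``V_rest`` that stands in for the axial load of
    a continuing dendrite, suppressing the sealed-end voltage reflection; it
    carries no current at rest and is excluded from the reported I_m (it
    models axial, not transmembrane, flux).
    """

    g_L: float = 0.05
    E_L: float = -60.0
    g_Na: float = 50.0
    g_K: float = 5.0
    dendrite_scale: float = 0.02
    E_Na: float = 50.0
    E_K: float = -90.0
    V_T: float = -55.0
    V_rest: float = -69.0
    Cm: float = 1.0
    Ra: float = 150.0
    terminal_leak: float = 2.0

    def validate(self) -> "ChannelConfig":
        if min(self.g_L, self.g_Na, self.g_K, self.Cm, self.Ra) < 0:
            raise ValueError("conductances, capacitance and resistivity must be >= 0")
        if not (self.E_K < self.V_rest < self.E_L):
            raise ValueError("resting target must lie between E_K and E_L for the leak solve")
        return self


@dataclass(frozen=True)
class SynapseConfig:
    """Excitatory synapse: fast AMPA-like + slow NMDA-like conductance.

    Peak conductances in nS (per activation, before the weight multiplier),
    decay times in ms, reversal 0 mV.  The NMDA component carries the
    standard sigmoidal magnesium block 1/(1 + [Mg]/3.57 · e^(−0.062·V)).
    ``include_in_Im`` controls whether synaptic current enters the reported
    membrane current density.
    """

    g_ampa: float = 0.5
    tau_ampa: float = 2.0
    g_nmda: float = 8.0
    tau_nmda: float = 50.0
    mg: float = 1.0
    include_in_Im: bool = True

    def validate(self) -> "SynapseConfig":
        if min(self.g_ampa, self.g_nmda, self.mg) < 0 or min(self.tau_ampa, self.tau_nmda) <= 0:
            raise ValueError("synaptic conductances must be >= 0 and decay times > 0")
        return self


# --- Traub/Pospischil-style rate functions (ms⁻¹, V in mV, relative to V_T) ---


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def _rates(v, VT):
    u = v - VT
    a_m = 0.32 * _vtrap(13.0 - u, 4.0)
    b_m = 0.28 * _vtrap(u - 40.0, 5.0)
    a_h = 0.128 * math.exp(-(u - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
    a_n = 0.032 * _vtrap(15.0 - u, 5.0)
    b_n = 0.5 * math.exp(-(u - 10.0) / 40.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@dataclass
class NeuronModel:
    """Compiled compartmental model (arrays in mV / ms / pA / nS / pF / μm)."""

    morphology: Morphology
    channels: ChannelConfig
    synapses: SynapseConfig
    compartments: list = field(default_factory=list)
    parent: np.ndarray = None
    g_ax: np.ndarray = None  # nS, compartment → parent
    area: np.ndarray = None  # μm²
    C_abs: np.ndarray = None  # pF
    gL: np.ndarray = None  # absolute nS per compartment
    gKL: np.ndarray = None
    gNa: np.ndarray = None
    gK: np.ndarray = None
    g_term: np.ndarray = None  # absorbing tip conductance, nS
    distance: np.ndarray = None  # path distance of compartment center from soma, μm
    branch: np.ndarray = None

    def index_of(self, name: str) -> int:
        try:
            return self.compartments.index(name)
        except ValueError:
            raise KeyError(f"unknown compartment {name!r}") from None

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)


def _steady_gates(v, VT):
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(v, VT)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def build_neuron(
    morphology: Morphology = Morphology(),
    channels: ChannelConfig = ChannelConfig(),
    synapses: SynapseConfig = SynapseConfig(),
) -> NeuronModel:
    """Compile a deterministic compartmental cable model from the configs.

    The potassium-leak density of each compartment is solved so that, with
    the spiking channels at their steady-state activation, the zero-input
    membrane equation balances exactly at ``channels.V_rest``.
    """
    morphology.validate()
    channels.validate()
    synapses.validate()
    L, nb = morphology.comps_per_branch, morphology.n_branches
    n = morphology.n_compartments
    names = ["soma"] + [f"b{b}c{i}" for b in range(nb) for i in range(L)]
    parent = np.zeros(n, dtype=np.int64)
    branch = np.full(n, -1, dtype=np.int64)
    dist = np.zeros(n)
    area = np.zeros(n)
    area[0] = math.pi * morphology.soma_diam**2
    a_cross = math.pi * morphology.comp_diam**2 / 4.0
    g_ax = np.zeros(n)
    for b in range(nb):
        for i in range(L):
            k = 1 + b * L + i
            parent[k] = k - 1 if i > 0 else 0
            branch[k] = b
            dist[k] = (i + 0.5) * morphology.comp_length
            area[k] = math.pi * morphology.comp_diam * morphology.comp_length
            # axial conductance to parent: half-cylinder into soma, full spacing otherwise
            length = morphology.comp_length if i > 0 else morphology.comp_length / 2.0
            g_ax[k] = 1e5 * a_cross / (channels.Ra * length)

    dens_Na = np.full(n, channels.g_Na * channels.dendrite_scale)
    dens_K = np.full(n, channels.g_K * channels.dendrite_scale)
    dens_Na[0] = channels.g_Na
    dens_K[0] = channels.g_K

    vr = channels.V_rest
    m0, h0, n0 = _steady_gates(vr, channels.V_T)
    # per-area balance at rest: g_L(vr-E_L) + g_Na m³h(vr-E_Na) + (g_K n⁴ + g_KL)(vr-E_K) = 0
    dens_KL = -(
        channels.g_L * (vr - channels.E_L)
        + dens_Na * m0**3 * h0 * (vr - channels.E_Na)
        + dens_K * n0**4 * (vr - channels.E_K)
    ) / (vr - channels.E_K)
    if np.any(dens_KL < 0):
        raise ValueError("channel configuration cannot rest at V_rest (negative leak solve)")

    g_term = np.zeros(n)
    for b in range(nb):
        g_term[1 + b * L + (L - 1)] = channels.terminal_leak

    return NeuronModel(
        morphology=morphology,
        channels=channels,
        synapses=synapses,
        compartments=names,
        parent=parent,
        g_ax=g_ax,
        area=area,
        C_abs=channels.Cm * _CM * area,
        gL=channels.g_L * _DENS * area,
        gKL=dens_KL * _DENS * area,
        gNa=dens_Na * _DENS * area,
        gK=dens_K * _DENS * area,
        g_term=g_term,
        distance=dist,
        branch=branch,
    )


@njit(cache=True)
def _sim_kernel(
    parent, g_ax, C_abs, gL, gKL, gNa, gK, g_term, area,
    EL, EK, ENa, VT, v0, dt, n_steps,
    inj,  # (n_steps,) pA injected at the soma
    syn_comp, syn_ga_amp, syn_gn_amp,  # per synapse: target comp, peak nS × weight
    ev_step, ev_syn,  # activation events, sorted by step
    dec_a, dec_n, mg_coef, syn_in_im,
    rec, rec_stride,  # recorded compartment indices, output stride
):
    n = parent.shape[0]
    n_syn = syn_comp.shape[0]
    V = np.full(n, v0)
    m = np.empty(n)
    h = np.empty(n)
    ng = np.empty(n)
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(v0, VT)
    for i in range(n):
        m[i] = a_m / (a_m + b_m)
        h[i] = a_h / (a_h + b_h)
        ng[i] = a_n / (a_n + b_n)
    ga = np.zeros(n_syn)
    gn = np.zeros(n_syn)
    gs = np.zeros(n)  # synaptic conductance per compartment (Mg block applied)

    n_out = n_steps // rec_stride
    outV = np.empty((rec.shape[0], n_out))
    outI = np.empty((rec.shape[0], n_out))
    diag = np.empty(n)
    rhs = np.empty(n)
    ev_ptr = 0
    r = 0
    for k in range(n_steps):
        # synaptic events fire at the start of the step, then conductances decay
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == k:
            s = ev_syn[ev_ptr]
            ga[s] += syn_ga_amp[s]
            gn[s] += syn_gn_amp[s]
            ev_ptr += 1
        for i in range(n):
            gs[i] = 0.0
        for s in range(n_syn):
            c = syn_comp[s]
            blk = 1.0 / (1.0 + mg_coef * math.exp(-0.062 * V[c]))
            gs[c] += ga[s] + gn[s] * blk
            ga[s] *= dec_a
            gn[s] *= dec_n

        # gates: exponential Euler at the pre-step voltage
        for i in range(n):
            am, bm, ah, bh, an, bn = _rates(V[i], VT)
            m[i] += (am / (am + bm) - m[i]) * (1.0 - math.exp(-dt * (am + bm)))
            h[i] += (ah / (ah + bh) - h[i]) * (1.0 - math.exp(-dt * (ah + bh)))
            ng[i] += (an / (an + bn) - ng[i]) * (1.0 - math.exp(-dt * (an + bn)))

        # implicit voltage solve (Hines elimination toward the soma)
        for i in range(n):
            gna = gNa[i] * m[i] ** 3 * h[i]
            gk = gK[i] * ng[i] ** 4 + gKL[i]
            g_tot = gL[i] + gna + gk + gs[i] + g_term[i]
            diag[i] = C_abs[i] / dt + g_tot
            rhs[i] = C_abs[i] / dt * V[i] + gL[i] * EL + gna * ENa + gk * EK + g_term[i] * v0
        rhs[0] += inj[k]
        for i in range(1, n):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]
        for i in range(n - 1, 0, -1):
            f = g_ax[i] / diag[i]
            diag[parent[i]] -= f * g_ax[i]
            rhs[parent[i]] += f * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, n):
            V[i] = (rhs[i] + g_ax[i] * V[parent[i]]) / diag[i]

        if (k + 1) % rec_stride == 0:
            for j in range(rec.shape[0]):
                i = rec[j]
                gna = gNa[i] * m[i] ** 3 * h[i]
                gk = gK[i] * ng[i] ** 4 + gKL[i]
                im = gL[i] * (V[i] - EL) + gna * (V[i] - ENa) + gk * (V[i] - EK)
                if syn_in_im:
                    im += gs[i] * V[i]
                outV[j, r] = V[i]
                outI[j, r] = -im / area[i]  # depolarizing-positive, pA/μm²
            r += 1
    return outV, outI


def run_sim(
    neuron: NeuronModel,
    stimuli,
    duration: float,
    dt: float = 1e-4,
    synapse_weights: dict | None = None,
    record=None,
    record_stride: int = 1,
) -> TraceSet:
    """Simulate the neuron under a stimulation protocol.

    Parameters
    ----------
    stimuli:
        A :class:`synenergy.protocols.ProtocolSpec`-like object with
        ``pre_events`` (mapping compartment name → presynaptic event times,
        s) and ``somatic_pulses`` (list of (onset_s, amplitude_nA, width_ms)).
    duration:
        Total simulated time, s.
    dt:
        Step, s (cable integration and output grid).
    synapse_weights:
        Conductance weight multiplier per stimulated compartment (default
        0.5, the initial synaptic weight).
    record:
        Compartment names to record (default: all).
    record_stride:
        Keep every ``record_stride``-th sample.

    Returns
    -------
    TraceSet
        V_m (mV) and I_m (pA/μm²) per recorded compartment.
    """
    dt_ms = dt * 1e3
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")

    pre = getattr(stimuli, "pre_events", {}) or {}
    pulses = getattr(stimuli, "somatic_pulses", []) or []
    weights = synapse_weights or {}

    syn_comp, syn_ga, syn_gn, ev = [], [], [], []
    for s, (comp, times) in enumerate(sorted(pre.items())):
        ci = neuron.index_of(comp)
        w = weights.get(comp, 0.5)
        syn_comp.append(ci)
        syn_ga.append(neuron.synapses.g_ampa * w)
        syn_gn.append(neuron.synapses.g_nmda * w)
        for t in np.atleast_1d(times):
            k = int(round(float(t) / dt))
            if not (0 <= k < n_steps):
                raise ValueError(f"presynaptic event at {t} s outside [0, {duration}) s")
            ev.append((k, s))
    ev.sort()
    ev_step = np.array([e[0] for e in ev], dtype=np.int64) if ev else np.empty(0, np.int64)
    ev_syn = np.array([e[1] for e in ev], dtype=np.int64) if ev else np.empty(0, np.int64)

    inj = np.zeros(n_steps)
    for onset, amp_nA, width_ms in pulses:
        k0 = int(round(onset / dt))
        k1 = k0 + max(1, int(round(width_ms * 1e-3 / dt)))
        if k0 < 0 or k0 >= n_steps:
            raise ValueError(f"somatic pulse at {onset} s outside the simulated window")
        inj[k0:min(k1, n_steps)] = amp_nA * 1e3  # pA

    rec_names = list(record) if record is not None else list(neuron.compartments)
    rec_idx = np.array([neuron.index_of(c) for c in rec_names], dtype=np.int64)

    ch, sy = neuron.channels, neuron.synapses
    outV, outI = _sim_kernel(
        neuron.parent, neuron.g_ax, neuron.C_abs, neuron.gL, neuron.gKL,
        neuron.gNa, neuron.gK, neuron.g_term, neuron.area,
        ch.E_L, ch.E_K, ch.E_Na, ch.V_T, ch.V_rest, dt_ms, n_steps,
        inj,
        np.array(syn_comp, dtype=np.int64) if syn_comp else np.empty(0, np.int64),
        np.array(syn_ga) if syn_ga else np.empty(0),
        np.array(syn_gn) if syn_gn else np.empty(0),
        ev_step, ev_syn,
        math.exp(-dt_ms / sy.tau_ampa), math.exp(-dt_ms / sy.tau_nmda),
        sy.mg / 3.57, sy.include_in_Im,
        rec_idx, record_stride,
    )
    n_out = outV.shape[1]
    t = (np.arange(n_out) + 1) * dt * record_stride
    return TraceSet(
        t=t,
        compartments=rec_names,
        V_m=outV,
        I_m=outI,
        distance=neuron.distance[rec_idx],
        branch=neuron.branch[rec_idx],
    )
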