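"""Protocol sweeps over the reduced neuron + plasticity engine.

Each experiment runs one of the stimulation protocols across recording
sites on the basal dendrites, integrates the energy engine over the
resulting membrane traces, and tabulates end-of-stimulation weights and
energies — constrained and unconstrained — as mean ± SD over compartments.

Recording sites sit in the proximal third and the distal third of each
branch, evenly spaced within each zone.  Pairing sweeps stimulate one
synapse per run; the afferent sweep activates at most one site per branch
at a time (independent Poisson streams do not synchronize, so cross-branch
interaction through the soma stays negligible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PlasticityParams
from .engine import run as engine_run
from .neuron import NeuronModel, build_neuron, run_sim
from .protocols import ProtocolSpec, afferent_protocol, hfs_protocol, pairing_protocol

__all__ = [
    "ExperimentResult",
    "recording_sites",
    "frequency_curve",
    "timing_curve",
    "afferent_curve",
    "mexican_hat",
]

_QUANTITIES = ["dW", "dW_u", "P", "P_u", "P_bas", "P_sup", "P_bas_u", "P_sup_u",
               "S_end", "P_max", "euler_inc"]


@dataclass
class ExperimentResult:
    """Tabulated sweep output.

    ``table`` holds one row per (swept value, synapse) with end-of-
    stimulation quantities; ``summary`` one row per swept value with the
    mean and SD over synapses of each quantity.  ``x_name`` names the swept
    variable (frequency_Hz, delta_t_ms, or site).
    """

    x_name: str
    table: pd.DataFrame
    summary: pd.DataFrame
    n_compartments: int
    failures: list

    @property
    def x(self) -> np.ndarray:
        return self.summary[self.x_name].to_numpy()

    def mean(self, quantity: str) -> np.ndarray:
        return self.summary[f"{quantity}_mean"].to_numpy()

    def sd(self, quantity: str) -> np.ndarray:
        return self.summary[f"{quantity}_sd"].to_numpy()


def _summarize(table: pd.DataFrame, x_name: str) -> pd.DataFrame:
    g = table.groupby(x_name)
    out = {x_name: []}
    for q in _QUANTITIES:
        out[f"{q}_mean"] = []
        out[f"{q}_sd"] = []
    for x, sub in g:
        out[x_name].append(x)
        for q in _QUANTITIES:
            out[f"{q}_mean"].append(sub[q].mean())
            out[f"{q}_sd"].append(sub[q].std(ddof=0))
    return pd.DataFrame(out)


def recording_sites(neuron: NeuronModel, sites_per_zone: int = 3) -> dict:
    """Evenly spaced recording compartments in each branch's proximal and
    distal thirds.

    Returns ``{"proximal": [...], "distal": [...]}`` with
    ``sites_per_zone`` compartment names per branch per zone.
    """
    L = neuron.morphology.comps_per_branch
    third = L // 3
    prox_idx = np.unique(np.round(np.linspace(0, third - 1, sites_per_zone)).astype(int))
    dist_idx = np.unique(np.round(np.linspace(L - third, L - 1, sites_per_zone)).astype(int))
    out = {"proximal": [], "distal": []}
    for b in range(neuron.morphology.n_branches):
        out["proximal"] += [f"b{b}c{i}" for i in prox_idx]
        out["distal"] += [f"b{b}c{i}" for i in dist_idx]
    return out


def _batches(neuron: NeuronModel, sites: list) -> list:
    """Group sites so each run stimulates at most one site per branch."""
    by_branch = {}
    for s in sites:
        b = int(neuron.branch[neuron.index_of(s)])
        by_branch.setdefault(b, []).append(s)
    n = max(len(v) for v in by_branch.values())
    return [
        [v[i] for v in by_branch.values() if i < len(v)]
        for i in range(n)
    ]


def _final_rows(neuron, trace, spec, params, comps, x_name, x, synapses_per_comp=1):
    """Integrate the engine over a trace and flatten the final states."""
    eng_params = params.with_scale(spec.A_scale)
    if synapses_per_comp == 1:
        synapse_map = {c: c for c in comps}
    else:
        synapse_map = {c: [f"{c}_s{k}" for k in range(synapses_per_comp)] for c in comps}
    out = engine_run(trace, eng_params, synapse_map=synapse_map, record=None)
    rows = []
    for name in out.synapses:
        comp = name.split("_s")[0] if synapses_per_comp > 1 else name
        row_i = trace.index_of(comp)
        max_vi = float(np.max(np.abs(trace.V_m[row_i] * trace.I_m[row_i])))
        st = out.final[name]
        s_end = st.supply(eng_params)
        rows.append(
            {
                x_name: x,
                "synapse": name,
                "compartment": comp,
                "distance_um": float(trace.distance[row_i]),
                "branch": int(trace.branch[row_i]),
                "dW": st.W - 0.5,
                "dW_u": st.W_u - 0.5,
                "P": st.P,
                "P_u": st.P_u,
                "P_bas": st.P_bas,
                "P_sup": st.P_sup,
                "P_bas_u": st.P_bas_u,
                "P_sup_u": st.P_sup_u,
                "S_end": s_end,
                "P_max": s_end * np.sign(st.P),
                "euler_inc": eng_params.A_scale * max_vi * trace.dt,
            }
        )
    return rows


def _pairing_sweep(x_name, values, make_proto, neuron, params, dt, sites_per_zone):
    # pairing runs stimulate one synapse at a time: simultaneously active
    # synapses on different branches would sum at the soma and fire spikes
    # the pairing protocol does not prescribe
    if neuron is None:
        neuron = build_neuron()
    sites = recording_sites(neuron, sites_per_zone)
    all_sites = sites["proximal"] + sites["distal"]
    rows, failures = [], []
    for x in values:
        try:
            proto = make_proto(x)
            for batch in [[s] for s in all_sites]:
                spec = proto.for_compartments(batch)
                trace = run_sim(neuron, spec, spec.duration, dt, record=batch)
                rows += _final_rows(neuron, trace, spec, params, batch, x_name, x)
        except Exception as exc:  # keep sweeping; report at the end
            failures.append((x, repr(exc)))
    table = pd.DataFrame(rows)
    summary = _summarize(table, x_name) if len(table) else pd.DataFrame()
    return ExperimentResult(x_name, table, summary, len(all_sites), failures)


def frequency_curve(
    delta_t_ms: float,
    freqs,
    neuron: NeuronModel | None = None,
    params: PlasticityParams = PlasticityParams(),
    dt: float = 1e-4,
    repeats: int = 5,
    sites_per_zone: int = 3,
) -> ExperimentResult:
    """Pairing protocol swept over repetition frequency at fixed Δt.

    Five pre/post pairs (A_scale = 12) per frequency; one synapse on each
    proximal and distal recording site, pooled for the statistics.
    """
    return _pairing_sweep(
        "frequency_Hz", list(freqs),
        lambda f: pairing_protocol(f, delta_t_ms, repeats),
        neuron, params, dt, sites_per_zone,
    )


def timing_curve(
    delta_ts_ms,
    freq: float = 20.0,
    neuron: NeuronModel | None = None,
    params: PlasticityParams = PlasticityParams(),
    dt: float = 1e-4,
    repeats: int = 5,
    sites_per_zone: int = 3,
) -> ExperimentResult:
    """Pairing protocol swept over the pre/post interval Δt at fixed frequency."""
    return _pairing_sweep(
        "delta_t_ms", list(delta_ts_ms),
        lambda d: pairing_protocol(freq, d, repeats),
        neuron, params, dt, sites_per_zone,
    )


def afferent_curve(
    rates,
    seed: int | None = None,
    neuron: NeuronModel | None = None,
    params: PlasticityParams = PlasticityParams(),
    dt: float = 1e-4,
    n_pulses: int = 20,
    sites_per_zone: int = 3,
) -> ExperimentResult:
    """Presynaptic-only Poisson afferent protocol swept over input rate.

    Each synapse receives its own count-conditioned Poisson realization of
    ``n_pulses`` events (independent streams spawned from ``seed``); no
    somatic injection; A_scale = 1.
    """
    if neuron is None:
        neuron = build_neuron()
    sites = recording_sites(neuron, sites_per_zone)
    all_sites = sites["proximal"] + sites["distal"]
    root = np.random.SeedSequence(seed)
    rows, failures = [], []
    for rate, ss in zip(rates, root.spawn(len(list(rates)))):
        try:
            child_seeds = iter(ss.generate_state(len(all_sites)) % (2**31))
            for batch in _batches(neuron, all_sites):
                per_comp, dur = {}, 0.0
                for c in batch:
                    p = afferent_protocol(rate, n_pulses, seed=int(next(child_seeds)))
                    per_comp[c] = p.pre_times
                    dur = max(dur, p.duration)
                spec = ProtocolSpec(
                    pre_times=np.empty(0), somatic_pulses=[], duration=dur,
                    A_scale=1.0, seed=seed, name=f"afferent_{rate:g}Hz",
                ).for_compartments(batch, per_comp)
                trace = run_sim(neuron, spec, spec.duration, dt, record=batch)
                rows += _final_rows(neuron, trace, spec, params, batch, "rate_Hz", rate)
        except Exception as exc:
            failures.append((rate, repr(exc)))
    table = pd.DataFrame(rows)
    summary = _summarize(table, "rate_Hz") if len(table) else pd.DataFrame()
    return ExperimentResult("rate_Hz", table, summary, len(all_sites), failures)


def mexican_hat(
    stim_location: str = "both",
    seed: int | None = None,
    neuron: NeuronModel | None = None,
    params: PlasticityParams = PlasticityParams(),
    dt: float = 1e-4,
    sites_per_zone: int = 2,
    inter_series_gap: float = 10.0,
) -> ExperimentResult:
    """HFS at one site per run; 7-site homo/heterosynaptic profile.

    Every compartment of the stimulated branch carries two synapses; only
    the stimulated compartment's synapses receive the shocks.  Site 0 is the
    stimulated compartment; the remaining same-branch compartments are
    binned into sites 1–6 by equal-width path distance from site 0 and each
    site's value is the average over its compartments (and both synapses).
    Synapses on other branches are recorded in ``table`` (site = -1) but
    excluded from the 7-site summary.  The supply clock runs continuously
    over the four shock series.
    """
    if stim_location not in ("proximal", "distal", "both"):
        raise ValueError("stim_location must be 'proximal', 'distal' or 'both'")
    if neuron is None:
        neuron = build_neuron()
    sites = recording_sites(neuron, sites_per_zone)
    if stim_location == "both":
        stim_sites = sites["proximal"] + sites["distal"]
    else:
        stim_sites = sites[stim_location]
    L = neuron.morphology.comps_per_branch
    root = np.random.SeedSequence(seed)
    rows, failures = [], []
    for stim, ss in zip(stim_sites, root.spawn(len(stim_sites))):
        try:
            proto = hfs_protocol(seed=int(ss.generate_state(1)[0] % (2**31)),
                                 inter_series_gap=inter_series_gap)
            b = int(neuron.branch[neuron.index_of(stim)])
            branch_comps = [f"b{b}c{i}" for i in range(L)]
            other = [c for c in sites["proximal"] + sites["distal"]
                     if int(neuron.branch[neuron.index_of(c)]) != b]
            spec = proto.for_compartments([stim])
            trace = run_sim(neuron, spec, spec.duration, dt, record=branch_comps + other)
            batch_rows = _final_rows(
                neuron, trace, spec, params, branch_comps + other,
                "stim_site", stim, synapses_per_comp=2,
            )
            d0 = neuron.distance[neuron.index_of(stim)]
            same = np.array([r["branch"] == b for r in batch_rows])
            dists = np.array([abs(r["distance_um"] - d0) for r in batch_rows])
            hetero = same & (dists > 0)
            width = dists[hetero].max() / 6.0 if hetero.any() else 1.0
            for r, d, s in zip(batch_rows, dists, same):
                if not s:
                    r["site"] = -1  # off-branch: recorded, excluded from the 7-site table
                else:
                    r["site"] = 0 if d == 0 else min(6, 1 + int(d / width))
            rows += batch_rows
        except Exception as exc:
            failures.append((stim, repr(exc)))
    table = pd.DataFrame(rows)
    # per-run per-site averages, then statistics across runs
    per_run = (
        table[table.site >= 0].groupby(["stim_site", "site"])[_QUANTITIES].mean().reset_index()
        if len(table) else pd.DataFrame()
    )
    summary = _summarize(per_run, "site") if len(per_run) else pd.DataFrame()
    return ExperimentResult("site", table, summary, len(stim_sites), failures)
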