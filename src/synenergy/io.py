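"""Trace/table file formats and configuration plumbing.

Traces travel as long-format delimited text with the header
``time_s, compartment, V_m_mV, I_m_pA_per_um2`` (optional ``distance_um``
and ``branch`` columns are preserved).  Engine outputs and experiment
tables are CSV.  Configs are flat YAML or JSON mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PlasticityParams, TraceSet
from .neuron import ChannelConfig, Morphology, SynapseConfig

__all__ = [
    "read_trace",
    "write_trace",
    "write_engine_output",
    "load_config",
    "save_config",
    "build_configs",
]

_TRACE_COLS = ["time_s", "compartment", "V_m_mV", "I_m_pA_per_um2"]


def read_trace(path) -> TraceSet:
    """Read a delimited trace table into a validated :class:`TraceSet`.

    Rows may be in any order (they are sorted by time per compartment);
    missing columns, NaN values and a non-uniform time grid are each
    reported distinctly.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _TRACE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing columns: {missing}")
    if df[_TRACE_COLS].isna().any().any():
        bad = df.columns[df[_TRACE_COLS].isna().any().to_numpy().nonzero()[0]]
        raise ValueError(f"trace file {path} contains NaN values in {list(bad)}")
    comps = list(dict.fromkeys(df["compartment"]))
    t = np.sort(df["time_s"].unique())
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError(
                f"trace file {path} has a non-uniform time grid: "
                f"step range [{steps.min():g}, {steps.max():g}] s"
            )
    V = np.empty((len(comps), len(t)))
    I = np.empty((len(comps), len(t)))
    dist = np.zeros(len(comps))
    branch = np.full(len(comps), -1)
    for j, c in enumerate(comps):
        sub = df[df["compartment"] == c].sort_values("time_s")
        if len(sub) != len(t):
            raise ValueError(f"compartment {c!r} does not cover the full time grid")
        V[j] = sub["V_m_mV"].to_numpy()
        I[j] = sub["I_m_pA_per_um2"].to_numpy()
        if "distance_um" in sub:
            dist[j] = sub["distance_um"].iloc[0]
        if "branch" in sub:
            branch[j] = sub["branch"].iloc[0]
    return TraceSet(t=t, compartments=comps, V_m=V, I_m=I, distance=dist, branch=branch)


def write_trace(trace: TraceSet, path) -> None:
    """Write a :class:`TraceSet` in the long delimited format (full precision)."""
    frames = []
    for j, c in enumerate(trace.compartments):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trace.t,
                    "compartment": c,
                    "V_m_mV": trace.V_m[j],
                    "I_m_pA_per_um2": trace.I_m[j],
                    "distance_um": trace.distance[j],
                    "branch": trace.branch[j],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_engine_output(out, path) -> None:
    """Write engine trajectories (or the final snapshot) as CSV."""
    if len(out.t):
        df = out.to_frame()
    else:
        rows = []
        for name in out.synapses:
            st = out.final[name]
            rows.append(
                {
                    "synapse": name, "t_s": np.nan,
                    "P": st.P, "P_bas": st.P_bas, "P_sup": st.P_sup,
                    "S": st.supply(out.params), "W": st.W,
                    "P_u": st.P_u, "P_bas_u": st.P_bas_u,
                    "P_sup_u": st.P_sup_u, "W_u": st.W_u,
                }
            )
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a flat YAML/JSON config mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(cfg, indent=2, default=float))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def build_configs(cfg: dict):
    """Split a flat config into (PlasticityParams, Morphology, ChannelConfig,
    SynapseConfig); unknown keys are ignored so one file can hold everything."""
    params = PlasticityParams.from_config(cfg)
    morph = Morphology(**{k: cfg[k] for k in (
        "n_branches", "comps_per_branch", "comp_length", "comp_diam", "soma_diam",
    ) if k in cfg})
    chan = ChannelConfig(**{k: cfg[k] for k in (
        "g_L", "E_L", "g_Na", "g_K", "dendrite_scale", "E_Na", "E_K", "V_T",
        "V_rest", "Cm", "Ra", "terminal_leak",
    ) if k in cfg})
    syn = SynapseConfig(**{k: cfg[k] for k in (
        "g_ampa", "tau_ampa", "g_nmda", "tau_nmda", "mg", "include_in_Im",
    ) if k in cfg})
    return params, morph, chan, syn
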