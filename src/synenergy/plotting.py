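"""Experiment figures: weight and energy curves versus the swept variable."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_result"]


def plot_result(res, path, title: str = ""):
    """Three-panel summary of an :class:`ExperimentResult`.

    Top: constrained potential energy (±SD) with the supply-limited P_max;
    middle: baseline vs suprathreshold energy; bottom: weight change,
    constrained (solid, ±SD band) and unconstrained (dashed).
    """
    x = res.x
    fig, axes = plt.subplots(3, 1, figsize=(5.5, 8), sharex=True)
    ax = axes[0]
    ax.plot(x, res.mean("P"), "k-", label="P (constrained)")
    ax.plot(x, res.mean("P_u"), "b--", label="P (unconstrained)")
    ax.plot(x, res.mean("P_max"), "r:", label="P_max")
    ax.set_ylabel("P (fJ/μm²)")
    ax.legend(fontsize=8)
    ax = axes[1]
    ax.plot(x, res.mean("P_bas"), "k--", label="P_bas")
    ax.plot(x, res.mean("P_sup"), "k-", label="P_sup")
    ax.plot(x, res.mean("P_bas_u"), "b--", alpha=0.5, label="P_bas (uncon)")
    ax.plot(x, res.mean("P_sup_u"), "b-", alpha=0.5, label="P_sup (uncon)")
    ax.set_ylabel("energy (fJ/μm²)")
    ax.legend(fontsize=8)
    ax = axes[2]
    ax.fill_between(x, res.mean("dW") - res.sd("dW"), res.mean("dW") + res.sd("dW"),
                    color="k", alpha=0.2)
    ax.plot(x, res.mean("dW"), "k-", label="ΔW (constrained)")
    ax.plot(x, res.mean("dW_u"), "b--", label="ΔW (unconstrained)")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_ylabel("ΔW")
    ax.set_xlabel(res.x_name)
    ax.legend(fontsize=8)
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
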