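"""Optional figures: trajectory curves and projected risk reductions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_SCENARIO_LABELS = {
    "observed": "Observed LLT",
    "opt_statin": "Optimized statin",
    "opt_statin_ez": "Optimized statin + ezetimibe",
}


def plot_trajectories(curves: dict, path: str) -> None:
    """Mean LDL-C curves with 95% CI bands per treatment scenario."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sc, curve in curves.items():
        ax.plot(curve.grid, curve.mean, label=_SCENARIO_LABELS.get(sc, sc))
        ax.fill_between(curve.grid, curve.lo, curve.hi, alpha=0.2)
    ax.set_xlabel("Days after index angiography")
    ax.set_ylabel("LDL-C (mg/dL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk_reduction(projection: pd.DataFrame, path: str, stratum: str = "all") -> None:
    """Projected absolute risk reduction per outcome over time."""
    sub = projection.loc[projection["stratum"] == stratum]
    outcomes = sub["outcome"].unique()
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, outcome in zip(axes.ravel(), outcomes):
        for sc, g in sub.loc[sub["outcome"] == outcome].groupby("scenario"):
            ax.errorbar(
                g["months"],
                100 * g["arr"],
                yerr=[100 * (g["arr"] - g["arr_lo"]), 100 * (g["arr_hi"] - g["arr"])],
                marker="o",
                capsize=3,
                label=_SCENARIO_LABELS.get(sc, sc),
            )
        ax.set_title(outcome)
        ax.set_ylabel("Projected ARR (%)")
        ax.set_xlabel("Months")
    axes.ravel()[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
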