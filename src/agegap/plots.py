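"""Optional figures: the dual-axis sweep plot and the attribution heat map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sweep import RegionReport, SweepResult

__all__ = ["plot_attribution_heatmap", "plot_sweep"]


def plot_sweep(sweep: SweepResult, regions: RegionReport, path: str | Path) -> None:
    """Effect size (left axis) and MAE (right axis) against alpha.

    Vertical dashed lines mark the accuracy-optimal (red) and
    majority-detection-optimal (blue) regularization strengths; horizontal
    dashed lines show each condition's d at those two alphas, i.e. the
    potential sensitivity gain.
    """
    fig, ax_d = plt.subplots(figsize=(8, 5))
    ax_mae = ax_d.twinx()
    d_wide = sweep.d_agg.pivot(index="alpha", columns="condition", values="mean_d")
    se_wide = sweep.d_agg.pivot(index="alpha", columns="condition", values="se_d")
    for cond in d_wide.columns:
        line = ax_d.plot(d_wide.index, d_wide[cond], label=f"d: {cond}")[0]
        se = se_wide[cond].fillna(0.0)
        ax_d.fill_between(
            d_wide.index, d_wide[cond] - se, d_wide[cond] + se, alpha=0.2, color=line.get_color()
        )
        r = regions.per_condition[cond]
        ax_d.axhline(r.d_at_mae_opt, color="red", ls=":", lw=0.8)
        ax_d.axhline(r.d_at_d_opt, color="blue", ls=":", lw=0.8)
    mae = sweep.mae_agg.set_index("alpha")
    ax_mae.plot(mae.index, mae["mean_mae"], color="red", label="MAE")
    ax_mae.fill_between(
        mae.index,
        mae["mean_mae"] - mae["se_mae"].fillna(0.0),
        mae["mean_mae"] + mae["se_mae"].fillna(0.0),
        alpha=0.2,
        color="red",
    )
    ax_d.axvline(regions.alpha_mae_opt, color="red", ls="--")
    ax_d.axvline(regions.alpha_majority_opt, color="blue", ls="--")
    ax_d.set_xscale("log")
    ax_d.set_xlabel(r"regularization strength $\alpha$")
    ax_d.set_ylabel("effect size (Cohen's d)", color="blue")
    ax_mae.set_ylabel("MAE (years)", color="red")
    ax_d.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_attribution_heatmap(table: pd.DataFrame, path: str | Path, k: int = 10) -> None:
    """Heat map of relative importance (mean |SHAP| / per-alpha max) for the
    overall top-k features across the grid."""
    top = table.mean(axis=0).sort_values(ascending=False).index[:k]
    rel = table[top].div(table.max(axis=1).replace(0.0, np.nan), axis=0).fillna(0.0)
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(rel.T.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(top)), top)
    ticks = np.linspace(0, len(table.index) - 1, 6).astype(int)
    ax.set_xticks(ticks, [f"{table.index[t]:.0e}" for t in ticks])
    ax.set_xlabel(r"regularization strength $\alpha$")
    fig.colorbar(im, ax=ax, label="relative |SHAP|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
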