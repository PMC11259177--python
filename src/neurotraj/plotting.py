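"""Static plot export: cohort density profiles and cascade heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_cohort_densities(density: pd.DataFrame, path: str | Path,
                          segmentation=None) -> None:
    """Per-cohort pseudotime density curves (pooled curve dashed), with
    optional state-boundary lines from a segmentation."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for cohort, grp in density.groupby("cohort"):
        style = dict(linestyle="--", color="black") if cohort == "pooled" else {}
        ax.plot(grp["t"], grp["density"], label=str(cohort), **style)
    if segmentation is not None:
        for v in segmentation.valleys:
            ax.axvline(v, color="grey", linestyle=":", linewidth=0.8)
    ax.set_xlabel("pseudotime (0-100)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7, title="cohort")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cascade_heatmap(heat: pd.DataFrame, path: str | Path) -> None:
    """Row-normalized per-cluster mean expression of switching TFs, rows
    ordered by switching pseudotime."""
    fig, ax = plt.subplots(figsize=(5, max(3, 0.06 * len(heat))))
    im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="viridis",
                   interpolation="nearest")
    ax.set_xticks(range(len(heat.columns)), heat.columns, rotation=45,
                  fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(heat)} switching TFs (ordered by t_switch)")
    fig.colorbar(im, ax=ax, label="row-normalized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
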