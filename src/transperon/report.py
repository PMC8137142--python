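"""Static figure rendering for result bundles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .loci import CLASS_LABELS  # noqa: E402


def scatter_with_sem(per_cell_frames: dict[str, pd.DataFrame], out_path) -> Path:
    """Per-cell fraction scatter per group with mean ± SEM bars."""
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(per_cell_frames), 3.5))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, (name, frame) in enumerate(per_cell_frames.items()):
        vals = frame["fraction"].dropna().to_numpy()
        x = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        if len(vals):
            mean = vals.mean()
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            ax.hlines(mean, i - 0.2, i + 0.2, color="k", lw=2)
            ax.vlines(i, mean - sem, mean + sem, color="k", lw=2)
    ax.set_xticks(range(len(per_cell_frames)))
    ax.set_xticklabels(list(per_cell_frames), rotation=30, ha="right")
    ax.set_ylabel("co-localized fraction per cell")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)


def enrichment_heatmap(matrix: pd.DataFrame, out_path) -> Path:
    """Heatmap of a gene x sample enrichment matrix with labels."""
    if matrix.empty:
        raise ValidationError("enrichment matrix is empty")
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.5 * matrix.shape[1], 1.0 + 0.22 * matrix.shape[0])
    )
    vmax = float(np.nanmax(np.abs(matrix.values))) or 1.0
    im = ax.imshow(matrix.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 enrichment vs control")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)


def class_histogram(summary: dict, out_path) -> Path:
    """Bar chart of locus-pair class percentages (with replicate SD if given)."""
    percent = summary.get("replicate_mean", summary["percent"])
    err = summary.get("replicate_std")
    labels = list(CLASS_LABELS)
    vals = [percent[c] for c in labels]
    errs = [err[c] for c in labels] if err else None
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(labels, vals, yerr=errs, capsize=4, color=["#444", "#888", "#ccc"])
    ax.set_ylabel("% of cells")
    ax.set_ylim(0, 100)
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
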