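"""Minimal figures: PC scatter with border lines, KM curves with censor marks."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .axis import AxisPartition, PcaResult
from .io import ClinicalRecord, clinical_index
from .survival import SurvivalFit


def plot_axis_scatter(
    pca: PcaResult,
    partitions: Sequence[AxisPartition],
    clinical: Sequence[ClinicalRecord] | None,
    path: str | Path,
    components: tuple[int, int] = (1, 2),
) -> None:
    """Scatter of two component scores with +/-border lines per partition."""
    cx, cy = components
    x = pca.component_scores(cx)
    y = pca.component_scores(cy)
    colors = "steelblue"
    if clinical is not None:
        by_sample = clinical_index(clinical)
        palette = {"light": "seagreen", "heavy": "firebrick", "unknown": "grey"}
        colors = [
            palette[by_sample[s].smoking_group if s in by_sample else "unknown"]
            for s in pca.sample_ids
        ]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, c=colors, s=28, edgecolor="k", linewidth=0.3)
    for part in partitions:
        if part.component_index == cx:
            ax.axvline(part.border, color="orange", ls="--", lw=1)
            ax.axvline(-part.border, color="orange", ls="--", lw=1)
        elif part.component_index == cy:
            ax.axhline(part.border, color="tab:blue", ls="--", lw=1)
            ax.axhline(-part.border, color="tab:blue", ls="--", lw=1)
    ax.set_xlabel(f"PC{cx} ({100 * pca.explained_fraction[cx - 1]:.1f}%)")
    ax.set_ylabel(f"PC{cy} ({100 * pca.explained_fraction[cy - 1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(fit: SurvivalFit, path: str | Path) -> None:
    """Step curves per group; censored samples marked with crosses."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    colors = {"inside": "tab:blue", "outside": "tab:red"}
    for name, curve in fit.km_curves.items():
        ax.step(
            curve["time"], curve["survival"], where="post",
            label=f"{name} (n={fit.n_per_group.get(name, '?')})",
            color=colors.get(name),
        )
    if fit.logrank_p is not None:
        ax.text(0.62, 0.92, f"log-rank p = {fit.logrank_p:.3g}", transform=ax.transAxes)
    ax.set_xlabel("time (days)")
    ax.set_ylabel(f"{fit.endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
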