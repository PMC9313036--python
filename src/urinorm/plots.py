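"""Heat maps and forest-style association plots (pure views of results)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .correlations import CorrelationResult
from .regression import records_to_frame


def correlation_heatmap(result: CorrelationResult, path, title: str | None = None):
    """Render a correlation map with a diverging scale anchored at 0."""
    ordered = result.ordered_matrix()
    fig, ax = plt.subplots(figsize=(0.22 * len(ordered) + 2,) * 2)
    im = ax.imshow(ordered.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(ordered)), ordered.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=5)
    ax.set_title(title or f"{result.scheme} "
                 f"({'adjusted: ' + ', '.join(result.adjusted_for) if result.adjusted_for else 'unadjusted'})",
                 fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.7, label="Spearman rho")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def forest_plot(records, outcome: str, path, sex_adjusted: bool = True):
    """Dot-and-whisker plot of SD-unit betas per metabolite, grouped by scheme."""
    frame = records_to_frame(records)
    frame = frame[(frame["outcome"] == outcome) & (frame["sex_adjusted"] == sex_adjusted)]
    if frame.empty:
        raise ValueError(f"no records for outcome {outcome!r}")
    metabolites = sorted(frame["metabolite"].unique())
    schemes = list(dict.fromkeys(frame["scheme"]))
    fig, ax = plt.subplots(figsize=(6, 0.28 * len(metabolites) + 1.5))
    cmap = plt.get_cmap("tab10")
    for k, scheme in enumerate(schemes):
        sub = frame[frame["scheme"] == scheme].set_index("metabolite")
        y = np.array([metabolites.index(m) for m in sub.index], dtype=float)
        offset = (k - (len(schemes) - 1) / 2) / (len(schemes) + 2)
        ax.errorbar(sub["beta"], y + offset, xerr=1.96 * sub["se"], fmt="o",
                    ms=2.5, lw=0.7, color=cmap(k % 10), label=scheme)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(metabolites)), metabolites, fontsize=6)
    ax.set_xlabel(f"{outcome} association (SD units)")
    ax.legend(fontsize=6, ncol=2)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
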