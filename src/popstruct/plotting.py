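"""Basic figures: ancestry barplot ordered by longitude, PCA scatter by region."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pca_cluster import PCAFit
from .vcf_io import SampleTable

_REGION_COLORS = {"western": "#1b9e77", "central": "#d95f02",
                  "eastern": "#7570b3", "west_virginia": "#e7298a"}


def admixture_barplot(Q: np.ndarray, st: SampleTable, path,
                      sample_ids=None) -> None:
    """Stacked ancestry proportions, individuals sorted west to east."""
    tbl = st.table
    if sample_ids is not None:
        tbl = tbl.set_index("sample_id").loc[list(sample_ids)].reset_index()
    order = np.argsort(tbl["longitude"].to_numpy(), kind="stable")
    Qo = Q[order]
    fig, ax = plt.subplots(figsize=(10, 2.5))
    bottom = np.zeros(len(Qo))
    for k in range(Q.shape[1]):
        ax.bar(np.arange(len(Qo)), Qo[:, k], bottom=bottom, width=1.0,
               linewidth=0, label=f"cluster {k}")
        bottom += Qo[:, k]
    ax.set_xlim(0, len(Qo))
    ax.set_ylim(0, 1)
    ax.set_xlabel("individuals (west to east)")
    ax.set_ylabel("ancestry")
    ax.legend(fontsize=6, ncol=Q.shape[1], loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(fit: PCAFit, st: SampleTable, path, axes=(1, 2)) -> None:
    """Axis scores colored by geographic region (axes are 1-based)."""
    tbl = st.table.set_index("sample_id").loc[fit.samples]
    a, b = axes[0] - 1, axes[1] - 1
    fig, ax = plt.subplots(figsize=(5, 4))
    for region, color in _REGION_COLORS.items():
        sel = (tbl["region"] == region).to_numpy()
        if sel.any():
            ax.scatter(fit.scores[sel, a], fit.scores[sel, b], s=8,
                       alpha=0.7, color=color, label=region, linewidths=0)
    ax.set_xlabel(f"PC{axes[0]}")
    ax.set_ylabel(f"PC{axes[1]}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
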