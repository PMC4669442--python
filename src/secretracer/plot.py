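"""Heat-map and model-selection plots for reporter activity."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_activity_heatmap", "plot_gap_curves"]


def plot_activity_heatmap(model, path) -> None:
    """Reporter x timepoint mean-activity heat map, rows grouped by
    cluster rank (most active cluster on top)."""
    feats = model.features
    order = (
        model.assignments()
        .assign(activity=feats.mean(axis=1))
        .sort_values(["cluster_rank", "activity"], ascending=[True, False])
        .index
    )
    mat = feats.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(mat))))
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]), [f"{t:g}h" for t in mat.columns])
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    ax.set_xlabel("time")
    fig.colorbar(im, ax=ax, label="normalized log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gap_curves(model, path) -> None:
    """SSE, permuted-null SSE and their gap against k."""
    ks = sorted(model.sse)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.plot(ks, [model.sse[k] for k in ks], "o-", label="SSE(k)")
    ax1.plot(ks, [model.sse_perm[k] for k in ks], "s--", label="null SSE(k)")
    ax1.set_xlabel("k")
    ax1.set_ylabel("within-cluster SSE")
    ax1.legend()
    gap = model.gap
    ax2.plot(ks, [gap[k] for k in ks], "o-")
    ax2.axvline(model.k, color="red", ls=":", label=f"chosen k={model.k}")
    ax2.set_xlabel("k")
    ax2.set_ylabel("gap = null SSE - SSE")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
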