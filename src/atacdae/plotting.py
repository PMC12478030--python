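"""Optional figures for benchmark reports (matplotlib imported lazily).

Scoring never depends on these; UMAP in particular is only used here, for
2D embedding plots, never for any metric.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import EvalReport

__all__ = ["plot_library_sizes", "plot_embedding", "plot_confusion"]


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_library_sizes(report: EvalReport, path: str | Path) -> Path:
    """Scatter of per-cell library size, ground truth vs imputed."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(report.library_truth, report.library_imputed, s=6, alpha=0.5)
    lim = max(report.library_truth.max(), report.library_imputed.max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel("ground-truth library size")
    ax.set_ylabel("imputed library size")
    ax.set_title(f"r = {report.library_correlation:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_embedding(values, labels: np.ndarray, path: str | Path,
                   method: str = "pca", seed: int = 0) -> Path:
    """2D embedding of cells (PCA, or PCA followed by UMAP), colored by
    population."""
    from sklearn.decomposition import PCA
    import scipy.sparse as sp

    X = values.toarray().T if sp.issparse(values) else np.asarray(values).T
    n_comp = min(50, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if method == "umap":
        from umap import UMAP  # deliberately local: plotting-only dependency
        emb = UMAP(n_components=2, random_state=seed).fit_transform(emb)
    elif method != "pca":
        raise ValueError(f"method must be 'pca' or 'umap', got {method!r}")

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for t in np.unique(labels):
        sel = labels == t
        ax.scatter(emb[sel, 0], emb[sel, 1], s=8, label=str(t), alpha=0.7)
    ax.legend(title="population", fontsize=7, markerscale=1.5)
    ax.set_xlabel(f"{method.upper()} 1")
    ax.set_ylabel(f"{method.upper()} 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_confusion(report: EvalReport, path: str | Path) -> Path:
    """Heatmap of the Hungarian-matched population/cluster confusion."""
    plt = _pyplot()
    conf = report.confusion
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(conf, cmap="Blues")
    for (i, j), v in np.ndenumerate(conf):
        ax.text(j, i, str(v), ha="center", va="center", fontsize=8,
                color="black" if v < conf.max() * 0.6 else "white")
    ax.set_xlabel("matched cluster")
    ax.set_ylabel("population")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
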