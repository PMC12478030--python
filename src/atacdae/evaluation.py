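"""Evaluation metrics for the imputation benchmark.

Covers per-cell mean squared error (count and normalized scales), meta-cell
distance (one minus the Pearson correlation between a cell's imputed vector
and the per-peak average of its population's ground-truth cells), K-means
clustering indices (ARI/NMI/AMI against labels, silhouette label-free in PCA
space), the Hungarian-matched confusion matrix, per-cell library sizes, and
the dropout-zero / biological-zero separation statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             normalized_mutual_info_score, silhouette_score)

from .preprocess import CorruptionRecord

__all__ = [
    "EvalReport",
    "per_cell_mse",
    "meta_cell_distance",
    "cluster_and_score",
    "hungarian_confusion",
    "library_size_table",
    "zero_separation",
    "evaluate",
]


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


@dataclass
class EvalReport:
    """All benchmark metrics for one imputation run."""

    per_cell_mse_counts: np.ndarray
    per_cell_mse_normalized: np.ndarray | None
    meta_cell_distances: np.ndarray
    meta_cell_distance_by_type: dict[int, float]
    ari: float
    nmi: float
    ami: float
    sc: float
    confusion: np.ndarray
    confusion_assignment: np.ndarray
    library_truth: np.ndarray
    library_imputed: np.ndarray
    library_correlation: float
    recovery_pct: float | None
    retention_pct: float | None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_mse_counts": float(np.mean(self.per_cell_mse_counts)),
            "mean_mse_normalized": (
                float(np.mean(self.per_cell_mse_normalized))
                if self.per_cell_mse_normalized is not None else None),
            "mean_meta_cell_distance": float(np.mean(self.meta_cell_distances)),
            "meta_cell_distance_by_type": {
                str(k): v for k, v in self.meta_cell_distance_by_type.items()},
            "ari": self.ari, "nmi": self.nmi, "ami": self.ami, "sc": self.sc,
            "confusion": self.confusion.tolist(),
            "confusion_assignment": self.confusion_assignment.tolist(),
            "library_correlation": self.library_correlation,
            "recovery_pct": self.recovery_pct,
            "retention_pct": self.retention_pct,
            "config": self.config,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def save_tables(self, directory: str | Path) -> Path:
        """Write the per-cell metrics as a TSV alongside the JSON report."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = {
            "mse_counts": self.per_cell_mse_counts,
            "meta_cell_distance": self.meta_cell_distances,
            "library_truth": self.library_truth,
            "library_imputed": self.library_imputed,
        }
        if self.per_cell_mse_normalized is not None:
            cols["mse_normalized"] = self.per_cell_mse_normalized
        pd.DataFrame(cols).to_csv(directory / "per_cell_metrics.tsv",
                                  sep="\t", index_label="cell_index")
        return directory


def per_cell_mse(truth, imputed) -> np.ndarray:
    """Mean over peaks of the squared error, one value per cell."""
    t, p = _dense(truth), _dense(imputed)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return np.mean((t - p) ** 2, axis=0)


def meta_cell_distance(imputed, truth, labels: np.ndarray,
                       metric: str = "pearson") -> np.ndarray:
    """Per-cell distance to its population's ground-truth meta-cell.

    The meta-cell of population t is the per-peak mean of the ground-truth
    vectors of the cells in t. The default distance is 1 - Pearson
    correlation (affine invariant); ``metric='euclidean'`` is offered as an
    alternative. A constant (zero-variance) vector has distance 1 by
    convention under the Pearson metric.
    """
    imp, tru = _dense(imputed), _dense(truth)
    labels = np.asarray(labels)
    if imp.shape != tru.shape:
        raise ValueError(f"shape mismatch: {imp.shape} vs {tru.shape}")
    if len(labels) != imp.shape[1]:
        raise ValueError("labels must cover all cells")
    out = np.empty(imp.shape[1])
    metas = {t: tru[:, labels == t].mean(axis=1) for t in np.unique(labels)}
    for j in range(imp.shape[1]):
        meta = metas[labels[j]]
        v = imp[:, j]
        if metric == "euclidean":
            out[j] = np.linalg.norm(v - meta)
            continue
        sv, sm = v.std(), meta.std()
        if sv == 0 or sm == 0:
            out[j] = 1.0
        else:
            out[j] = 1.0 - float(np.corrcoef(v, meta)[0, 1])
    return out


def cluster_and_score(imputed, labels: np.ndarray, k: int | None = None,
                      seed: int = 0, n_components: int = 50
                      ) -> tuple[float, float, float, float]:
    """PCA + K-means on cells, scored as (ARI, NMI, AMI, silhouette).

    ARI/NMI/AMI compare clusters with the given labels; the silhouette is
    label-free, computed in PCA space against the K-means clusters.
    """
    X = _dense(imputed).T  # cells x peaks
    labels = np.asarray(labels)
    n = X.shape[0]
    k = k if k is not None else len(np.unique(labels))
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    n_comp = min(n_components, n - 1, X.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    clusters = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    ari = adjusted_rand_score(labels, clusters)
    nmi = normalized_mutual_info_score(labels, clusters)
    ami = adjusted_mutual_info_score(labels, clusters)
    sc = silhouette_score(emb, clusters) if len(np.unique(clusters)) > 1 else 0.0
    return float(ari), float(nmi), float(ami), float(sc)


def hungarian_confusion(labels: np.ndarray, clusters: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Contingency matrix with columns permuted to maximize the diagonal.

    Returns ``(confusion, assignment)`` where ``assignment[i]`` is the
    cluster matched to population i by the Hungarian algorithm.
    """
    labels, clusters = np.asarray(labels), np.asarray(clusters)
    if labels.shape != clusters.shape:
        raise ValueError("labels and clusters must have the same length")
    q = int(labels.max()) + 1
    kc = int(clusters.max()) + 1
    size = max(q, kc)
    cont = np.zeros((size, size), dtype=np.int64)
    np.add.at(cont, (labels, clusters), 1)
    row, col = linear_sum_assignment(cont, maximize=True)
    assignment = np.empty(size, dtype=np.int64)
    assignment[row] = col
    return cont[:, assignment][:q, :kc], assignment[:q]


def library_size_table(truth, imputed) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell column sums on the count scale and their Pearson correlation."""
    t, p = _dense(truth), _dense(imputed)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    ts, ps = t.sum(axis=0), p.sum(axis=0)
    if ts.std() == 0 or ps.std() == 0:
        corr = 1.0 if np.allclose(ts, ps) else 0.0
    else:
        corr = float(np.corrcoef(ts, ps)[0, 1])
    return ts, ps, corr


def zero_separation(truth, corruption: CorruptionRecord, imputed_counts,
                    threshold: float = 0.5) -> tuple[float, float]:
    """Dropout-zero recovery and biological-zero retention percentages.

    Dropout zeros are the artificially masked positions (nonzero in the
    ground truth, zeroed in the corrupted matrix); biological zeros are the
    positions already zero in the ground truth. A dropout zero is recovered
    when its imputed count is >= ``threshold``; a biological zero is retained
    when its imputed count stays < ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = sp.csr_matrix(truth.X if hasattr(truth, "X") else truth)
    imp = _dense(imputed_counts)
    rows, cols = corruption.mask_rows, corruption.mask_cols
    if len(rows) == 0:
        raise ValueError("corruption record has an empty mask")
    masked_truth = np.asarray(t[rows, cols]).ravel()
    if np.any(masked_truth == 0):
        raise ValueError("mask refers to positions that are zero in the truth")

    recovery = 100.0 * float(np.mean(imp[rows, cols] >= threshold))
    bio = np.asarray(~(t != 0).todense())
    retention = 100.0 * float(np.mean(imp[bio] < threshold))
    return recovery, retention


def evaluate(truth, imputed_counts, labels: np.ndarray,
             imputed_normalized=None, truth_normalized=None,
             corruption: CorruptionRecord | None = None,
             threshold: float = 0.5, seed: int = 0,
             config: dict | None = None) -> EvalReport:
    """Assemble the full metric report for one run."""
    labels = np.asarray(labels)
    mse_counts = per_cell_mse(truth.X if hasattr(truth, "X") else truth,
                              imputed_counts)
    mse_norm = None
    if imputed_normalized is not None and truth_normalized is not None:
        tn = (truth_normalized.values if hasattr(truth_normalized, "values")
              else truth_normalized)
        mse_norm = per_cell_mse(tn, imputed_normalized)

    cluster_input = imputed_normalized if imputed_normalized is not None \
        else imputed_counts
    dist = meta_cell_distance(cluster_input,
                              tn if mse_norm is not None else
                              (truth.X if hasattr(truth, "X") else truth),
                              labels)
    by_type = {int(t): float(np.mean(dist[labels == t]))
               for t in np.unique(labels)}

    ari, nmi, ami, sc = cluster_and_score(cluster_input, labels, seed=seed)
    X = _dense(cluster_input).T
    n_comp = min(50, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    clusters = KMeans(n_clusters=len(np.unique(labels)), n_init=10,
                      random_state=seed).fit_predict(emb)
    confusion, assignment = hungarian_confusion(labels, clusters)

    ts, ps, corr = library_size_table(truth.X if hasattr(truth, "X") else truth,
                                      imputed_counts)
    recovery = retention = None
    if corruption is not None:
        recovery, retention = zero_separation(truth, corruption, imputed_counts,
                                              threshold=threshold)
    return EvalReport(
        per_cell_mse_counts=mse_counts,
        per_cell_mse_normalized=mse_norm,
        meta_cell_distances=dist,
        meta_cell_distance_by_type=by_type,
        ari=ari, nmi=nmi, ami=ami, sc=sc,
        confusion=confusion, confusion_assignment=assignment,
        library_truth=ts, library_imputed=ps, library_correlation=corr,
        recovery_pct=recovery, retention_pct=retention,
        config=config or {})
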