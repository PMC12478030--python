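"""Normalization, outlier handling, and the artificial-masking operator.

Normalization puts every peak on a common [0, 1] scale:

    X_ij = log2(X'_ij + 1) / max_j log2(X'_ij + 1)

with the maximum taken per peak across cells. The per-peak denominators are
kept so the transform can be inverted exactly on the observed support
(``denormalize``). Peaks whose maximum is 0 map to all-zero rows with a
zero denominator. Because zero counts map to zero, normalized matrices stay
sparse.

``mask_corrupt`` zeroes, for each cell with k nonzero entries, exactly
round(rate * k) of them chosen uniformly without replacement. The same
operator serves two roles: a fixed-seed benchmark corruption that simulates
dropout events, and the per-epoch training corruption of the denoising
autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import PeakMatrix

__all__ = ["NormalizedMatrix", "CorruptionRecord", "cap_outliers", "normalize",
           "denormalize", "mask_corrupt", "write_mask", "read_mask"]


@dataclass
class NormalizedMatrix:
    """Log-scaled peak-by-cell values in [0, 1] plus per-peak denominators."""

    values: sp.csr_matrix            # peaks x cells, float64 in [0, 1]
    peak_denominators: np.ndarray    # per-peak max_j log2(X'_ij + 1)
    peak_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CorruptionRecord:
    """An artificially masked matrix plus the positions that were zeroed."""

    corrupted: "NormalizedMatrix | PeakMatrix"
    mask_rows: np.ndarray            # peak indices of masked entries
    mask_cols: np.ndarray            # cell indices of masked entries
    rate: float
    seed: int

    @property
    def n_masked(self) -> int:
        return len(self.mask_rows)


def cap_outliers(matrix: PeakMatrix, percentile: float = 99.9) -> PeakMatrix:
    """Winsorize extreme counts at the given percentile of nonzero entries.

    Entries above the threshold are capped to it (shape is preserved; nothing
    is deleted). Idempotent.
    """
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    X = sp.csr_matrix(matrix.X, copy=True)
    if X.nnz == 0:
        raise ValueError("cannot cap outliers of an all-zero matrix")
    # 'lower' keeps the threshold an actually observed count, so integer
    # matrices stay integer and the operation is idempotent
    threshold = np.percentile(X.data, percentile, method="lower")
    X.data = np.minimum(X.data, threshold)
    return PeakMatrix(X=X, peak_ids=list(matrix.peak_ids),
                      cell_ids=list(matrix.cell_ids))


def normalize(matrix: PeakMatrix) -> NormalizedMatrix:
    """Per-peak log-scale normalization into [0, 1]."""
    X = matrix.X.tocsr()
    if X.nnz and X.data.min() < 0:
        raise ValueError("negative entries cannot be normalized")
    logged = X.astype(np.float64)
    logged.data = np.log2(logged.data + 1.0)
    denom = np.asarray(logged.max(axis=1).todense()).ravel()
    scale = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
    norm = sp.csr_matrix(sp.diags(scale) @ logged, dtype=np.float64)
    return NormalizedMatrix(values=norm, peak_denominators=denom,
                            peak_ids=list(matrix.peak_ids),
                            cell_ids=list(matrix.cell_ids))


def denormalize(values: "NormalizedMatrix | np.ndarray",
                peak_denominators: np.ndarray | None = None) -> np.ndarray:
    """Invert the normalization: count = 2^(value * denominator) - 1.

    Accepts either a :class:`NormalizedMatrix` or a dense (peaks x cells)
    array together with the per-peak denominators. Returns a dense float
    array; exact inverse on the observed support.
    """
    if isinstance(values, NormalizedMatrix):
        dense = values.values.toarray()
        denom = values.peak_denominators
    else:
        dense = np.asarray(values, dtype=np.float64)
        denom = peak_denominators
    if denom is None:
        raise ValueError("peak denominators are required to denormalize")
    denom = np.asarray(denom, dtype=np.float64).reshape(-1, 1)
    if dense.shape[0] != denom.shape[0]:
        raise ValueError(
            f"denominator length {denom.shape[0]} does not match {dense.shape[0]} peaks")
    return np.exp2(dense * denom) - 1.0


def mask_corrupt(matrix: "NormalizedMatrix | PeakMatrix", rate: float,
                 seed: int = 0) -> CorruptionRecord:
    """Zero exactly round(rate * k) of each cell's k nonzero entries.

    Positions are sampled uniformly without replacement per cell; already-zero
    entries are never masked, so the corrupted matrix plus the mask exactly
    reconstructs the source.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"masking rate must be in [0, 1), got {rate}")
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix.X
    csc = values.tocsc()
    rng = np.random.default_rng(seed)

    mask_rows, mask_cols = [], []
    kill = np.zeros(csc.nnz, dtype=bool)
    for j in range(csc.shape[1]):
        start, end = csc.indptr[j], csc.indptr[j + 1]
        k = end - start
        n_mask = int(round(rate * k))
        if n_mask == 0:
            continue
        chosen = rng.choice(k, size=n_mask, replace=False)
        kill[start + chosen] = True
        mask_rows.append(csc.indices[start + chosen])
        mask_cols.append(np.full(n_mask, j, dtype=np.int64))

    data = csc.data.copy()
    data[kill] = 0
    corrupted_values = sp.csc_matrix((data, csc.indices.copy(), csc.indptr.copy()),
                                     shape=csc.shape)
    corrupted_values.eliminate_zeros()
    corrupted_values = corrupted_values.tocsr()

    rows = np.concatenate(mask_rows) if mask_rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(mask_cols) if mask_cols else np.empty(0, dtype=np.int64)

    if isinstance(matrix, NormalizedMatrix):
        corrupted: NormalizedMatrix | PeakMatrix = NormalizedMatrix(
            values=corrupted_values.astype(np.float64),
            peak_denominators=matrix.peak_denominators.copy(),
            peak_ids=list(matrix.peak_ids), cell_ids=list(matrix.cell_ids))
    else:
        corrupted = PeakMatrix(X=corrupted_values.astype(matrix.X.dtype),
                               peak_ids=list(matrix.peak_ids),
                               cell_ids=list(matrix.cell_ids))
    return CorruptionRecord(corrupted=corrupted, mask_rows=rows, mask_cols=cols,
                            rate=rate, seed=seed)


def write_mask(record: CorruptionRecord, path: str | Path) -> Path:
    """Serialize masked positions as TSV of 0-based (peak_index, cell_index)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r, c in zip(record.mask_rows, record.mask_cols):
            fh.write(f"{r}\t{c}\n")
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                r, c = line.split("\t")
                rows.append(int(r))
                cols.append(int(c))
    return np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64)
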