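"""Reading and writing peak-by-cell matrices and sidecar metadata.

On disk a dataset is a directory holding ``matrix.mtx`` (MatrixMarket
coordinate format, 1-based indices), ``peaks.bed`` (BED3, 0-based half-open)
and ``barcodes.tsv`` (one barcode per line); a dense CSV with peak ids as the
index and barcodes as columns is accepted for tiny fixtures. Population
labels live in a two-column TSV ``barcode<TAB>label``. All readers accept
gzip-compressed files transparently. Matrices are oriented peaks x cells
internally.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["PeakMatrix", "CellLabels", "read_matrix", "write_matrix",
           "read_labels", "write_labels"]


class FormatError(ValueError):
    """Raised when an on-disk matrix or sidecar violates the format contract."""


def _open_text(path: Path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class PeakMatrix:
    """Sparse nonnegative peak-by-cell count matrix with ids attached."""

    X: sp.csr_matrix                      # peaks x cells
    peak_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        m, n = self.X.shape
        if m < 1 or n < 1:
            raise FormatError(f"matrix must be at least 1x1, got {self.X.shape}")
        if not self.peak_ids:
            self.peak_ids = [f"chrS:{i * 500}-{i * 500 + 500}" for i in range(m)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{j:05d}" for j in range(n)]
        if len(self.peak_ids) != m:
            raise FormatError(f"{len(self.peak_ids)} peak ids for {m} peaks")
        if len(self.cell_ids) != n:
            raise FormatError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if len(set(self.cell_ids)) != n:
            raise FormatError("cell barcodes are not unique")
        if len(set(self.peak_ids)) != m:
            raise FormatError("peak ids are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_peaks(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


@dataclass
class CellLabels:
    """Integer population assignment per cell, factorized 0..q-1."""

    assignments: np.ndarray
    population_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.ndim != 1:
            raise ValueError("assignments must be one-dimensional")
        if self.assignments.size and self.assignments.min() < 0:
            raise ValueError("negative population index")
        if self.population_names is not None:
            if self.assignments.size and self.assignments.max() >= len(self.population_names):
                raise ValueError("population index out of range of names")

    @property
    def q(self) -> int:
        if self.population_names is not None:
            return len(self.population_names)
        return int(self.assignments.max()) + 1 if self.assignments.size else 0

    def __len__(self) -> int:
        return len(self.assignments)


def _parse_bed(path: Path) -> list[str]:
    ids = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with <3 fields in {path}: {line!r}")
            ids.append(f"{parts[0]}:{parts[1]}-{parts[2]}")
    return ids


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_matrix(path: str | Path, format: str | None = None,
                peaks_path: str | Path | None = None,
                barcodes_path: str | Path | None = None,
                integer: bool = True) -> PeakMatrix:
    """Read a peak-by-cell matrix from MTX (+ sidecars) or dense CSV.

    ``path`` may be a dataset directory containing ``matrix.mtx[.gz]`` or a
    direct path to the matrix file. Format is inferred from the suffix when
    not given. Raw count matrices are integer; pass ``integer=False`` for
    real-valued (e.g. imputed) matrices.
    """
    path = Path(path)
    if path.is_dir():
        for cand in ("matrix.mtx", "matrix.mtx.gz", "matrix.csv", "matrix.csv.gz"):
            if (path / cand).exists():
                return read_matrix(path / cand, format=format,
                                   peaks_path=peaks_path,
                                   barcodes_path=barcodes_path, integer=integer)
        raise FileNotFoundError(f"no matrix.mtx or matrix.csv under {path}")
    if not path.exists():
        raise FileNotFoundError(path)

    stem = path.name.removesuffix(".gz")
    fmt = format or ("mtx" if stem.endswith(".mtx") else
                     "csv" if stem.endswith(".csv") else None)
    if fmt not in ("mtx", "csv"):
        raise FormatError(f"cannot infer format of {path}; pass format='mtx'|'csv'")

    if fmt == "mtx":
        with _open_text(path, "rb" if str(path).endswith(".gz") else "r") as fh:
            mat = mmread(fh)
        X = sp.csr_matrix(mat)
        if X.nnz and np.any(X.data < 0):
            raise FormatError(f"negative entries in {path}")
        if integer:
            if X.nnz and not np.allclose(X.data, np.round(X.data)):
                raise FormatError(f"non-integer entries in {path}")
            X = X.astype(np.int64)
        directory = path.parent
        peaks_path = Path(peaks_path) if peaks_path else _first_existing(
            directory, ("peaks.bed", "peaks.bed.gz"))
        barcodes_path = Path(barcodes_path) if barcodes_path else _first_existing(
            directory, ("barcodes.tsv", "barcodes.tsv.gz"))
        peak_ids = _parse_bed(peaks_path) if peaks_path else []
        cell_ids = _read_lines(barcodes_path) if barcodes_path else []
        return PeakMatrix(X=X, peak_ids=peak_ids, cell_ids=cell_ids)

    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if np.any(values < 0):
        raise FormatError(f"negative entries in {path}")
    if integer:
        if not np.allclose(values, np.round(values)):
            raise FormatError(f"non-integer entries in {path}")
        values = values.astype(np.int64)
    return PeakMatrix(X=sp.csr_matrix(values),
                      peak_ids=[str(i) for i in df.index],
                      cell_ids=[str(c) for c in df.columns])


def _first_existing(directory: Path, names: tuple[str, ...]) -> Path | None:
    for name in names:
        if (directory / name).exists():
            return directory / name
    return None


def _peak_to_bed(peak_id: str, index: int) -> tuple[str, int, int]:
    try:
        chrom, span = peak_id.rsplit(":", 1)
        start, end = span.split("-")
        return chrom, int(start), int(end)
    except ValueError:
        # synthetic coordinates for ids that are not chrom:start-end
        return "chrS", index * 500, index * 500 + 500


def write_matrix(matrix: PeakMatrix, path: str | Path, format: str = "mtx") -> Path:
    """Write a dataset directory (mtx + peaks.bed + barcodes.tsv) or a CSV.

    MTX entries are written column-major with 1-based indices; round-trips
    through :func:`read_matrix` are exact.
    """
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        coo = matrix.X.tocsc().tocoo()  # column-major entry order
        with open(path / "matrix.mtx", "wb") as fh:
            mmwrite(fh, coo, field="integer"
                    if np.issubdtype(matrix.X.dtype, np.integer) else "real")
        with open(path / "peaks.bed", "w") as fh:
            for i, pid in enumerate(matrix.peak_ids):
                chrom, start, end = _peak_to_bed(pid, i)
                fh.write(f"{chrom}\t{start}\t{end}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
        return path
    if format == "csv":
        if path.suffix != ".csv":
            path = path / "matrix.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(matrix.X.toarray(), index=matrix.peak_ids,
                          columns=matrix.cell_ids)
        df.to_csv(path)
        return path
    raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path, cell_ids: list[str] | None = None) -> CellLabels:
    """Read barcode<TAB>label pairs, factorized in first-appearance order.

    When ``cell_ids`` is given, rows are aligned to that order; unknown or
    missing barcodes are an error, as are duplicates.
    """
    path = Path(path)
    rows = [line.split("\t") for line in _read_lines(path)]
    bad = [r for r in rows if len(r) != 2]
    if bad:
        raise FormatError(f"labels file {path} must be barcode<TAB>label")
    barcodes = [r[0] for r in rows]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcodes in {path}")
    label_strs = [r[1] for r in rows]
    codes, uniques = pd.factorize(np.asarray(label_strs, dtype=object))

    if cell_ids is not None:
        index = {b: i for i, b in enumerate(barcodes)}
        missing = [b for b in cell_ids if b not in index]
        if missing:
            raise FormatError(f"barcodes missing from {path}: {missing[:5]}")
        unknown = set(barcodes) - set(cell_ids)
        if unknown:
            raise FormatError(f"unknown barcodes in {path}: {sorted(unknown)[:5]}")
        codes = np.asarray([codes[index[b]] for b in cell_ids])
    return CellLabels(assignments=np.asarray(codes),
                      population_names=[str(u) for u in uniques])


def write_labels(labels: CellLabels, cell_ids: list[str], path: str | Path) -> Path:
    path = Path(path)
    names = labels.population_names or [str(i) for i in range(labels.q)]
    with open(path, "w") as fh:
        for barcode, code in zip(cell_ids, labels.assignments):
            fh.write(f"{barcode}\t{names[code]}\n")
    return path
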