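"""Dual-task optimization loop.

Each epoch draws a fresh corruption mask per batch (masking a fraction of
every cell's nonzero entries), runs the corrupted vectors through the
network, and minimizes the uncertainty-weighted sum of the reconstruction
loss (against the uncorrupted vectors) and the classification loss with
Adam, which also updates the two log task variances. Early stopping watches
the validation total; the best-validation parameters are restored before
returning.

When population labels are unavailable, :func:`derive_labels` provides the
clustering fallback: PCA followed by seeded K-means on the cells.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import CellLabels
from .model import (ImputerNetwork, ModelConfig, build_network, ce_loss,
                    combined_loss, mse_loss)
from .nn import Adam
from .preprocess import NormalizedMatrix

__all__ = ["TrainConfig", "TrainHistory", "fit", "derive_labels"]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    early_stop_patience: int = 10
    seed: int = 0
    deterministic_mode: bool = True   # all randomness is Generator-seeded
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if not 0.0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5]")


@dataclass
class TrainHistory:
    """Per-epoch loss components; lengths are all equal."""

    l_mse: list[float] = field(default_factory=list)
    l_ce: list[float] = field(default_factory=list)
    sigma1_sq: list[float] = field(default_factory=list)
    sigma2_sq: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def n_epochs(self) -> int:
        return len(self.total)


def _batch_dense(csc, cols: np.ndarray) -> np.ndarray:
    """Densify a set of cells (columns) as a (batch, m) float32 array."""
    return np.ascontiguousarray(csc[:, cols].toarray().T, dtype=np.float32)


def _corrupt_batch(batch: np.ndarray, csc, cols: np.ndarray, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Zero round(rate*k) of each cell's k nonzero entries (fresh draw)."""
    out = batch.copy()
    for b, j in enumerate(cols):
        idx = csc.indices[csc.indptr[j]:csc.indptr[j + 1]]
        n_mask = int(round(rate * len(idx)))
        if n_mask:
            out[b, rng.choice(idx, size=n_mask, replace=False)] = 0.0
    return out


def fit(matrix: NormalizedMatrix, labels: CellLabels | None,
        model_cfg: ModelConfig, train_cfg: TrainConfig | None = None
        ) -> tuple[ImputerNetwork, TrainHistory]:
    """Train the dual-task network on normalized peak-by-cell data.

    ``matrix`` is peaks x cells; cells are the samples. Returns the network
    with the best-validation parameters restored, plus the loss history.
    """
    train_cfg = train_cfg or TrainConfig()
    m, n = matrix.shape
    if model_cfg.input_length == 0:
        model_cfg = dataclasses.replace(model_cfg, input_length=m)
    if model_cfg.input_length != m:
        raise ValueError(f"model expects {model_cfg.input_length} peaks, data has {m}")

    y = None
    if model_cfg.use_classifier:
        if labels is None:
            raise ValueError(
                "population labels are required when use_classifier is on; "
                "derive them with derive_labels() or disable the classifier")
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} cells")
        if labels.q != model_cfg.n_populations:
            raise ValueError(
                f"labels have {labels.q} populations, model expects "
                f"{model_cfg.n_populations}")
        y = labels.assignments

    net = build_network(model_cfg)
    opt = Adam(net.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    csc = matrix.values.tocsc()

    perm = rng.permutation(n)
    n_val = int(round(train_cfg.validation_fraction * n))
    val_cols, train_cols = perm[:n_val], perm[n_val:]
    if len(train_cols) == 0:
        raise ValueError("no training cells left after the validation split")

    history = TrainHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] | None = None
    patience_left = train_cfg.early_stop_patience

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(train_cols)
        sums = {"mse": 0.0, "ce": 0.0, "n": 0}
        for start in range(0, len(order), train_cfg.batch_size):
            cols = order[start:start + train_cfg.batch_size]
            target = _batch_dense(csc, cols)
            if model_cfg.use_masking and model_cfg.train_mask_rate > 0:
                xin = _corrupt_batch(target, csc, cols, model_cfg.train_mask_rate, rng)
            else:
                xin = target
            recon, probs = net.forward(xin, train=True)

            b = len(cols)
            l_mse = mse_loss(recon, target)
            opt.zero_grad()
            if model_cfg.use_classifier:
                yb = y[cols]
                l_ce = ce_loss(probs, yb)
                s1 = float(net.s1.value)
                s2 = float(net.s2.value)
                drecon = (np.exp(-s1) * 2.0 / b) * (recon - target)
                onehot = np.zeros_like(probs)
                onehot[np.arange(b), yb] = 1.0
                dlogits = (np.exp(-s2) / b) * (probs - onehot)
                net.s1.grad += np.float32(-np.exp(-s1) * l_mse + 1.0)
                net.s2.grad += np.float32(-np.exp(-s2) * l_ce + 1.0)
                net.backward(drecon.astype(np.float32), dlogits.astype(np.float32))
            else:
                l_ce = 0.0
                net.backward(((2.0 / b) * (recon - target)).astype(np.float32))
            if not np.isfinite(l_mse) or not np.isfinite(l_ce):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (L_MSE={l_mse}, L_CE={l_ce})")
            opt.step()
            sums["mse"] += l_mse * b
            sums["ce"] += l_ce * b
            sums["n"] += b

        ep_mse = sums["mse"] / sums["n"]
        ep_ce = sums["ce"] / sums["n"]
        s1 = float(net.s1.value)
        s2 = float(net.s2.value)
        if model_cfg.use_classifier:
            state = combined_loss(ep_mse, ep_ce, s1, s2)
            ep_total = state.total
        else:
            ep_total = ep_mse

        val_total = _validation_total(net, csc, val_cols, y, model_cfg) \
            if n_val else ep_total
        history.l_mse.append(ep_mse)
        history.l_ce.append(ep_ce)
        history.sigma1_sq.append(float(np.exp(s1)))
        history.sigma2_sq.append(float(np.exp(s2)))
        history.total.append(ep_total)
        history.val_total.append(val_total)
        if train_cfg.verbose:
            print(f"epoch {epoch + 1}/{train_cfg.epochs} "
                  f"L_MSE={ep_mse:.4f} L_CE={ep_ce:.4f} val={val_total:.4f}",
                  file=sys.stderr)

        if val_total < best_val - 1e-12:
            best_val = val_total
            history.best_epoch = epoch
            best_state = {p.name: p.value.copy() for p in net.params()}
            best_bn = [(bn.running_mean.copy(), bn.running_var.copy())
                       for bn in net._batchnorms()]
            patience_left = train_cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_state is not None:
        for p in net.params():
            p.value = best_state[p.name]
        for bn, (mean, var) in zip(net._batchnorms(), best_bn):
            bn.running_mean, bn.running_var = mean, var
    return net, history


def _validation_total(net: ImputerNetwork, csc, val_cols: np.ndarray,
                      y: np.ndarray | None, model_cfg: ModelConfig,
                      batch_size: int = 64) -> float:
    l_mse_sum = l_ce_sum = 0.0
    for start in range(0, len(val_cols), batch_size):
        cols = val_cols[start:start + batch_size]
        x = _batch_dense(csc, cols)
        recon, probs = net.forward(x, train=False)
        l_mse_sum += mse_loss(recon, x) * len(cols)
        if model_cfg.use_classifier:
            l_ce_sum += ce_loss(probs, y[cols]) * len(cols)
    l_mse = l_mse_sum / len(val_cols)
    if not model_cfg.use_classifier:
        return l_mse
    l_ce = l_ce_sum / len(val_cols)
    return combined_loss(l_mse, l_ce, float(net.s1.value), float(net.s2.value)).total


def derive_labels(matrix: NormalizedMatrix, k: int, seed: int = 0) -> CellLabels:
    """Clustering fallback for missing population labels: PCA + K-means."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = matrix.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    cells = np.asarray(matrix.values.T.toarray(), dtype=np.float64)
    n_comp = min(50, n - 1, matrix.n_peaks)
    embedded = PCA(n_components=n_comp, random_state=seed).fit_transform(cells)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(embedded)
    return CellLabels(assignments=km.labels_.astype(np.int64))
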