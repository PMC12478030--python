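"""Dual-task hierarchical network for peak-count imputation.

The network couples a denoising autoencoder with a parallel multi-classifier:

* ``E_bottom`` — a stride-2 1D convolution (kernel 4) with dropout and ReLU,
  followed by a kernel-3 stride-1 channel-fusion convolution, capturing
  local detail of the normalized peak-count vector.
* ``E_top`` — the same block with the strided first layer duplicated
  (two kernel-4 stride-2 convolutions, then the fusion layer), aggregating
  local detail into coarser, more global features.
* ``D_top`` / ``D_bottom`` — mirror-symmetric decoders built from transposed
  convolutions; ``D_bottom`` consumes the channel-wise concatenation of
  ``D_top``'s upsampled output and ``E_bottom``'s output (skip connection)
  and ends in a sigmoid head so reconstructions live in [0, 1].
* classifier — flatten(top features) -> dense -> batch norm -> ReLU ->
  dense -> softmax over ``q`` cell populations.

The two task losses are combined with homoscedastic-uncertainty weighting,

    L = L_MSE / sigma1^2 + L_CE / sigma2^2 + 2 log sigma1 + 2 log sigma2,

where the task variances are learned as log-variances ``s_k = log sigma_k^2``
(initialized at 0) so positivity is automatic.

Variant switches: ``levels=1`` drops the top encoder/decoder pair (one-level
variant), ``levels=3`` adds a duplicated top stage with doubled channels
(three-level variant), ``use_masking=False`` disables the training-time
corruption (plain autoencoder), ``use_classifier=False`` reduces the loss to
the reconstruction term alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Adam, softmax  # re-exported for convenience

__all__ = [
    "ModelConfig",
    "LossState",
    "ImputerNetwork",
    "build_network",
    "mse_loss",
    "ce_loss",
    "combined_loss",
]

_LOG_CLAMP = 1e-12


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_length`` is the number of peaks m; inputs are zero-padded to the
    next multiple of the total stride (8 for two levels) and cropped after
    decoding. Channel widths and the classifier hidden size are deliberately
    small so the model trains in minutes on a single CPU.
    """

    input_length: int = 0
    levels: int = 2
    bottom_channels: int = 32
    top_channels: int = 64
    encoder_dropout: float = 0.1
    classifier_hidden: int = 128
    n_populations: int = 0
    train_mask_rate: float = 0.2
    use_masking: bool = True
    use_classifier: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels not in (1, 2, 3):
            raise ValueError(f"levels must be 1, 2, or 3, got {self.levels}")
        if not 0.0 <= self.encoder_dropout < 1.0:
            raise ValueError("encoder_dropout must be in [0, 1)")
        if not 0.0 <= self.train_mask_rate < 1.0:
            raise ValueError("train_mask_rate must be in [0, 1)")

    @property
    def stride_multiple(self) -> int:
        # one stride-2 stage at the bottom, two per upper level
        return 2 * 4 ** (self.levels - 1)


@dataclass
class LossState:
    """Components of the uncertainty-weighted dual-task loss."""

    l_mse: float
    l_ce: float
    sigma1_sq: float
    sigma2_sq: float
    total: float


def _pad_length(m: int, multiple: int) -> int:
    return ((m + multiple - 1) // multiple) * multiple


class ImputerNetwork:
    """Instantiated parameters and the forward/backward graph.

    Holds the encoder/decoder stacks, the classifier, and the two learnable
    log-variances; training code drives :meth:`forward` /
    :meth:`backward` and owns the optimizer.
    """

    def __init__(self, config: ModelConfig) -> None:
        if config.input_length < 16:
            raise ValueError(
                f"input_length must be >= 16 for the stride stack, got {config.input_length}")
        if config.use_classifier and config.n_populations < 2:
            raise ValueError("n_populations must be >= 2 when use_classifier is on")
        self.config = config
        self.m = config.input_length
        self.m_pad = _pad_length(self.m, config.stride_multiple)
        self.pad_left = (self.m_pad - self.m) // 2
        self.pad_right = self.m_pad - self.m - self.pad_left

        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])
        cb, ct = config.bottom_channels, config.top_channels
        p = config.encoder_dropout

        def drop() -> nn.Dropout:
            return nn.Dropout(p, rng=self._dropout_rng)

        self.e_bottom = nn.Sequential(
            nn.Conv1d(1, cb, 4, stride=2, pad=1, rng=rng, name="e_bottom.0"),
            drop(), nn.ReLU(),
            nn.Conv1d(cb, cb, 3, stride=1, pad=1, rng=rng, name="e_bottom.1"),
            nn.ReLU(),
        )
        self.e_top: nn.Sequential | None = None
        self.e_top2: nn.Sequential | None = None
        self.d_top: nn.Sequential | None = None
        self.d_top2: nn.Sequential | None = None

        if config.levels >= 2:
            self.e_top = nn.Sequential(
                nn.Conv1d(cb, ct, 4, stride=2, pad=1, rng=rng, name="e_top.0"),
                drop(), nn.ReLU(),
                nn.Conv1d(ct, ct, 4, stride=2, pad=1, rng=rng, name="e_top.1"),
                drop(), nn.ReLU(),
                nn.Conv1d(ct, ct, 3, stride=1, pad=1, rng=rng, name="e_top.2"),
                nn.ReLU(),
            )
            self.d_top = nn.Sequential(
                nn.Conv1d(ct, ct, 3, stride=1, pad=1, rng=rng, name="d_top.0"),
                nn.ReLU(),
                nn.ConvTranspose1d(ct, ct, 4, stride=2, pad=1, rng=rng, name="d_top.1"),
                nn.ReLU(),
                nn.ConvTranspose1d(ct, cb, 4, stride=2, pad=1, rng=rng, name="d_top.2"),
                nn.ReLU(),
            )
        if config.levels == 3:
            c3 = 2 * ct
            self.e_top2 = nn.Sequential(
                nn.Conv1d(ct, c3, 4, stride=2, pad=1, rng=rng, name="e_top2.0"),
                drop(), nn.ReLU(),
                nn.Conv1d(c3, c3, 4, stride=2, pad=1, rng=rng, name="e_top2.1"),
                drop(), nn.ReLU(),
                nn.Conv1d(c3, c3, 3, stride=1, pad=1, rng=rng, name="e_top2.2"),
                nn.ReLU(),
            )
            self.d_top2 = nn.Sequential(
                nn.Conv1d(c3, c3, 3, stride=1, pad=1, rng=rng, name="d_top2.0"),
                nn.ReLU(),
                nn.ConvTranspose1d(c3, c3, 4, stride=2, pad=1, rng=rng, name="d_top2.1"),
                nn.ReLU(),
                nn.ConvTranspose1d(c3, ct, 4, stride=2, pad=1, rng=rng, name="d_top2.2"),
                nn.ReLU(),
            )

        d_bottom_in = cb if config.levels == 1 else 2 * cb
        self.d_bottom = nn.Sequential(
            nn.Conv1d(d_bottom_in, cb, 3, stride=1, pad=1, rng=rng, name="d_bottom.0"),
            nn.ReLU(),
            nn.ConvTranspose1d(cb, 1, 4, stride=2, pad=1, rng=rng, name="d_bottom.1"),
            nn.Sigmoid(),
        )

        self.classifier: nn.Sequential | None = None
        if config.use_classifier:
            if config.levels == 1:
                latent_len = (self.m_pad // 2) * cb
            elif config.levels == 2:
                latent_len = (self.m_pad // 8) * ct
            else:
                latent_len = (self.m_pad // 32) * (2 * ct)
            self.classifier = nn.Sequential(
                nn.Flatten(),
                nn.Dense(latent_len, config.classifier_hidden, rng=rng, name="clf.0"),
                nn.BatchNorm1d(config.classifier_hidden),
                nn.ReLU(),
                nn.Dense(config.classifier_hidden, config.n_populations, rng=rng, name="clf.1"),
            )

        # learnable log task variances s_k = log sigma_k^2, initialized at 0
        self.s1 = nn.Param(np.zeros(()), "s1")
        self.s2 = nn.Param(np.zeros(()), "s2")
        self.dtype = np.float32
        self._cache: dict | None = None

    def astype(self, dtype) -> "ImputerNetwork":
        """Cast all parameters and the working dtype (float64 is useful for
        finite-difference gradient verification)."""
        self.dtype = dtype
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for bn in self._batchnorms():
            bn.running_mean = bn.running_mean.astype(dtype)
            bn.running_var = bn.running_var.astype(dtype)
        return self

    # ------------------------------------------------------------------ params
    def param_groups(self) -> dict[str, list[nn.Param]]:
        groups = {"e_bottom": self.e_bottom.params(), "d_bottom": self.d_bottom.params()}
        if self.e_top is not None:
            groups["e_top"] = self.e_top.params()
            groups["d_top"] = self.d_top.params()
        if self.e_top2 is not None:
            groups["e_top2"] = self.e_top2.params()
            groups["d_top2"] = self.d_top2.params()
        if self.classifier is not None:
            groups["classifier"] = self.classifier.params()
            groups["uncertainty"] = [self.s1, self.s2]
        return groups

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for group in self.param_groups().values():
            out.extend(group)
        return out

    # ----------------------------------------------------------------- forward
    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.m_pad == self.m:
            return x
        return np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))

    def forward(self, x: np.ndarray, train: bool = False
                ) -> tuple[np.ndarray, np.ndarray | None]:
        """Run a (batch, m) or (batch, 1, m) input through both task heads.

        Returns the cropped reconstruction with the same trailing length as
        the input, and the softmax class probabilities (or ``None`` without
        the classifier).
        """
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.m:
            raise ValueError(f"expected input length {self.m}, got {x.shape[2]}")
        x = self._pad(np.asarray(x, dtype=self.dtype))

        h1 = self.e_bottom.forward(x, train=train)
        latent = h1
        if self.config.levels >= 2:
            h2 = self.e_top.forward(h1, train=train)
            latent = h2
            if self.config.levels == 3:
                h3 = self.e_top2.forward(h2, train=train)
                latent = h3
                u2 = self.d_top2.forward(h3, train=train)
                u = self.d_top.forward(u2, train=train)
            else:
                u = self.d_top.forward(h2, train=train)
            cat = np.concatenate([u, h1], axis=1)
        else:
            cat = h1
        recon_pad = self.d_bottom.forward(cat, train=train)

        logits = probs = None
        if self.classifier is not None:
            logits = self.classifier.forward(latent, train=train)
            probs = softmax(logits)

        recon = recon_pad[:, 0, self.pad_left:self.pad_left + self.m]
        self._cache = {"train": train, "recon_pad_len": recon_pad.shape[2]}
        return recon, probs

    def backward(self, drecon: np.ndarray, dlogits: np.ndarray | None = None) -> None:
        """Backpropagate gradients of the loss w.r.t. the cropped
        reconstruction (batch, m) and, optionally, the classifier logits."""
        cache = self._cache
        B = drecon.shape[0]
        drecon = np.asarray(drecon, dtype=self.dtype)
        if dlogits is not None:
            dlogits = np.asarray(dlogits, dtype=self.dtype)
        dpad = np.zeros((B, 1, cache["recon_pad_len"]), dtype=self.dtype)
        dpad[:, 0, self.pad_left:self.pad_left + self.m] = drecon
        dcat = self.d_bottom.backward(dpad)
        cb = self.config.bottom_channels

        if self.config.levels >= 2:
            du, dh1_skip = dcat[:, :cb], dcat[:, cb:]
            if self.config.levels == 3:
                du2 = self.d_top.backward(du)
                dh3 = self.d_top2.backward(du2)
                if dlogits is not None:
                    dh3 = dh3 + self.classifier.backward(dlogits)
                dh2 = self.e_top2.backward(dh3)
            else:
                dh2 = self.d_top.backward(du)
                if dlogits is not None:
                    dh2 = dh2 + self.classifier.backward(dlogits)
            dh1 = self.e_top.backward(dh2) + dh1_skip
        else:
            dh1 = dcat
            if dlogits is not None:
                dh1 = dh1 + self.classifier.backward(dlogits)
        self.e_bottom.backward(dh1)

    # -------------------------------------------------------------- checkpoint
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params()}

    def save(self, path: str | Path) -> None:
        """Serialize parameters (npz) plus a JSON config echo."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.state_arrays())
        bn = self._batchnorms()
        if bn:
            np.savez(path / "running_stats.npz",
                     **{f"bn{i}.{k}": v for i, b in enumerate(bn)
                        for k, v in (("mean", b.running_mean), ("var", b.running_var))})
        (path / "config.json").write_text(json.dumps(asdict(self.config), indent=2))

    def _batchnorms(self) -> list[nn.BatchNorm1d]:
        out = []
        if self.classifier is not None:
            out = [l for l in self.classifier.layers if isinstance(l, nn.BatchNorm1d)]
        return out

    @classmethod
    def load(cls, path: str | Path) -> "ImputerNetwork":
        path = Path(path)
        cfg = ModelConfig(**json.loads((path / "config.json").read_text()))
        net = cls(cfg)
        with np.load(path / "weights.npz") as data:
            for p in net.params():
                if p.name not in data:
                    raise ValueError(f"checkpoint missing parameter {p.name!r}")
                if data[p.name].shape != p.value.shape:
                    raise ValueError(f"checkpoint shape mismatch for {p.name!r}")
                p.value = data[p.name].astype(np.float32)
        stats = path / "running_stats.npz"
        if stats.exists():
            with np.load(stats) as data:
                for i, b in enumerate(net._batchnorms()):
                    b.running_mean = data[f"bn{i}.mean"]
                    b.running_var = data[f"bn{i}.var"]
        return net


def build_network(config: ModelConfig) -> ImputerNetwork:
    """Instantiate the network described by ``config`` (seeded, deterministic)."""
    return ImputerNetwork(config)


# ------------------------------------------------------------------- losses
def mse_loss(reconstructions: np.ndarray, targets: np.ndarray) -> float:
    """Reconstruction loss: squared Euclidean norm per cell over peaks,
    averaged over cells."""
    reconstructions = np.asarray(reconstructions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if reconstructions.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: {reconstructions.shape} vs {targets.shape}")
    diff = reconstructions - targets
    return float(np.sum(diff * diff) / diff.shape[0])


def ce_loss(class_probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Multi-class cross-entropy against integer population labels,
    averaged over cells; probabilities are clamped at 1e-12."""
    probs = np.asarray(class_probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.max(initial=0) >= probs.shape[1]:
        raise ValueError("label index out of range for the probability matrix")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, _LOG_CLAMP))))


def combined_loss(l_mse: float, l_ce: float, s1: float, s2: float) -> LossState:
    """Homoscedastic-uncertainty weighting of the two task losses.

    With ``s_k = log sigma_k^2`` the total is
    ``exp(-s1) L_MSE + exp(-s2) L_CE + s1 + s2``, identical to
    ``L_MSE/sigma1^2 + L_CE/sigma2^2 + 2 log sigma1 + 2 log sigma2``.
    """
    for v in (l_mse, l_ce, s1, s2):
        if not np.isfinite(v):
            raise ValueError("non-finite input to combined_loss")
    total = float(np.exp(-s1) * l_mse + np.exp(-s2) * l_ce + s1 + s2)
    return LossState(l_mse=float(l_mse), l_ce=float(l_ce),
                     sigma1_sq=float(np.exp(s1)), sigma2_sq=float(np.exp(s2)),
                     total=total)
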