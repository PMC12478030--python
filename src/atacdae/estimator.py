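"""scikit-learn style estimator facade over the imputation pipeline.

:class:`ScATACImputer` follows the transformer contract: ``fit(X, y)`` on a
(cells x peaks) count matrix trains the dual-task network, ``transform(X)``
returns the imputed matrix on the count scale. It composes with sklearn
pipelines, ``clone`` and ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import CellLabels, PeakMatrix
from .imputation import impute
from .model import ModelConfig
from .preprocess import NormalizedMatrix, cap_outliers, normalize
from .training import TrainConfig, derive_labels, fit

__all__ = ["ScATACImputer"]


class ScATACImputer(TransformerMixin, BaseEstimator):
    """Impute dropout zeros in a peak-by-cell count matrix.

    Parameters mirror the model and training configurations; see
    :class:`~atacdae.model.ModelConfig` and
    :class:`~atacdae.training.TrainConfig`. ``X`` is (n_cells, n_peaks) per
    sklearn convention; internally the data is transposed to peaks x cells.

    Attributes (after fit)
    ----------------------
    network_ : the trained network
    history_ : per-epoch loss history
    peak_denominators_ : per-peak normalization denominators
    labels_ : the population labels used (given or derived)
    """

    def __init__(self, levels: int = 2, bottom_channels: int = 32,
                 top_channels: int = 64, encoder_dropout: float = 0.1,
                 classifier_hidden: int = 128, use_masking: bool = True,
                 use_classifier: bool = True, train_mask_rate: float = 0.2,
                 n_populations: int | None = None, epochs: int = 100,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 validation_fraction: float = 0.1, early_stop_patience: int = 10,
                 outlier_percentile: float = 99.9,
                 impute_mode: str = "full_reconstruction",
                 random_state: int = 0, verbose: bool = False) -> None:
        self.levels = levels
        self.bottom_channels = bottom_channels
        self.top_channels = top_channels
        self.encoder_dropout = encoder_dropout
        self.classifier_hidden = classifier_hidden
        self.use_masking = use_masking
        self.use_classifier = use_classifier
        self.train_mask_rate = train_mask_rate
        self.n_populations = n_populations
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.early_stop_patience = early_stop_patience
        self.outlier_percentile = outlier_percentile
        self.impute_mode = impute_mode
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def _to_normalized(self, X) -> NormalizedMatrix:
        X = sp.csr_matrix(X).T.tocsr()  # peaks x cells
        if X.nnz and not np.allclose(X.data, np.round(X.data)):
            raise ValueError("X must contain integer counts")
        pm = PeakMatrix(X=X.astype(np.int64))
        pm = cap_outliers(pm, self.outlier_percentile)
        return normalize(pm)

    def fit(self, X, y=None) -> "ScATACImputer":
        """Train on (n_cells, n_peaks) counts; ``y`` are population labels."""
        norm = self._to_normalized(X)
        if y is not None:
            y = np.asarray(y)
            codes = np.unique(y, return_inverse=True)[1]
            labels = CellLabels(assignments=codes)
        elif self.use_classifier:
            if self.n_populations is None:
                raise ValueError(
                    "use_classifier=True needs labels y or n_populations to "
                    "derive them by clustering")
            labels = derive_labels(norm, self.n_populations,
                                   seed=self.random_state)
        else:
            labels = None

        q = labels.q if labels is not None else 0
        model_cfg = ModelConfig(
            input_length=norm.n_peaks, levels=self.levels,
            bottom_channels=self.bottom_channels, top_channels=self.top_channels,
            encoder_dropout=self.encoder_dropout,
            classifier_hidden=self.classifier_hidden,
            n_populations=q, train_mask_rate=self.train_mask_rate,
            use_masking=self.use_masking, use_classifier=self.use_classifier,
            seed=self.random_state)
        train_cfg = TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            validation_fraction=self.validation_fraction,
            early_stop_patience=self.early_stop_patience,
            seed=self.random_state, verbose=self.verbose)
        self.network_, self.history_ = fit(norm, labels, model_cfg, train_cfg)
        self.peak_denominators_ = norm.peak_denominators
        self.labels_ = labels
        self.n_features_in_ = norm.n_peaks
        return self

    # ------------------------------------------------------------- transform
    def transform(self, X) -> np.ndarray:
        """Impute (n_cells, n_peaks) counts; returns the same shape."""
        check_is_fitted(self, "network_")
        norm = self._to_normalized(X)
        if norm.n_peaks != self.n_features_in_:
            raise ValueError(
                f"X has {norm.n_peaks} peaks, fitted on {self.n_features_in_}")
        result = impute(norm, self.network_, mode=self.impute_mode)
        return result.imputed_counts.T

    def predict_proba(self, X) -> np.ndarray:
        """Population membership probabilities from the multi-classifier."""
        check_is_fitted(self, "network_")
        if not self.use_classifier:
            raise AttributeError("classifier was disabled (use_classifier=False)")
        norm = self._to_normalized(X)
        return impute(norm, self.network_).class_probabilities

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
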