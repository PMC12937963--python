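"""scikit-learn estimator facade over the network and training loop.

``NucleiSegmenter`` is a fit/predict segmentation estimator: ``X`` is an
(N, H, W, 3) uint8 image stack, ``y`` an (N, H, W) stack of 3-class
watershed masks.  It composes with sklearn model selection and pipelines
(e.g. preceded by :class:`wedseg.watershed.WatershedMasker` to derive the
targets from raw images).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .metrics import (DEFAULT_THRESHOLD, MetricsReport, dataset_pixel_accuracy,
                      evaluate_dataset, threshold_refine)
from .network import NetworkConfig, SegmentationNet
from .train import TrainConfig, predict_batch, split_dataset, train

__all__ = ["NucleiSegmenter"]


class NucleiSegmenter(BaseEstimator):
    """Watershed-supervised encoder-decoder nuclei segmenter.

    Parameters mirror the architecture defaults (encoder widths
    ``base_width * 2**stage``, bottleneck ``base_width * 2**depth``,
    dropout increasing 0.1-0.4) and the training regime (Adam at 4e-4,
    dice + categorical cross-entropy, reduce-on-plateau, early stopping).
    A fraction ``validation_fraction`` of the fitted data is held out as
    the validation set monitored by both callbacks.
    """

    def __init__(self, base_width: int = 8, depth: int = 4, num_classes: int = 3,
                 dropout_rates: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4),
                 use_batch_norm: bool = False, learning_rate: float = 4e-4,
                 batch_size: int = 16, epochs: int = 100,
                 weight_decay: float = 1e-5, early_stop_patience: int = 10,
                 plateau_factor: float = 0.5, plateau_patience: int = 5,
                 dice_weight: float = 1.0, ce_weight: float = 1.0,
                 validation_fraction: float = 0.2,
                 threshold: float = DEFAULT_THRESHOLD,
                 random_state: int = 0, verbose: bool = False,
                 dtype: str = "float32"):
        self.base_width = base_width
        self.depth = depth
        self.num_classes = num_classes
        self.dropout_rates = dropout_rates
        self.use_batch_norm = use_batch_norm
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.early_stop_patience = early_stop_patience
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.dice_weight = dice_weight
        self.ce_weight = ce_weight
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose
        self.dtype = dtype

    # -- construction helpers ---------------------------------------------

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            in_channels=3, base_width=self.base_width, depth=self.depth,
            bottleneck_width=self.base_width * 2 ** self.depth,
            num_classes=self.num_classes, dropout_rates=tuple(self.dropout_rates),
            use_batch_norm=self.use_batch_norm,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, split_fraction=1.0 - self.validation_fraction,
            weight_decay=self.weight_decay,
            early_stop_patience=self.early_stop_patience,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            dice_weight=self.dice_weight, ce_weight=self.ce_weight,
            seed=self.random_state,
        )

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (N, H, W, 3), got {X.shape}")
        return X

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, validation_data: tuple | None = None) -> "NucleiSegmenter":
        """Train on image/mask stacks.

        If ``validation_data=(X_val, y_val)`` is given it replaces the
        internal hold-out split and all of ``X`` is used for gradient
        updates.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (N, H, W) matching X, got {y.shape}")
        dtype = np.dtype(self.dtype).type
        self.network_ = SegmentationNet(self._network_config(),
                                        seed=self.random_state, dtype=dtype)
        self.n_parameters_ = self.network_.n_parameters()
        self.classes_ = np.arange(self.num_classes)
        config = self._train_config()
        if validation_data is not None:
            X_val = self._check_X(validation_data[0])
            y_val = np.asarray(validation_data[1])
            images = np.concatenate([X, X_val], axis=0)
            masks = np.concatenate([y, y_val], axis=0)
            from .train import DatasetSplit
            split = DatasetSplit(
                train_indices=np.arange(len(X)),
                test_indices=np.arange(len(X), len(X) + len(X_val)),
            )
        else:
            images, masks = X, y
            split = split_dataset(len(X), config.split_fraction, self.random_state)
        self.split_ = split
        self.history_ = train(self.network_, images, masks, split, config,
                              verbose=self.verbose)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, (N, H, W, num_classes)."""
        check_is_fitted(self, "network_")
        probs = predict_batch(self.network_, self._check_X(X),
                              batch_size=self.batch_size)
        return probs.transpose(0, 2, 3, 1)

    def predict(self, X) -> np.ndarray:
        """Argmax 3-class labels, (N, H, W)."""
        check_is_fitted(self, "network_")
        probs = predict_batch(self.network_, self._check_X(X),
                              batch_size=self.batch_size)
        return probs.argmax(axis=1).astype(np.uint8)

    def predict_nuclei(self, X) -> np.ndarray:
        """Binary nucleus masks from the post-hoc probability threshold."""
        check_is_fitted(self, "network_")
        probs = predict_batch(self.network_, self._check_X(X),
                              batch_size=self.batch_size)
        return np.stack([threshold_refine(p, self.threshold)[1] for p in probs])

    def score(self, X, y) -> float:
        """Dataset pixel accuracy of the argmax labeling."""
        preds = self.predict(X)
        return dataset_pixel_accuracy(list(preds), list(np.asarray(y)))

    def evaluate(self, X, y) -> MetricsReport:
        check_is_fitted(self, "network_")
        return evaluate_dataset(self.network_, self._check_X(X),
                                list(np.asarray(y)), threshold=self.threshold,
                                batch_size=self.batch_size)
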