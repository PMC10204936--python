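"""CNN classifiers for windowed fNIRS examples, scikit-learn style.

Two architectures, both ending in fully connected classification layers
over three task states (left / right / rest):

* :class:`CNN3DClassifier` - an initial 3D convolutional stage extracts
  spatial and temporal features simultaneously from stacked topographic
  image sequences ([layers, time, height, width] input, e.g. the Block
  or S-by-D structures).  The same filters are applied at every position,
  so the feature space is positionally invariant.
* :class:`CNN1DClassifier` - temporal convolution only, applied per row of
  a [rows, time] input (the Flat structure); every measurement row is an
  independent variable and the classification head learns per-row
  weights.

Default hyperparameters are the grid-search selections: one conv stage
(16 filters for the 3D model, 8 for the 1D; temporal kernel 4), two
hidden fully connected layers of 100 units with dropout (0.4 / 0.8),
batch size 50, 60 epochs, Adam at learning rate 0.01.  A single integer
seed drives initialisation, shuffling and dropout, making fits
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import _nn


class _CNNBase(ClassifierMixin, BaseEstimator):
    def __init__(
        self,
        n_conv_layers=1,
        n_filters=16,
        temporal_kernel=4,
        spatial_kernel=3,
        n_fc_layers=2,
        fc_size=100,
        dropout_rate=0.4,
        batch_size=50,
        n_epochs=60,
        learning_rate=0.01,
        seed=0,
    ):
        self.n_conv_layers = n_conv_layers
        self.n_filters = n_filters
        self.temporal_kernel = temporal_kernel
        self.spatial_kernel = spatial_kernel
        self.n_fc_layers = n_fc_layers
        self.fc_size = fc_size
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # -- subclass hooks -------------------------------------------------
    def _validate_X(self, X):  # pragma: no cover - interface
        raise NotImplementedError

    def _build(self, input_shape, n_classes, rng):  # pragma: no cover
        raise NotImplementedError

    # -- estimator API --------------------------------------------------
    def _check_params(self):
        for name in (
            "n_conv_layers",
            "n_filters",
            "temporal_kernel",
            "n_fc_layers",
            "fc_size",
            "batch_size",
            "n_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def fit(self, X, y):
        self._check_params()
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.seed)
        self._net = self._build(X.shape[1:], len(self.classes_), rng)
        self.n_parameters_ = self._net.n_parameters
        self.loss_curve_ = _nn.train_network(
            self._net,
            X,
            y_idx,
            n_epochs=self.n_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            rng=rng,
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def _check_fitted(self):
        if not hasattr(self, "_net"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")

    def predict_proba(self, X):
        self._check_fitted()
        X = self._validate_X(X)
        if len(X) == 0:
            return np.empty((0, len(self.classes_)))
        out = []
        chunk = 64  # keeps conv scratch buffers modest
        for start in range(0, len(X), chunk):
            logits = self._net.forward(X[start : start + chunk], train=False)
            out.append(_nn.softmax(logits))
        return np.concatenate(out)

    def predict(self, X):
        self._check_fitted()
        proba = self.predict_proba(X)
        if len(proba) == 0:
            return np.array([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(proba, axis=1)]


class CNN3DClassifier(_CNNBase):
    """Spatial-temporal 3D CNN over [layers, time, height, width] examples."""

    def _validate_X(self, X):
        X = np.asarray(X, dtype=_nn.DTYPE)
        if X.ndim != 5:
            raise ValueError(
                f"expected [n, layers, time, height, width] input, got ndim={X.ndim}"
            )
        return X

    def _build(self, input_shape, n_classes, rng):
        C, T, H, W = input_shape
        kt = self.temporal_kernel
        ks = self.spatial_kernel
        layers = []
        in_ch = C
        for i in range(self.n_conv_layers):
            kernel = (kt, min(ks, H), min(ks, W))
            layers.append(
                _nn.Conv3D(in_ch, self.n_filters, kernel, rng, needs_input_grad=i > 0)
            )
            layers.append(_nn.ReLU())
            T = T - kernel[0] + 1
            H = H - kernel[1] + 1
            W = W - kernel[2] + 1
            if min(T, H, W) < 1:
                raise ValueError("convolution stack shrinks input below 1 voxel")
            in_ch = self.n_filters
        layers.append(_nn.Flatten())
        # dropout regularises the large flattened feature vector; applied
        # inside the narrow 100-unit head it makes high rates (0.8)
        # untrainable, so it sits once after the flatten
        layers.append(_nn.Dropout(self.dropout_rate))
        n_in = in_ch * T * H * W
        for _ in range(self.n_fc_layers):
            layers.append(_nn.Dense(n_in, self.fc_size, rng))
            layers.append(_nn.ReLU())
            n_in = self.fc_size
        layers.append(_nn.Dense(n_in, n_classes, rng, scale=1.0))
        return _nn.Network(layers)

    def feature_maps(self, X):
        """Output of the first convolutional stage (post-ReLU), for inspection."""
        self._check_fitted()
        X = self._validate_X(X)
        out = self._net.layers[0].forward(X, train=False)
        return np.maximum(out, 0)


class CNN1DClassifier(_CNNBase):
    """Per-row temporal CNN over [rows, time] examples (Flat structure)."""

    def __init__(
        self,
        n_conv_layers=1,
        n_filters=8,
        temporal_kernel=4,
        spatial_kernel=1,
        n_fc_layers=2,
        fc_size=100,
        dropout_rate=0.8,
        batch_size=50,
        n_epochs=60,
        learning_rate=0.01,
        seed=0,
    ):
        super().__init__(
            n_conv_layers=n_conv_layers,
            n_filters=n_filters,
            temporal_kernel=temporal_kernel,
            spatial_kernel=spatial_kernel,
            n_fc_layers=n_fc_layers,
            fc_size=fc_size,
            dropout_rate=dropout_rate,
            batch_size=batch_size,
            n_epochs=n_epochs,
            learning_rate=learning_rate,
            seed=seed,
        )

    def _validate_X(self, X):
        X = np.asarray(X, dtype=_nn.DTYPE)
        if X.ndim != 3:
            raise ValueError(f"expected [n, rows, time] input, got ndim={X.ndim}")
        return X[:, :, None, :]  # -> [n, rows, 1, time]

    def _build(self, input_shape, n_classes, rng):
        R, C, T = input_shape
        layers = []
        in_ch = C
        for i in range(self.n_conv_layers):
            layers.append(
                _nn.ConvTime1D(
                    in_ch, self.n_filters, self.temporal_kernel, rng,
                    needs_input_grad=i > 0,
                )
            )
            layers.append(_nn.ReLU())
            T = T - self.temporal_kernel + 1
            if T < 1:
                raise ValueError("convolution stack shrinks input below 1 frame")
            in_ch = self.n_filters
        layers.append(_nn.Flatten())
        layers.append(_nn.Dropout(self.dropout_rate))  # see CNN3DClassifier note
        n_in = R * in_ch * T
        for _ in range(self.n_fc_layers):
            layers.append(_nn.Dense(n_in, self.fc_size, rng))
            layers.append(_nn.ReLU())
            n_in = self.fc_size
        layers.append(_nn.Dense(n_in, n_classes, rng, scale=1.0))
        return _nn.Network(layers)

    def feature_maps(self, X):
        """Per-row temporal feature maps from the first conv stage (post-ReLU)."""
        self._check_fitted()
        X = self._validate_X(X)
        out = self._net.layers[0].forward(X, train=False)
        return np.maximum(out, 0)
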