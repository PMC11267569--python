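"""Scikit-learn estimators wrapping the capsule network and its ablation.

``CapsNetClassifier`` is the main model: it consumes stacked FCGR count
images of shape ``(n_samples, N, N)`` (e.g. from :class:`~fcgrcaps.fcgr.FCGREncoder`,
with which it composes in a sklearn ``Pipeline``) and binary labels.
``DenseHeadClassifier`` swaps the capsule layers for a plain dense head while
keeping the frontend, loss and training loop — the ablation comparator.

Label convention: ``classes_`` is ordered ``[negative, positive]`` and
``classes_[1]`` is always the positive class — by default the
lexicographically larger label, overridable with ``positive_label`` (so
"enhancer" and "strong" can be the positives of their stages).  The decision
rule is the capsule convention — predict positive iff the positive capsule
is strictly longer than the negative one (an exact tie goes to the negative
class).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .capsnet import (Adam, CapsNet, CapsNetConfig, ConfigurationError,
                      DenseHeadNet, scale_images, small_config)

__all__ = ["CapsNetClassifier", "DenseHeadClassifier", "infer_positive_label"]

_PRESETS = {"small": small_config}


def infer_positive_label(labels) -> str | None:
    """Domain default for which class is 'positive': enhancer over
    nonenhancer, strong over weak; None when the label set is unrecognized."""
    s = set(np.asarray(labels).tolist())
    if s == {"enhancer", "nonenhancer"}:
        return "enhancer"
    if s == {"strong", "weak"}:
        return "strong"
    return None


class _FCGRNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses pick the network."""

    def __init__(self, config: CapsNetConfig | str = "small", n_epochs: int = 100,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 random_state: int | None = None, positive_label=None):
        self.config = config
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.positive_label = positive_label

    # -- subclass hooks ----------------------------------------------------
    def _build_net(self, config, rng):
        raise NotImplementedError

    def _resolve_config(self, X) -> CapsNetConfig:
        cfg = self.config
        if isinstance(cfg, str):
            try:
                factory = _PRESETS[cfg]
            except KeyError:
                raise ConfigurationError(
                    f"unknown config preset {cfg!r}; available: {sorted(_PRESETS)}") from None
            cfg = factory(input_resolution=X.shape[1])
        return cfg

    @staticmethod
    def _validate_X(X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n_samples, N, N) stacked FCGR images, got {X.shape}")
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        """Train by minibatch Adam on the margin loss.

        All randomness (parameter init, epoch shuffling) is driven by
        ``random_state``.  Records the per-epoch mean loss in ``loss_curve_``
        and aborts with a diagnostic if the loss goes NaN (e.g. at a
        divergent learning rate).
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
        pos = self.positive_label if self.positive_label is not None else classes[1]
        if pos not in classes:
            raise ValueError(f"positive_label {pos!r} not among labels {classes.tolist()}")
        neg = classes[0] if classes[1] == pos else classes[1]
        self.classes_ = np.array([neg, pos])  # capsule 0 = negative, 1 = positive
        yi = (y == pos).astype(np.int64)

        cfg = self._resolve_config(X)
        if X.shape[1] != cfg.input_resolution:
            raise ConfigurationError(
                f"images are {X.shape[1]}x{X.shape[2]} but config expects "
                f"N={cfg.input_resolution}")
        self.config_ = cfg
        rng = np.random.default_rng(self.random_state)
        net = self._build_net(cfg, rng)
        Xs = scale_images(X, cfg.input_scaling)

        opt = Adam(net.param_names, lr=self.learning_rate)
        n = X.shape[0]
        self.loss_curve_ = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss, grads = net.loss_and_grads(Xs[idx], yi[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch + 1} "
                        f"(learning rate {self.learning_rate}); lower the learning rate")
                opt.step(net.params, grads)
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)) if losses else float("nan"))
        self.net_ = net
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _forward(self, X, want_all: bool = False):
        check_is_fitted(self, "net_")
        X = self._validate_X(X)
        Xs = scale_images(X, self.config_.input_scaling)
        return self.net_.forward(Xs)

    def predict_lengths(self, X) -> np.ndarray:
        """Per-class capsule lengths p_j in [0, 1), columns ordered like
        ``classes_``.  These are independent presence probabilities and need
        not sum to 1."""
        return self._forward(X)["p"]

    def decision_function(self, X) -> np.ndarray:
        """p_positive - p_negative; positive means the positive class."""
        p = self.predict_lengths(X)
        return p[:, 1] - p[:, 0]

    def predict(self, X) -> np.ndarray:
        p = self.predict_lengths(X)
        return self.classes_[(p[:, 1] > p[:, 0]).astype(int)]

    def predict_proba(self, X) -> np.ndarray:
        """Capsule lengths renormalized to sum to 1 per row (sklearn
        convention); use :meth:`predict_lengths` for the raw lengths."""
        p = self.predict_lengths(X)
        s = p.sum(axis=1, keepdims=True)
        return np.where(s > 0, p / np.where(s > 0, s, 1.0), 0.5)

    def forward_details(self, X) -> dict:
        """Expose intermediate activities (primary capsules u, type capsules
        V, coupling coefficients c) for embedding export and diagnostics."""
        return self._forward(X)


class CapsNetClassifier(_FCGRNetClassifier):
    """FCGR-image classifier with a capsule head and dynamic routing.

    Parameters
    ----------
    config : CapsNetConfig or 'small'
        Architecture; the 'small' preset builds a compact geometry at the
        images' resolution.  See :func:`fcgrcaps.capsnet.full_scale_config`
        for the heavier variant.
    n_epochs, batch_size, learning_rate
        Adam training schedule.  Adam at learning rate 0.1 frequently
        diverges on the margin loss; 1e-3 is the stable default, and a
        divergent run aborts with a clear error rather than returning junk.
    random_state : int
        Seeds parameter initialization and minibatch shuffling.

    Attributes
    ----------
    classes_ : (2,) array; ``classes_[1]`` is the positive class.
    loss_curve_ : per-epoch mean margin loss.
    net_ : the underlying :class:`~fcgrcaps.capsnet.CapsNet`.
    """

    def _build_net(self, config, rng):
        return CapsNet(config, rng=rng)


class DenseHeadClassifier(_FCGRNetClassifier):
    """Ablation: capsule layers replaced by a dense (MLP) head.

    Trains and evaluates through the identical pipeline as
    :class:`CapsNetClassifier`; its "lengths" are per-class sigmoid outputs
    fed to the same margin loss.
    """

    def __init__(self, config: CapsNetConfig | str = "small", n_epochs: int = 100,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 random_state: int | None = None, positive_label=None, hidden: int = 64):
        super().__init__(config, n_epochs, batch_size, learning_rate, random_state,
                         positive_label)
        self.hidden = hidden

    def _build_net(self, config, rng):
        return DenseHeadNet(config, rng=rng, hidden=self.hidden)
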