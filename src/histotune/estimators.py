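"""scikit-learn style estimators.

``TinyConvNetClassifier`` is a small, self-contained convolutional
classifier used as the trainable fitness backend: a fixed random
convolutional backbone (the stand-in for a pretrained feature extractor)
followed by a partially-trainable hidden layer and a softmax head.  It
honors the searched hyperparameters — batch size, dropout, loss function,
weight optimizer and the transfer-learn ratio (the fraction of non-head
units left trainable).

``ImageScaler`` wraps the per-image intensity scalings as a transformer,
and ``MetaheuristicSearch`` exposes the full hyperparameter search as a
fit/predict estimator over labelled image arrays.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import scale_image
from .search_space import LOSS_OPTIONS, OPTIMIZER_OPTIONS

__all__ = ["TinyConvNetClassifier", "ImageScaler", "MetaheuristicSearch"]


class ConfigurationError(ValueError):
    """An unsupported decoded option was requested."""


# ---------------------------------------------------------------------------
# gradient rules for the eleven weight optimizers
# ---------------------------------------------------------------------------

_DEFAULT_LR = {
    "sgd": 0.1,
    "sgd_nesterov": 0.1,
    "adam": 0.02,
    "nadam": 0.02,
    "adamax": 0.02,
    "adam_amsgrad": 0.02,
    "adagrad": 0.1,
    "adadelta": 1.0,
    "rmsprop": 0.01,
    "rmsprop_centered": 0.01,
    "ftrl": 0.5,
}


class _WeightOptimizer:
    """Stateful first-order update rule shared by all trainable tensors."""

    def __init__(self, name: str, lr: float | None = None):
        if name not in _DEFAULT_LR:
            raise ConfigurationError(
                f"unsupported parameter optimizer {name!r}; supported: {sorted(_DEFAULT_LR)}"
            )
        self.name = name
        self.lr = _DEFAULT_LR[name] if lr is None else lr
        self.t = 0
        self.state: dict[str, dict[str, np.ndarray]] = {}

    def _slot(self, key: str, like: np.ndarray) -> dict:
        if key not in self.state:
            self.state[key] = {k: np.zeros_like(like) for k in ("m", "v", "vhat", "g2", "dx2", "z", "n")}
        return self.state[key]

    def step_begin(self) -> None:
        self.t += 1

    def update(self, key: str, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        lr, t = self.lr, self.t
        s = self._slot(key, param)
        eps = 1e-7
        name = self.name
        if name == "sgd":
            return param - lr * grad
        if name == "sgd_nesterov":
            mu = 0.9
            s["m"] = mu * s["m"] - lr * grad
            return param + mu * s["m"] - lr * grad
        if name in ("adam", "adam_amsgrad", "nadam"):
            b1, b2 = 0.9, 0.999
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            s["v"] = b2 * s["v"] + (1 - b2) * grad**2
            mhat = s["m"] / (1 - b1**t)
            vhat = s["v"] / (1 - b2**t)
            if name == "adam_amsgrad":
                s["vhat"] = np.maximum(s["vhat"], vhat)
                vhat = s["vhat"]
            if name == "nadam":
                mhat = b1 * mhat + (1 - b1) * grad / (1 - b1**t)
            return param - lr * mhat / (np.sqrt(vhat) + eps)
        if name == "adamax":
            b1, b2 = 0.9, 0.999
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            s["v"] = np.maximum(b2 * s["v"], np.abs(grad))
            return param - lr * s["m"] / ((1 - b1**t) * (s["v"] + eps))
        if name == "adagrad":
            s["g2"] += grad**2
            return param - lr * grad / (np.sqrt(s["g2"]) + eps)
        if name == "adadelta":
            rho = 0.95
            s["g2"] = rho * s["g2"] + (1 - rho) * grad**2
            dx = -np.sqrt(s["dx2"] + eps) / np.sqrt(s["g2"] + eps) * grad
            s["dx2"] = rho * s["dx2"] + (1 - rho) * dx**2
            return param + lr * dx
        if name in ("rmsprop", "rmsprop_centered"):
            rho = 0.9
            s["g2"] = rho * s["g2"] + (1 - rho) * grad**2
            denom = s["g2"]
            if name == "rmsprop_centered":
                s["m"] = rho * s["m"] + (1 - rho) * grad
                denom = s["g2"] - s["m"] ** 2
            return param - lr * grad / (np.sqrt(denom) + eps)
        if name == "ftrl":
            # FTRL-proximal without regularization reduces to a per-weight
            # adaptive-learning-rate descent
            alpha = lr
            new_n = s["n"] + grad**2
            sig = (np.sqrt(new_n) - np.sqrt(s["n"])) / alpha
            s["z"] += grad - sig * param
            s["n"] = new_n
            # coordinates that never saw a gradient keep their initial value
            return np.where(s["n"] > 0, -alpha * s["z"] / (np.sqrt(s["n"]) + eps), param)
        raise AssertionError(name)


# ---------------------------------------------------------------------------
# losses: gradient of the mean loss with respect to the softmax logits
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _chain_through_softmax(p: np.ndarray, dLdp: np.ndarray) -> np.ndarray:
    inner = (dLdp * p).sum(axis=1, keepdims=True)
    return p * (dLdp - inner)


def _loss_grad(name: str, p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean loss)/d(logits) for one-hot targets ``y`` and softmax output ``p``."""
    n, k = p.shape
    if name in ("categorical_crossentropy", "kl_divergence"):
        # for one-hot targets the KL divergence equals the cross-entropy up
        # to a constant, so the gradients coincide
        return (p - y) / n
    pc = np.clip(p, 1e-7, 1.0)
    if name == "poisson":
        dLdp = (1.0 - y / pc) / k
        return _chain_through_softmax(p, dLdp) / n
    y_pm = 2.0 * y - 1.0
    if name == "hinge":
        active = (1.0 - y_pm * p) > 0
        dLdp = -y_pm * active / k
        return _chain_through_softmax(p, dLdp) / n
    if name == "squared_hinge":
        margin = np.maximum(0.0, 1.0 - y_pm * p)
        dLdp = -2.0 * y_pm * margin / k
        return _chain_through_softmax(p, dLdp) / n
    if name == "categorical_hinge":
        neg = np.where(y > 0, -np.inf, p)
        j = neg.argmax(axis=1)
        pos = (p * y).sum(axis=1)
        loss_active = (neg[np.arange(n), j] - pos + 1.0) > 0
        dLdp = np.zeros_like(p)
        dLdp[np.arange(n), j] += loss_active
        dLdp -= y * loss_active[:, None]
        return _chain_through_softmax(p, dLdp) / n
    raise ConfigurationError(f"unsupported loss {name!r}; supported: {sorted(LOSS_OPTIONS)}")


class TinyConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Small convolutional softmax classifier trained by minibatch descent.

    Architecture: block-mean downsample to ``pool_to`` x ``pool_to``, one
    fixed random 3x3 convolution with ``n_filters`` filters (the frozen
    "pretrained" backbone), ReLU, 4x4 adaptive average pooling, feature
    standardization, then a dense hidden layer (partially trainable, see
    ``learn_ratio``) with ReLU and dropout, and a softmax output head.

    Parameters
    ----------
    loss : str
        One of the six supported loss functions.
    batch_size : int
        Minibatch size; the sizes actually consumed are recorded in
        ``batch_sizes_`` for instrumentation.
    dropout : float
        Dropout rate on the hidden activations during training.
    learn_ratio : int
        Percentage (1-100) of hidden units whose incoming weights are
        trainable; the remainder stay at their initial ("pretrained")
        values.  The output head is always trainable.
    optimizer : str
        One of the eleven supported weight-update rules.
    epochs : int
        Training passes over the data; 0 leaves the model untrained (the
        zero-initialized head then predicts the first class everywhere,
        i.e. chance level on balanced data).
    """

    def __init__(
        self,
        loss: str = "categorical_crossentropy",
        batch_size: int = 16,
        dropout: float = 0.0,
        learn_ratio: int = 100,
        optimizer: str = "adam",
        epochs: int = 5,
        learning_rate: float | None = None,
        n_filters: int = 8,
        hidden: int = 32,
        pool_to: int = 16,
        backbone_seed: int = 0,
        random_state: int | None = None,
    ):
        self.loss = loss
        self.batch_size = batch_size
        self.dropout = dropout
        self.learn_ratio = learn_ratio
        self.optimizer = optimizer
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.n_filters = n_filters
        self.hidden = hidden
        self.pool_to = pool_to
        self.backbone_seed = backbone_seed
        self.random_state = random_state

    # -- backbone ------------------------------------------------------

    def _filters(self) -> np.ndarray:
        rng = np.random.default_rng(self.backbone_seed)
        return rng.standard_normal((self.n_filters, 3, 3, 3)) / math.sqrt(27.0)

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"expected images of shape (n, H, W, 3), got {X.shape}")
        n, h, w, _ = X.shape
        p = min(self.pool_to, h, w)
        fy, fx = h // p, w // p
        Xc = X[:, : fy * p, : fx * p, :].reshape(n, p, fy, p, fx, 3).mean(axis=(2, 4))
        win = np.lib.stride_tricks.sliding_window_view(Xc, (3, 3), axis=(1, 2))  # (n, p-2, p-2, c, wy, wx)
        conv = np.einsum("nijcyx,fyxc->nijf", win, self._filters())
        act = np.maximum(conv, 0.0)
        pooled = [
            blk.mean(axis=(1, 2))
            for row in np.array_split(act, min(4, act.shape[1]), axis=1)
            for blk in np.array_split(row, min(4, act.shape[2]), axis=2)
        ]
        feats = np.concatenate([np.stack(pooled, axis=1).reshape(n, -1), Xc.mean(axis=(1, 2))], axis=1)
        return feats

    # -- training ------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        feats = self._features(X)
        self._mu = feats.mean(axis=0)
        self._sd = feats.std(axis=0) + 1e-8
        F = (feats - self._mu) / self._sd
        n, d = F.shape

        rng = np.random.default_rng(
            self.backbone_seed if self.random_state is None else self.random_state
        )
        init_rng = np.random.default_rng(self.backbone_seed + 1)
        self.W1_ = init_rng.standard_normal((d, self.hidden)) * math.sqrt(2.0 / d)
        self.b1_ = np.zeros(self.hidden)
        self.W2_ = np.zeros((self.hidden, k))
        self.b2_ = np.zeros(k)

        if not 1 <= self.learn_ratio <= 100:
            raise ConfigurationError("learn_ratio must be an integer percent in [1, 100]")
        n_train = max(1, math.ceil(self.learn_ratio / 100.0 * self.hidden))
        mask = np.zeros(self.hidden)
        mask[:n_train] = 1.0
        self.trainable_mask_ = mask

        Y = np.eye(k)[y_idx]
        opt = _WeightOptimizer(self.optimizer, self.learning_rate)
        self.batch_sizes_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                fb, yb = F[idx], Y[idx]
                self.batch_sizes_.append(len(idx))
                h_pre = fb @ self.W1_ + self.b1_
                h = np.maximum(h_pre, 0.0)
                if self.dropout > 0:
                    keep = rng.random(h.shape) >= self.dropout
                    hd = h * keep / (1.0 - self.dropout)
                else:
                    keep = None
                    hd = h
                z = hd @ self.W2_ + self.b2_
                p = _softmax(z)
                dz = _loss_grad(self.loss, p, yb)
                dW2 = hd.T @ dz
                db2 = dz.sum(axis=0)
                dh = dz @ self.W2_.T
                if keep is not None:
                    dh = dh * keep / (1.0 - self.dropout)
                dh_pre = dh * (h_pre > 0)
                dW1 = (fb.T @ dh_pre) * mask[None, :]
                db1 = dh_pre.sum(axis=0) * mask
                opt.step_begin()
                self.W2_ = opt.update("W2", self.W2_, dW2)
                self.b2_ = opt.update("b2", self.b2_, db2)
                self.W1_ = opt.update("W1", self.W1_, dW1)
                self.b1_ = opt.update("b1", self.b1_, db1)
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "W1_")
        F = (self._features(X) - self._mu) / self._sd
        h = np.maximum(F @ self.W1_ + self.b1_, 0.0)
        return _softmax(h @ self.W2_ + self.b2_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class ImageScaler(BaseEstimator, TransformerMixin):
    """Per-image intensity scaling transformer (stateless).

    ``method`` is one of normalize / standard / minmax / maxabs; the
    statistics are computed per image, so fit learns nothing.
    """

    def __init__(self, method: str = "minmax"):
        self.method = method

    def fit(self, X, y=None):
        self.n_features_in_ = None
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([scale_image(x, self.method) for x in X])


class MetaheuristicSearch(BaseEstimator):
    """Hyperparameter search over labelled images with fit/predict semantics.

    ``fit(X, y)`` partitions the images, runs the chosen population-based
    optimizer (AO or GTO) with the configured fitness backend, stores the
    best decoded configuration, and — for the trainable backend — refits a
    :class:`TinyConvNetClassifier` with that configuration on the training
    pool so the search object can predict.
    """

    def __init__(
        self,
        algorithm: str = "AO",
        backend: str = "tiny",
        n_solutions: int = 10,
        t_max: int = 10,
        epochs: int = 5,
        include_augmentation: bool = False,
        fitness_metric: str = "accuracy",
        split_ratio: float = 0.85,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.backend = backend
        self.n_solutions = n_solutions
        self.t_max = t_max
        self.epochs = epochs
        self.include_augmentation = include_augmentation
        self.fitness_metric = fitness_metric
        self.split_ratio = split_ratio
        self.random_state = random_state

    def fit(self, X, y):
        from .fitness import (
            SurrogateBackend,
            TinyClassifierBackend,
            evaluate_configuration,
        )
        from .metaheuristics import run_optimizer
        from .preprocessing import ImageRecord, partition_dataset
        from .search_space import build_default_space

        y = np.asarray(y)
        records = [
            ImageRecord(pixels=np.asarray(x), label=str(lbl), provenance=f"array:{i}")
            for i, (x, lbl) in enumerate(zip(X, y))
        ]
        space = build_default_space(include_augmentation=self.include_augmentation)
        data = partition_dataset(records, ratio=self.split_ratio, seed=self.random_state)
        if self.backend == "surrogate":
            backend = SurrogateBackend(space)
        elif self.backend == "tiny":
            backend = TinyClassifierBackend()
        else:
            backend = self.backend

        def objective(config):
            return evaluate_configuration(
                config,
                backend,
                data,
                epochs=self.epochs,
                seed=self.random_state,
                fitness_metric=self.fitness_metric,
            ).fitness

        best, fitness, history = run_optimizer(
            objective,
            space,
            n_solutions=self.n_solutions,
            t_max=self.t_max,
            algorithm=self.algorithm,
            seed=self.random_state,
        )
        self.space_ = space
        self.best_config_ = best
        self.best_score_ = fitness
        self.history_ = history
        self.classes_ = np.unique([r.label for r in records])
        if isinstance(backend, TinyClassifierBackend):
            self.best_estimator_ = backend.build_classifier(best, self.epochs, self.random_state)
            pool = data.train + data.validation
            Xp = np.stack([scale_image(np.asarray(r.pixels, dtype=float), best.scaling_technique) for r in pool])
            yp = np.array([r.label for r in pool])
            self.best_estimator_.fit(Xp, yp)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_config_")
        if not hasattr(self, "best_estimator_"):
            raise AttributeError("predict requires the trainable backend")
        Xs = np.stack(
            [scale_image(np.asarray(x, dtype=float), self.best_config_.scaling_technique) for x in X]
        )
        return self.best_estimator_.predict(Xs)
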