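"""Comparator models consuming order-destroyed PSSM representations.

k-NN, Random Forest and SVM operate on the 400-dimensional summed-PSSM
features; the 2-D CNN treats the 20 x 20 summed matrix as an image.
Default hyper-parameters are the tuned values from the comparison study:
k = 10 neighbours, 500 trees, SVM with an RBF kernel at C = 8 and
gamma = 0.5, and 128 convolution filters of size 3 x 3.

Distance- and kernel-based methods receive standardised features (zero
mean, unit variance, fit on the training split only) additionally scaled
by 1/sqrt(n_features), so the expected squared distance between random
points is O(1) and an RBF width of order one (gamma = 0.5) falls inside
the kernel's responsive range; the rescaling is monotone in distance, so
k-NN neighbourhoods are unchanged.  The SVM scores
are mapped to (0, 1) through the logistic link applied to its decision
values — a fixed monotone transform, so ROC/AUC are unaffected.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn
from .evaluation import evaluate
from .training import inverse_class_frequency_weights, stratified_kfold

__all__ = [
    "BaselineConfig", "FittedBaseline",
    "fit_baseline", "predict_baseline", "cross_validate_baseline",
]

METHODS = ("knn", "rf", "svm", "cnn2d")


@dataclasses.dataclass
class BaselineConfig:
    method: str = "knn"
    knn_k: int = 10
    rf_trees: int = 500
    svm_c: float = 8.0
    svm_gamma: float = 0.5
    cnn2d_filters: int = 128
    cnn2d_kernel: int = 3
    cnn2d_epochs: int = 30
    cnn2d_lr: float = 1e-3
    cnn2d_batch: int = 32
    standardize: bool = True
    seed: int = 7

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if min(self.knn_k, self.rf_trees, self.cnn2d_filters, self.cnn2d_kernel) < 1:
            raise ValueError("hyper-parameters must be positive")
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ValueError("SVM hyper-parameters must be positive")


class _Cnn2d:
    """One conv-ReLU-maxpool block over the 20 x 20 summed matrix,
    flattened into a single sigmoid output; trained with Adam on the
    same weighted binary cross-entropy as the recurrent model."""

    def __init__(self, config: BaselineConfig, side: int = 20):
        rng = np.random.default_rng(config.seed)
        k, f = config.cnn2d_kernel, config.cnn2d_filters
        self.k, self.f, self.side = k, f, side
        self.conv_side = side - k + 1          # valid convolution
        self.pool_side = self.conv_side // 2   # 2x2 max pooling
        fan_in = k * k
        self.W = nn.Param("cnn2d.W", nn.glorot(rng, (f, fan_in), fan_in, f))
        self.b = nn.Param("cnn2d.b", np.zeros(f))
        flat = self.pool_side ** 2 * f
        self.out = nn.Dense(flat, 1, rng, relu=False, prefix="cnn2d.out")
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b, *self.out.params]

    def forward_logit(self, x: np.ndarray) -> float:
        cs = self.conv_side
        cols = sliding_window_view(x, (self.k, self.k)).reshape(cs * cs, -1)
        a = cols @ self.W.v.T + self.b.v              # (cs*cs, f)
        mask = a > 0
        a = np.where(mask, a, 0.0)
        amap = a.reshape(cs, cs, self.f)
        ps = self.pool_side
        windows = amap[: ps * 2, : ps * 2].reshape(ps, 2, ps, 2, self.f)
        pooled = windows.max(axis=(1, 3))
        flat = pooled.ravel()
        self._cache = (cols, mask, amap, windows, pooled, flat)
        return float(self.out.forward(flat)[0])

    def backward(self, dlogit: float) -> None:
        cols, mask, amap, windows, pooled, _ = self._cache
        gflat = self.out.backward(np.array([dlogit]))
        cs, ps = self.conv_side, self.pool_side
        gpooled = gflat.reshape(ps, ps, self.f)
        gwin = np.where(
            windows == pooled[:, None, :, None, :], gpooled[:, None, :, None, :], 0.0
        )
        gmap = np.zeros_like(amap)
        gmap[: ps * 2, : ps * 2] = gwin.reshape(ps * 2, ps * 2, self.f)
        ga = np.where(mask, gmap.reshape(cs * cs, self.f), 0.0)
        self.W.g += ga.T @ cols
        self.b.g += ga.sum(axis=0)

    def fit(self, X: np.ndarray, y: np.ndarray, config: BaselineConfig) -> None:
        w_pos, w_neg = inverse_class_frequency_weights(y)
        optimizer = nn.Adam(self.params, lr=config.cnn2d_lr)
        rng = np.random.default_rng(config.seed + 1)
        n = len(y)
        for _ in range(config.cnn2d_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.cnn2d_batch):
                batch = order[start:start + config.cnn2d_batch]
                optimizer.zero_grad()
                for i in batch:
                    logit = self.forward_logit(X[i])
                    p = float(nn.sigmoid(np.array([logit]))[0])
                    w = w_pos if y[i] == 1 else w_neg
                    self.backward(w * (p - float(y[i])) / len(batch))
                optimizer.step()

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits = np.array([self.forward_logit(x) for x in X])
        return nn.sigmoid(logits)


@dataclasses.dataclass
class FittedBaseline:
    config: BaselineConfig
    estimator: object
    scaler: StandardScaler | None
    n_features: int


def _check_inputs(X: np.ndarray, method: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if method == "cnn2d":
        if X.ndim != 3 or X.shape[1:] != (20, 20):
            raise ValueError("cnn2d consumes (n, 20, 20) summed matrices")
    else:
        if X.ndim != 2 or X.shape[1] != 400:
            raise ValueError(f"{method} consumes (n, 400) summed feature vectors")
    return X


def fit_baseline(X: np.ndarray, labels: np.ndarray, config: BaselineConfig) -> FittedBaseline:
    """Fit one comparator; returns a scorer producing class probabilities."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = _check_inputs(X, config.method)

    scaler = None
    if config.method == "cnn2d":
        scaler = StandardScaler()
        flat = scaler.fit_transform(X.reshape(len(X), -1))
        est = _Cnn2d(config)
        est.fit(flat.reshape(X.shape), y, config)
    else:
        if config.standardize:
            scaler = StandardScaler()
            scaler.fit(X)
            # fold the 1/sqrt(d) distance normalisation into the scaler
            scaler.scale_ = scaler.scale_ * np.sqrt(X.shape[1])
            X = scaler.transform(X)
        if config.method == "knn":
            est = KNeighborsClassifier(n_neighbors=config.knn_k).fit(X, y)
        elif config.method == "rf":
            est = RandomForestClassifier(
                n_estimators=config.rf_trees, random_state=config.seed
            ).fit(X, y)
        else:
            est = SVC(
                C=config.svm_c, gamma=config.svm_gamma, kernel="rbf"
            ).fit(X, y)
    return FittedBaseline(config, est, scaler, X.shape[-1])


def predict_baseline(model: FittedBaseline, X: np.ndarray) -> np.ndarray:
    """Class-1 probabilities in [0, 1] for new inputs."""
    X = _check_inputs(X, model.config.method)
    if model.config.method == "cnn2d":
        flat = model.scaler.transform(X.reshape(len(X), -1))
        return model.estimator.predict(flat.reshape(X.shape))
    if model.scaler is not None:
        X = model.scaler.transform(X)
    if model.config.method == "svm":
        return expit(model.estimator.decision_function(X))
    return model.estimator.predict_proba(X)[:, 1]


def cross_validate_baseline(
    X: np.ndarray, labels: np.ndarray, config: BaselineConfig,
    k: int = 5, seed: int = 7, threshold: float = 0.5,
):
    """Stratified k-fold cross-validation of one baseline; returns the
    fold reports and the mean-metric summary (same shape of result as
    :func:`pssmrnn.training.cross_validate`)."""
    y = np.asarray(labels)
    X = _check_inputs(X, config.method)
    reports = []
    for fold in stratified_kfold(y, k, seed):
        fitted = fit_baseline(X[fold.train_indices], y[fold.train_indices], config)
        probs = predict_baseline(fitted, X[fold.validation_indices])
        reports.append(evaluate(probs, y[fold.validation_indices], threshold))
    summary = {
        key: float(np.mean([getattr(r, key) for r in reports]))
        for key in ("sensitivity", "specificity", "accuracy", "mcc", "auc")
    }
    return reports, summary
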