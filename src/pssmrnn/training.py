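"""Weighted-loss training and stratified cross-validation.

Training follows the protocol of the architecture study: Adam at a fixed
learning rate of 1e-4 for 30 epochs, a weighted binary cross-entropy
loss whose class weights are the inverse class frequencies (so both
classes contribute equally to the loss under imbalance), and 5-fold
cross-validation.  Batches are formed by accumulating per-sample
gradients of the mean loss, which handles variable-length profiles
without padding and is prediction-equivalent to batch-of-one inference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import EvalReport, evaluate
from .model import CNNGRUClassifier, ModelConfig
from .nn import Adam, sigmoid
from .pssm_io import LabeledDataset

__all__ = [
    "TrainConfig", "FoldSplit",
    "inverse_class_frequency_weights", "weighted_bce_loss",
    "stratified_kfold", "train", "cross_validate", "grid_search",
]

LOSS_EPS = 1e-7


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 30
    optimizer: str = "adam"
    class_weighting: str = "inverse_frequency"   # or "none"
    threshold: float = 0.5
    seed: int = 7
    k_folds: int = 5
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ValueError("class_weighting must be 'inverse_frequency' or 'none'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass
class FoldSplit:
    k: int
    train_indices: np.ndarray
    validation_indices: np.ndarray


def inverse_class_frequency_weights(labels: np.ndarray) -> tuple[float, float]:
    """Per-class loss weights ``w_c = n_total / (2 n_c)``.

    The ratio w_pos / w_neg equals n_neg / n_pos (inverse class
    frequency) and the weighted sample count of each class is equal; the
    1/2 normalisation keeps the loss scale comparable across imbalance
    levels.  Returns ``(w_pos, w_neg)``.
    """
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to derive class weights")
    n_total = n_pos + n_neg
    return n_total / (2.0 * n_pos), n_total / (2.0 * n_neg)


def weighted_bce_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
    eps: float = LOSS_EPS,
) -> float:
    """Mean over samples of ``-w(y) * [y log p + (1-y) log(1-p)]``.

    Probabilities are clipped to [eps, 1-eps] before the logarithms.
    ``weights`` is ``(w_pos, w_neg)``.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    w = np.where(y == 1, weights[0], weights[1])
    return float(np.mean(-w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 7) -> list[FoldSplit]:
    """Shuffled stratified k-fold splits; validation sets partition the
    data and per-fold class counts are proportional to within one."""
    labels = np.asarray(labels)
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(i, train_idx, val_idx)
        for i, (train_idx, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels))
    ]


def _class_weights(labels: np.ndarray, config: TrainConfig) -> tuple[float, float]:
    if config.class_weighting == "inverse_frequency":
        return inverse_class_frequency_weights(labels)
    return 1.0, 1.0


def train(
    dataset: LabeledDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[CNNGRUClassifier, list[float]]:
    """Train a CNN-GRU classifier from scratch.

    Returns the trained model and the per-epoch mean training loss.
    Deterministic under a fixed seed: parameter initialisation, sample
    shuffling and dropout all derive from ``train_config.seed``.
    """
    labels = dataset.labels
    if len(dataset) == 0 or labels.min() == labels.max():
        raise ValueError("training requires a dataset with both classes")
    w_pos, w_neg = _class_weights(labels, train_config)
    model = CNNGRUClassifier(model_config, seed=train_config.seed)
    optimizer = Adam(model.params, lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng(train_config.seed + 1)
    dropout_rng = np.random.default_rng(train_config.seed + 2)

    n = len(dataset)
    history: list[float] = []
    for _epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            batch = order[start:start + train_config.batch_size]
            optimizer.zero_grad()
            for idx in batch:
                y = float(labels[idx])
                w = w_pos if y == 1 else w_neg
                logit = model.forward_logit(
                    dataset.profiles[idx].scores, train=True, rng=dropout_rng
                )
                p = float(sigmoid(np.array([logit]))[0])
                p_c = min(max(p, LOSS_EPS), 1.0 - LOSS_EPS)
                epoch_loss += -w * (y * np.log(p_c) + (1.0 - y) * np.log(1.0 - p_c))
                # d(mean batch loss)/d(logit); sigmoid+BCE fused for stability
                model.backward(w * (p - y) / len(batch))
            optimizer.step()
        history.append(epoch_loss / n)
    return model, history


def cross_validate(
    dataset: LabeledDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[list[EvalReport], dict[str, float]]:
    """k-fold stratified cross-validation of the CNN-GRU classifier.

    Each fold trains on its training indices and is evaluated on its
    validation indices; the summary is the unweighted mean of the fold
    metrics.
    """
    folds = stratified_kfold(dataset.labels, train_config.k_folds, train_config.seed)
    reports = []
    for fold in folds:
        model, _ = train(dataset.subset(fold.train_indices), model_config, train_config)
        val = dataset.subset(fold.validation_indices)
        probs = model.predict_dataset(val.profiles)
        reports.append(evaluate(probs, val.labels, train_config.threshold))
    summary = {
        key: float(np.mean([getattr(r, key) for r in reports]))
        for key in ("sensitivity", "specificity", "accuracy", "mcc", "auc")
    }
    return reports, summary


def grid_search(
    dataset: LabeledDataset,
    model_configs: list[ModelConfig],
    train_config: TrainConfig,
    metric: str = "auc",
) -> tuple[ModelConfig, list[dict[str, float]]]:
    """Cross-validate each candidate architecture and return the one with
    the best mean ``metric`` (hyper-parameter sweep helper; no sweep runs
    by default anywhere in the package)."""
    summaries = []
    for mc in model_configs:
        _, summary = cross_validate(dataset, mc, train_config)
        summaries.append(summary)
    best = int(np.argmax([s[metric] for s in summaries]))
    return model_configs[best], summaries
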