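"""Training protocol: stratified 70/30 split, k-fold cross-validation, blind test.

The evaluation protocol holds out 30% of the day-images as a blind test set,
runs k-fold cross-validation (k=3 by default) on the remaining 70% for a
fixed number of epochs while recording loss/accuracy curves, and finally
scores the held-out partition once, reporting the confusion matrix, per-class
metrics, and measured inference time and memory.

The default split unit is the image (each day counted independently), which
mirrors the published counts; ``group_by_subject`` keeps all of one subject's
days on the same side of every partition — the epidemiologically safer
choice, since day-images of one subject are strongly correlated.
"""

from __future__ import annotations

import dataclasses
import resource
import time

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .cnn import ArchitectureSpec
from .metrics import ClassMetrics, ConfusionMatrix, class_metrics, confusion
from .network import Adam, NumpyCNN
from .preprocess import LabeledDataset


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class SplitConfig:
    """Partitioning and schedule parameters of the protocol."""

    train_fraction: float = 0.7
    k: int = 3
    epochs: int = 100
    seed: int = 0
    stratified: bool = True
    group_by_subject: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be at least 2")


@dataclasses.dataclass
class OptimizerConfig:
    """Optimizer defaults: Adam, lr 1e-3, cross-entropy, batch size 32."""

    learning_rate: float = 1e-3
    batch_size: int = 32


@dataclasses.dataclass
class FoldResult:
    fold: int
    train_loss: list[float]
    train_acc: list[float]
    val_loss: list[float]
    val_acc: list[float]
    metrics: ClassMetrics | None
    accuracy: float
    model: NumpyCNN


@dataclasses.dataclass
class UnderfitCheck:
    final_train_loss: float
    final_val_loss: float
    verdict: str  # acceptable | underfit | overfit-suspect


@dataclasses.dataclass
class BlindTestReport:
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    accuracy: float
    predictions: np.ndarray
    inference_seconds_per_batch: float
    peak_memory_mb: float


def _allocate_counts(class_sizes: np.ndarray, target_total: int) -> np.ndarray:
    """Per-class train counts: floors plus largest fractional remainders.

    Guarantees the total equals ``target_total`` and each class is within one
    image of its proportional share.
    """
    exact = class_sizes * target_total / class_sizes.sum()
    counts = np.floor(exact).astype(int)
    remainder = target_total - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_split(
    dataset: LabeledDataset, config: SplitConfig
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/test split.

    The training partition holds floor(train_fraction * n) images, allocated
    per class by largest remainder, so each class's train fraction is within
    one image of the target (e.g. 70% of 1436 images is a training set of
    exactly 1005).  Reproducible under ``config.seed``.
    """
    labels = dataset.labels
    n = len(dataset)
    rng = np.random.default_rng(config.seed)
    classes, class_sizes = np.unique(labels, return_counts=True)
    if (class_sizes < 2).any():
        raise ValueError("every class needs at least 2 images to split")
    target_total = int(np.floor(config.train_fraction * n))
    if not config.stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:target_total], perm[target_total:]
    else:
        per_class = _allocate_counts(class_sizes, target_total)
        train_parts, test_parts = [], []
        for cls, take in zip(classes, per_class):
            idx = np.flatnonzero(labels == cls)
            if config.group_by_subject:
                # whole subjects go to one side; the train size is then only
                # approximately the target (no subject is ever split)
                tr, te = _split_by_subject(dataset, idx, take, rng)
                train_parts.append(tr)
                test_parts.append(te)
            else:
                idx = rng.permutation(idx)
                train_parts.append(idx[:take])
                test_parts.append(idx[take:])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def _split_by_subject(
    dataset: LabeledDataset, idx: np.ndarray, take: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole subjects to train until the target count is reached."""
    subjects = np.array([dataset.images[i].subject_id for i in idx])
    train_parts, test_parts = [], []
    count = 0
    for s in rng.permutation(np.unique(subjects)):
        block = idx[subjects == s]
        if count < take:
            train_parts.append(block)
            count += len(block)
        else:
            test_parts.append(block)
    empty = np.array([], dtype=int)
    return (
        np.concatenate(train_parts) if train_parts else empty,
        np.concatenate(test_parts) if test_parts else empty,
    )


def kfold_partition(
    dataset_or_labels, k: int, seed: int = 0, stratified: bool = True
) -> list[np.ndarray]:
    """Validation folds: k disjoint index arrays covering the set, sizes within 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if isinstance(dataset_or_labels, LabeledDataset):
        labels = dataset_or_labels.labels
    else:
        labels = np.asarray(dataset_or_labels)
    n = len(labels)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in splitter.split(np.zeros(n), labels)]


def fit(
    model: NumpyCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    epochs: int,
    opt: OptimizerConfig,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Mini-batch Adam training loop with per-epoch curve capture."""
    optimizer = Adam(model.parameters, lr=opt.learning_rate)
    rng = np.random.default_rng(seed)
    curves: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    n = len(y_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        loss_sum, n_correct = 0.0, 0
        for start in range(0, n, opt.batch_size):
            sel = order[start : start + opt.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            loss, correct = model.loss_and_backward(xb, yb, train=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            optimizer.step(model.gradients)
            loss_sum += loss * len(yb)
            n_correct += correct
        # training curves are batch-averaged (dropout active), the usual
        # curve convention; validation is scored with dropout off
        curves["train_loss"].append(loss_sum / n)
        curves["train_acc"].append(n_correct / n)
        if x_val is not None and len(y_val):
            curves["val_loss"].append(model.evaluate_loss(x_val, y_val))
            curves["val_acc"].append(float((model.predict(x_val) == y_val).mean()))
    return curves


def train_fold(
    arch: ArchitectureSpec,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: SplitConfig,
    opt: OptimizerConfig | None = None,
    fold: int = 0,
) -> FoldResult:
    """Train one fold for ``config.epochs`` and score its validation set.

    Deterministic given ``config.seed`` (weights, dropout and batch order all
    derive from it).  With zero epochs the untrained model is scored as-is.
    """
    opt = opt or OptimizerConfig()
    ss = np.random.SeedSequence(entropy=(config.seed, fold))
    model_seed, shuffle_seed = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2)]
    model = NumpyCNN(arch, seed=model_seed)
    x_tr = train_set.model_inputs()
    y_tr = train_set.labels
    x_val = val_set.model_inputs()
    y_val = val_set.labels
    curves = fit(model, x_tr, y_tr, x_val, y_val, config.epochs, opt, seed=shuffle_seed)
    pred = model.predict(x_val)
    cm = confusion(y_val, pred)
    cmetrics = class_metrics(cm)
    return FoldResult(
        fold=fold,
        train_loss=curves["train_loss"],
        train_acc=curves["train_acc"],
        val_loss=curves["val_loss"],
        val_acc=curves["val_acc"],
        metrics=cmetrics,
        accuracy=cmetrics.accuracy,
        model=model,
    )


def cross_validate(
    arch: ArchitectureSpec,
    train_set: LabeledDataset,
    config: SplitConfig,
    opt: OptimizerConfig | None = None,
) -> list[FoldResult]:
    """k-fold cross-validation over the training partition."""
    folds = kfold_partition(train_set, config.k, seed=config.seed, stratified=config.stratified)
    all_idx = np.arange(len(train_set))
    results = []
    for i, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(all_idx, val_idx)
        results.append(
            train_fold(
                arch,
                train_set.subset(tr_idx),
                train_set.subset(val_idx),
                config,
                opt,
                fold=i,
            )
        )
    return results


def underfit_check(result: FoldResult, tolerance: float = 0.05) -> UnderfitCheck:
    """Compare final train and validation losses.

    Verdict convention: a validation loss clearly *below* the training loss
    flags underfitting (the model should train longer); a validation loss
    clearly above flags suspected overfitting; within tolerance is acceptable.
    """
    if not result.train_loss or not result.val_loss:
        raise ValueError("empty loss curves")
    tr, val = result.train_loss[-1], result.val_loss[-1]
    if val < tr - tolerance:
        verdict = "underfit"
    elif val > tr + tolerance:
        verdict = "overfit-suspect"
    else:
        verdict = "acceptable"
    return UnderfitCheck(tr, val, verdict)


def blind_test(model: NumpyCNN, test_set: LabeledDataset, batch_size: int = 32) -> BlindTestReport:
    """Score the held-out partition once; measure inference time and memory.

    Wall-clock seconds per batch and peak RSS are measured and reported,
    never asserted — they depend on the host.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    x = test_set.model_inputs()
    y = test_set.labels
    t0 = time.perf_counter()
    pred = model.predict(x, batch_size=batch_size)
    elapsed = time.perf_counter() - t0
    n_batches = int(np.ceil(len(y) / batch_size))
    cm = confusion(y, pred)
    cmetrics = class_metrics(cm)
    peak_mb = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss / 1024.0
    return BlindTestReport(
        confusion=cm,
        metrics=cmetrics,
        accuracy=cmetrics.accuracy,
        predictions=pred,
        inference_seconds_per_batch=elapsed / n_batches,
        peak_memory_mb=peak_mb,
    )
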