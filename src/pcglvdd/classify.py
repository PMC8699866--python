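"""CNN classifier, confusion metrics and subject-wise 10-fold cross-validation.

The network takes 128x128x3 spectrogram images through three 3x3 convolution
+ ReLU + 2x2 max-pool blocks (64, 32, 16 channels), a flatten, two fully
connected layers (128 then 100 units, dropout 0.5 after the second) and a
two-class softmax. Training minimizes cross-entropy with Adam at 1e-4.
LVDD is the positive class for sensitivity/specificity.

Cross-validation is subject-wise: subjects (not images) are partitioned
into k folds, so no individual's images can appear in more than one fold
role. Images produced by augmentation inherit the subject of their source
frame; per-class GAN images have no source subject and are restricted to
training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool2d,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .types import CLASSES, CLASS_INDEX, SpectrogramImage, labels_of, stack_pixels

__all__ = [
    "CNNConfig", "CNNParams", "ConfusionCounts", "Metrics", "CVPlan",
    "build_cnn", "train_cnn", "predict", "confusion_metrics",
    "confusion_from_predictions", "make_cv_plan", "run_cross_validation",
]


@dataclass
class CNNConfig:
    """Classifier hyperparameters; image_size 128 reproduces the reference layout."""

    image_size: int = 128
    conv_channels: Tuple[int, int, int] = (64, 32, 16)
    fc_sizes: Tuple[int, int] = (128, 100)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    epochs: int = 500
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.image_size < 8 or (self.image_size & (self.image_size - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 8")


@dataclass
class CNNParams:
    net: Sequential
    cfg: CNNConfig

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_cnn(cfg: CNNConfig) -> CNNParams:
    """Construct the network; layer shapes at 128x128 follow the reference table."""
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    ch_in = 3
    size = cfg.image_size
    for ch_out in cfg.conv_channels:
        layers += [Conv2d(ch_in, ch_out, 3, 1, 1, rng=rng), ReLU(), MaxPool2d()]
        ch_in = ch_out
        size //= 2
    layers.append(Flatten())
    flat = ch_in * size * size
    layers += [Dense(flat, cfg.fc_sizes[0], rng=rng),
               Dense(cfg.fc_sizes[0], cfg.fc_sizes[1], rng=rng),
               Dropout(cfg.dropout),
               Dense(cfg.fc_sizes[1], len(CLASSES), rng=rng)]
    return CNNParams(Sequential(layers), cfg)


def predict(params: CNNParams, images: Sequence[SpectrogramImage],
            batch_size: int = 64) -> Tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels (ties at 0.5 go to the control class)."""
    x = stack_pixels(images)
    if x.shape[2] != params.cfg.image_size:
        raise ValueError("image size does not match the trained network")
    probs = np.empty((x.shape[0], len(CLASSES)), dtype=np.float64)
    for b0 in range(0, x.shape[0], batch_size):
        logits = params.net.forward(x[b0:b0 + batch_size], train=False)
        probs[b0:b0 + batch_size] = softmax(logits)
    labels = (probs[:, CLASS_INDEX["lvdd"]] > 0.5).astype(np.int64)
    return probs, labels


def _accuracy(params: CNNParams, images: Sequence[SpectrogramImage]) -> float:
    _, pred = predict(params, images)
    return float(np.mean(pred == labels_of(images)))


def train_cnn(
    train: Sequence[SpectrogramImage],
    val: Sequence[SpectrogramImage],
    cfg: CNNConfig,
    stop_at_val_accuracy: Optional[float] = None,
) -> Tuple[CNNParams, Dict[str, List[float]]]:
    """Adam/cross-entropy training with per-epoch train/val accuracy trace.

    ``stop_at_val_accuracy`` optionally ends training as soon as validation
    accuracy reaches the given level (training never exceeds ``cfg.epochs``).
    Dropout is active only during training, so prediction is deterministic.
    """
    y_train = labels_of(train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    x_train = stack_pixels(train)
    params = build_cnn(cfg)
    opt = Adam(params.net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    trace: Dict[str, List[float]] = {"loss": [], "train_accuracy": [], "val_accuracy": []}
    n = x_train.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, correct = 0.0, 0
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            logits = params.net.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            params.net.backward(dlogits)
            opt.step()
            ep_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        trace["loss"].append(ep_loss / n)
        trace["train_accuracy"].append(correct / n)
        val_acc = _accuracy(params, val) if len(val) else float("nan")
        trace["val_accuracy"].append(val_acc)
        if stop_at_val_accuracy is not None and val_acc >= stop_at_val_accuracy:
            break
    return params, trace


@dataclass
class ConfusionCounts:
    """Binary confusion counts; LVDD is positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Acc = (TP+TN)/(TP+TN+FP+FN), Se = TP/(TP+FN), Sp = TN/(TN+FP)."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise ZeroDivisionError("accuracy undefined: no samples")
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("specificity undefined: no negative samples")
    return Metrics(
        accuracy=(c.TP + c.TN) / total,
        sensitivity=c.TP / (c.TP + c.FN),
        specificity=c.TN / (c.TN + c.FP),
    )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = CLASS_INDEX["lvdd"]
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_true == pos) & (y_pred == pos))),
        TN=int(np.sum((y_true != pos) & (y_pred != pos))),
        FP=int(np.sum((y_true != pos) & (y_pred == pos))),
        FN=int(np.sum((y_true == pos) & (y_pred != pos))),
    )


@dataclass
class CVPlan:
    """Subject-level fold assignment with rotating test/validation roles."""

    fold_of_subject: Dict[str, int]
    k: int
    seed: int

    def __post_init__(self) -> None:
        folds = set(self.fold_of_subject.values())
        if folds - set(range(self.k)):
            raise ValueError("fold indices out of range")

    def roles(self, repetition: int) -> Tuple[int, int, List[int]]:
        """(test_fold, val_fold, train_folds) for one repetition."""
        test = repetition % self.k
        val = (repetition + 1) % self.k
        train = [f for f in range(self.k) if f not in (test, val)]
        return test, val, train

    def validate(self, images: Sequence[SpectrogramImage]) -> None:
        """Raise if any subject appears without an assignment."""
        for img in images:
            if img.origin != "gan_generated" and img.subject_id not in self.fold_of_subject:
                raise ValueError(f"subject {img.subject_id!r} missing from the CV plan")


def make_cv_plan(samples: Sequence[SpectrogramImage], k: int = 10, seed: int = 0) -> CVPlan:
    """Greedy balanced partition of subjects into ``k`` folds by sample count.

    Assignment is stratified by class (each class's subjects are spread over
    the folds before the next class is placed) so test folds mix classes
    whenever the cohort allows it.
    """
    counts: Dict[str, int] = {}
    label_of: Dict[str, str] = {}
    for img in samples:
        counts[img.subject_id] = counts.get(img.subject_id, 0) + 1
        label_of[img.subject_id] = img.class_label or ""
    if len(counts) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(counts)}")
    rng = np.random.default_rng(seed)
    fold_sizes = np.zeros(k, dtype=np.int64)
    fold_of: Dict[str, int] = {}
    for label in sorted(set(label_of.values())):
        members = [s for s in sorted(counts) if label_of[s] == label]
        perm = rng.permutation(len(members))
        order = sorted(perm, key=lambda i: -counts[members[i]])
        for i in order:
            f = int(np.argmin(fold_sizes))
            fold_of[members[i]] = f
            fold_sizes[f] += counts[members[i]]
    return CVPlan(fold_of, k, seed)


TrainerFn = Callable[[Sequence[SpectrogramImage], Sequence[SpectrogramImage]], CNNParams]


def run_cross_validation(
    real: Sequence[SpectrogramImage],
    extra_train: Sequence[SpectrogramImage],
    cfg: CNNConfig,
    plan: CVPlan,
    trainer: Optional[TrainerFn] = None,
    repetitions: Optional[int] = None,
) -> Dict[str, object]:
    """k-repetition subject-wise cross-validation.

    ``extra_train`` images join only training folds: augmented images whose
    source subject sits in the current test or validation fold raise a
    leakage error; per-class GAN images (no source subject) always train.
    ``trainer`` may replace the default CNN training (used for harness
    tests); it receives (train_images, val_images) and returns a fitted
    :class:`CNNParams`-like object accepted by :func:`predict`.
    """
    plan.validate(real)
    reps = repetitions if repetitions is not None else plan.k
    per_fold: List[Metrics] = []
    for rep in range(reps):
        test_f, val_f, _train_f = plan.roles(rep)
        train_imgs = [im for im in real
                      if plan.fold_of_subject[im.subject_id] not in (test_f, val_f)]
        val_imgs = [im for im in real if plan.fold_of_subject[im.subject_id] == val_f]
        test_imgs = [im for im in real if plan.fold_of_subject[im.subject_id] == test_f]
        for im in extra_train:
            if im.origin == "gan_generated":
                train_imgs.append(im)
                continue
            fold = plan.fold_of_subject.get(im.subject_id)
            if fold is None:
                raise ValueError(f"augmented image with unknown subject {im.subject_id!r}")
            if fold in (test_f, val_f):
                raise ValueError(
                    f"leakage: augmented image of subject {im.subject_id!r} "
                    f"falls in fold {fold} used for evaluation")
            train_imgs.append(im)
        if trainer is not None:
            params = trainer(train_imgs, val_imgs)
        else:
            params, _ = train_cnn(train_imgs, val_imgs, cfg)
        _, pred = predict(params, test_imgs)
        counts = confusion_from_predictions(labels_of(test_imgs), pred)
        per_fold.append(confusion_metrics(counts))

    def mean_sd(vals: List[float]) -> Tuple[float, float]:
        a = np.asarray(vals)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    summary = {}
    for name in ("accuracy", "sensitivity", "specificity"):
        m, s = mean_sd([getattr(f, name) for f in per_fold])
        summary[name] = {"mean": m, "sd": s}
    return {"per_fold": per_fold, "summary": summary}
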