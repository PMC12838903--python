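"""Three-phase training: source pre-training, learning-without-forgetting
adaptation on a small labeled slice of the target subject, and prediction.

Adaptation keeps a frozen copy of the pre-trained network as a *teacher* and
optimizes a *student* that inherits the teacher's feature extractor but gets
a freshly initialized classifier head.  The student's loss is

    L = L_new + λ · L_old

where L_new is the cross-entropy against the true labels of the incremental
samples and L_old is a distillation term: the cross-entropy between the
teacher's and the student's probability rows after both are softened by
raising each entry to the power 1/T and renormalizing (temperature T).
For softmax outputs this softening equals applying softmax to logits/T,
which is how the gradient is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import WindowedDataset
from .network import EmotionNet, NetworkConfig, softmax
from .nn import Adam

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (shared by both phases)."""

    batch_size: int = 128
    learning_rate: float = 1e-3
    pretrain_epochs: int = 100
    incremental_epochs: int = 15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.pretrain_epochs < 1 or self.incremental_epochs < 1:
            raise ValueError("batch size and epoch counts must be >= 1")


@dataclass(frozen=True)
class DistillConfig:
    """LwF hyperparameters: relaxation weight λ and temperature T."""

    lambda_relax: float = 0.1
    temperature: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_relax < 0:
            raise ValueError("lambda_relax must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class TeacherStudent:
    """Frozen teacher plus trainable student."""

    teacher: EmotionNet
    student: EmotionNet
    lwf: DistillConfig = field(default_factory=DistillConfig)


@dataclass
class IncrementalSplit:
    """The labeled adaptation subset and the held-out remainder of one
    target subject."""

    inc: WindowedDataset
    test: WindowedDataset
    inc_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    @property
    def n_inc(self) -> int:
        return len(self.inc)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-probability of the true classes."""
    p = np.clip(probs[np.arange(len(y)), y], _EPS, None)
    return float(-np.log(p).mean())


def temperature_rescale(p: np.ndarray, T: float) -> np.ndarray:
    """Soften probability rows: each entry to the power 1/T, renormalized.
    T = 1 is the identity; the uniform row is a fixed point for every T."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    q = p ** (1.0 / T)
    z = q.sum(axis=-1, keepdims=True)
    if np.any(z <= 0):
        raise ValueError("cannot rescale a zero-sum probability row")
    return q / z


def lwf_loss(
    y_n: np.ndarray, y_o: np.ndarray, y_true: np.ndarray, lwf: DistillConfig
) -> tuple[float, float, float]:
    """(total, L_new, L_old) for student rows ``y_n``, teacher rows ``y_o``
    and integer labels ``y_true``; total = L_new + λ·L_old exactly."""
    y_n = np.asarray(y_n, dtype=np.float64)
    y_o = np.asarray(y_o, dtype=np.float64)
    if y_n.shape != y_o.shape:
        raise ValueError("student and teacher outputs must have equal shapes")
    l_new = cross_entropy(y_n, np.asarray(y_true))
    q = temperature_rescale(y_o, lwf.temperature)
    s = temperature_rescale(y_n, lwf.temperature)
    l_old = float(-(q * np.log(np.clip(s, _EPS, None))).sum(axis=-1).mean())
    return l_new + lwf.lambda_relax * l_old, l_new, l_old


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def pretrain(
    source: WindowedDataset,
    model_config: NetworkConfig,
    train_config: TrainConfig = TrainConfig(),
    *,
    variant_drop: str | None = None,
) -> EmotionNet:
    """Phase 1: minimize mean cross-entropy on the source subjects.

    The returned model carries a per-epoch ``history`` of mean loss and
    training accuracy.  Initialization, shuffling and dropout are all
    functions of ``train_config.seed``.
    """
    classes = np.unique(source.labels)
    if len(classes) < 2:
        raise ValueError(f"source data contains a single class {classes}; cannot pretrain")
    from .network import make_variant

    model = make_variant(model_config, variant_drop, seed=train_config.seed)
    opt = Adam(model.param_refs(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(0x5C,)))
    K = model_config.n_classes
    for epoch in range(train_config.pretrain_epochs):
        losses, correct, seen = [], 0, 0
        for idx in _iter_batches(len(source), train_config.batch_size, rng):
            X, y = source.X[idx], source.labels[idx]
            probs = softmax(model.forward(X, training=True))
            losses.append(cross_entropy(probs, y) * len(idx))
            correct += int((probs.argmax(axis=1) == y).sum())
            seen += len(idx)
            model.backward((probs - one_hot(y, K)) / len(idx))
            opt.step()
        model.history.append(
            {"phase": "pretrain", "epoch": epoch, "loss": sum(losses) / seen, "acc": correct / seen}
        )
    return model


def init_student(
    teacher: EmotionNet, seed: int, lwf: DistillConfig = DistillConfig()
) -> TeacherStudent:
    """Phase 2 setup: the student copies the teacher's feature extractor and
    re-initializes the classifier head."""
    student = teacher.clone()
    student.reinit_head(seed)
    student.history = []
    return TeacherStudent(teacher=teacher, student=student, lwf=lwf)


def select_incremental(
    target: WindowedDataset, fraction: float = 0.02, seed: int = 42
) -> IncrementalSplit:
    """Sample ``ceil(fraction · N)`` windows uniformly without replacement as
    the adaptation set; the remainder is the test set."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(target)
    n_inc = math.ceil(fraction * n)
    if n_inc == 0 or n_inc >= n:
        raise ValueError(f"incremental split of {n_inc}/{n} samples is degenerate")
    rng = np.random.default_rng(seed)
    inc_idx = np.sort(rng.choice(n, size=n_inc, replace=False))
    mask = np.ones(n, dtype=bool)
    mask[inc_idx] = False
    test_idx = np.nonzero(mask)[0]
    return IncrementalSplit(
        inc=target.take(inc_idx),
        test=target.take(test_idx),
        inc_indices=inc_idx,
        test_indices=test_idx,
        seed=seed,
    )


def finetune_lwf(
    pair: TeacherStudent,
    split: IncrementalSplit,
    train_config: TrainConfig = TrainConfig(),
) -> EmotionNet:
    """Phase 2: optimize the student on the incremental samples under the
    LwF loss; the teacher provides distillation targets and is never
    updated.  With λ = 0 this is exactly plain fine-tuning."""
    if split.n_inc == 0:
        raise ValueError("empty incremental set")
    student, teacher, lwf = pair.student, pair.teacher, pair.lwf
    K = student.config.n_classes
    T = lwf.temperature
    batch_size = min(train_config.batch_size, split.n_inc)
    opt = Adam(student.param_refs(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(0xF1,)))
    X, y = split.inc.X, split.inc.labels
    # the frozen teacher's outputs on the fixed incremental set never change
    all_teacher_probs = teacher.predict_proba(X)
    for epoch in range(train_config.incremental_epochs):
        tot, n_seen = 0.0, 0
        for idx in _iter_batches(len(X), batch_size, rng):
            xb, yb = X[idx], y[idx]
            teacher_probs = all_teacher_probs[idx]
            logits = student.forward(xb, training=True)
            probs = softmax(logits)
            total, l_new, l_old = lwf_loss(probs, teacher_probs, yb, lwf)
            # gradient at the logits: power-(1/T) rescaling of softmax rows
            # equals softmax of logits/T
            grad = (probs - one_hot(yb, K)) / len(idx)
            if lwf.lambda_relax > 0:
                soft_student = softmax(logits / T)
                soft_teacher = temperature_rescale(teacher_probs, T)
                grad = grad + (lwf.lambda_relax / T) * (soft_student - soft_teacher) / len(idx)
            student.backward(grad)
            opt.step()
            tot += total * len(idx)
            n_seen += len(idx)
        student.history.append(
            {"phase": "finetune", "epoch": epoch, "loss": tot / n_seen}
        )
    return student


def predict(model: EmotionNet, X: np.ndarray) -> np.ndarray:
    """Phase 3: eval-mode class probabilities."""
    return model.predict_proba(X)
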