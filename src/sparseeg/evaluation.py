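"""Leave-one-subject-out evaluation, metrics, ablations and the
incremental-size sweep.

Each LOSO fold pre-trains on all-but-one subjects, adapts on a small labeled
fraction (default 2%) of the held-out subject and tests on that subject's
remaining windows.  Folds are repeated with per-repeat seed offsets (the
split and the initialization are both re-drawn) and summaries report the
mean ± standard deviation of accuracy and F-score pooled over subjects and
repeats, with per-axis breakdowns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import WindowedDataset
from .lwf import (
    DistillConfig,
    TrainConfig,
    finetune_lwf,
    init_student,
    pretrain,
    select_incremental,
)
from .network import EmotionNet, NetworkConfig


def confusion(pred_labels, true_labels, n_classes: int) -> np.ndarray:
    """K×K confusion matrix; rows are actual classes, columns predicted."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true, pred), 1)
    return cm


def accuracy(pred_labels, true_labels) -> float:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or len(pred) == 0:
        raise ValueError("need equal-length nonempty label vectors")
    return float((pred == true).mean())


def f_score(pred_labels, true_labels, averaging: str = "binary") -> float:
    """F-score TP / (TP + (FP+FN)/2); multiclass is the macro average of
    one-vs-rest binary scores.  A class absent from both truth and
    prediction contributes 0 with a warning."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape or len(pred) == 0:
        raise ValueError("need equal-length nonempty label vectors")

    def binary(pos: int) -> float:
        tp = int(np.sum((pred == pos) & (true == pos)))
        fp = int(np.sum((pred == pos) & (true != pos)))
        fn = int(np.sum((pred != pos) & (true == pos)))
        denom = tp + (fp + fn) / 2.0
        if denom == 0:
            warnings.warn(f"F-score undefined for class {pos} (no positives); returning 0")
            return 0.0
        return tp / denom

    if averaging == "binary":
        return float(binary(1))
    if averaging == "macro":
        classes = np.union1d(np.unique(true), np.unique(pred))
        return float(np.mean([binary(int(k)) for k in classes]))
    raise ValueError(f"unknown averaging {averaging!r}")


@dataclass
class Metrics:
    """Per-fold classification metrics."""

    confusion: np.ndarray
    accuracy: float
    f_score: float
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @staticmethod
    def from_labels(pred_labels, true_labels, n_classes: int) -> "Metrics":
        cm = confusion(pred_labels, true_labels, n_classes)
        acc = accuracy(pred_labels, true_labels)
        avg = "binary" if n_classes == 2 else "macro"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = f_score(pred_labels, true_labels, avg)
        m = Metrics(confusion=cm, accuracy=acc, f_score=f1)
        if n_classes == 2:
            m.tn, m.fp, m.fn, m.tp = (int(cm[0, 0]), int(cm[0, 1]), int(cm[1, 0]), int(cm[1, 1]))
        return m


@dataclass
class FoldResult:
    target_subject: int
    repeat_index: int
    metrics: Metrics
    n_test: int
    source_accuracy: float | None = None


def paired_t(acc_a, acc_b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject accuracies.

    Identical vectors give (0, 1); a nonzero constant difference has zero
    variance and the statistic is undefined, so it raises.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def _seed_for(base_seed: int, subject_id: int, repeat: int) -> int:
    """Per-(subject, repeat) seed: base + repeat offset, subject mixed in."""
    ss = np.random.SeedSequence(base_seed + repeat, spawn_key=(subject_id,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_fold(
    dataset: WindowedDataset,
    target_subject: int,
    model_config: NetworkConfig,
    train_config: TrainConfig,
    lwf_config: DistillConfig,
    repeat: int = 0,
    fraction: float = 0.02,
    *,
    variant_drop: str | None = None,
    teacher: EmotionNet | None = None,
    eval_source: bool = False,
) -> FoldResult:
    """One LOSO fold: pretrain (unless a teacher is supplied), adapt, test."""
    source = dataset.without_subject(target_subject)
    target = dataset.subject(target_subject)
    seed = train_config.seed + repeat
    if teacher is None:
        tc = TrainConfig(
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            pretrain_epochs=train_config.pretrain_epochs,
            incremental_epochs=train_config.incremental_epochs,
            seed=seed,
        )
        teacher = pretrain(source, model_config, tc, variant_drop=variant_drop)
    split_seed = _seed_for(train_config.seed, target_subject, repeat)
    split = select_incremental(target, fraction=fraction, seed=split_seed)
    pair = init_student(teacher, seed=split_seed, lwf=lwf_config)
    ft_config = TrainConfig(
        batch_size=train_config.batch_size,
        learning_rate=train_config.learning_rate,
        pretrain_epochs=train_config.pretrain_epochs,
        incremental_epochs=train_config.incremental_epochs,
        seed=split_seed,
    )
    student = finetune_lwf(pair, split, ft_config)
    pred = student.predict(split.test.X)
    metrics = Metrics.from_labels(pred, split.test.labels, model_config.n_classes)
    src_acc = None
    if eval_source:
        src_acc = accuracy(student.predict(source.X), source.labels)
    return FoldResult(
        target_subject=int(target_subject),
        repeat_index=repeat,
        metrics=metrics,
        n_test=len(split.test),
        source_accuracy=src_acc,
    )


def summarize(folds: list[FoldResult]) -> dict:
    accs = np.array([f.metrics.accuracy for f in folds])
    f1s = np.array([f.metrics.f_score for f in folds])
    subjects = sorted({f.target_subject for f in folds})
    repeats = sorted({f.repeat_index for f in folds})
    by_subject = {
        s: float(np.mean([f.metrics.accuracy for f in folds if f.target_subject == s]))
        for s in subjects
    }
    by_repeat = {
        r: float(np.mean([f.metrics.accuracy for f in folds if f.repeat_index == r]))
        for r in repeats
    }
    return {
        "n_folds": len(folds),
        "accuracy_mean": float(accs.mean()),
        "accuracy_std": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "f_score_mean": float(f1s.mean()),
        "f_score_std": float(f1s.std(ddof=1)) if len(f1s) > 1 else 0.0,
        "accuracy_by_subject": by_subject,
        "accuracy_by_repeat": by_repeat,
    }


def loso(
    dataset: WindowedDataset,
    model_config: NetworkConfig,
    train_config: TrainConfig = TrainConfig(),
    lwf_config: DistillConfig = DistillConfig(),
    repeats: int = 5,
    fraction: float = 0.02,
    *,
    variant_drop: str | None = None,
    no_distill: bool = False,
) -> tuple[list[FoldResult], dict]:
    """Full leave-one-subject-out protocol: M subjects × ``repeats`` folds."""
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if no_distill:
        lwf_config = DistillConfig(lambda_relax=0.0, temperature=lwf_config.temperature)
    folds = [
        run_fold(
            dataset,
            int(s),
            model_config,
            train_config,
            lwf_config,
            repeat=r,
            fraction=fraction,
            variant_drop=variant_drop,
        )
        for s in subjects
        for r in range(repeats)
    ]
    return folds, summarize(folds)


ABLATION_TAGS = ("full", "w/o mtcl", "w/o mscl", "w/o ffl", "w/o lwf")


def ablation_suite(
    dataset: WindowedDataset,
    model_config: NetworkConfig,
    train_config: TrainConfig = TrainConfig(),
    lwf_config: DistillConfig = DistillConfig(),
    repeats: int = 1,
    fraction: float = 0.02,
    variants: tuple[str, ...] = ABLATION_TAGS,
) -> dict[str, dict]:
    """Run LOSO once per model variant; 'w/o lwf' is the λ = 0 arm."""
    table: dict[str, dict] = {}
    for tag in variants:
        drop = None
        no_distill = False
        if tag == "w/o lwf":
            no_distill = True
        elif tag.startswith("w/o "):
            drop = tag.split()[-1]
        elif tag != "full":
            raise ValueError(f"unknown variant tag {tag!r}")
        _, summary = loso(
            dataset,
            model_config,
            train_config,
            lwf_config,
            repeats=repeats,
            fraction=fraction,
            variant_drop=drop,
            no_distill=no_distill,
        )
        table[tag] = summary
    return table


@dataclass
class SweepResult:
    fractions: list[float]
    n_inc: dict[float, int]
    summaries: dict[float, dict]
    baseline_comparisons: dict[float, tuple[float, float]] = field(default_factory=dict)


def sweep_incremental(
    dataset: WindowedDataset,
    model_config: NetworkConfig,
    train_config: TrainConfig = TrainConfig(),
    lwf_config: DistillConfig = DistillConfig(),
    fractions: tuple[float, ...] = (0.005, 0.01, 0.02, 0.03, 0.05),
    repeats: int = 1,
) -> SweepResult:
    """Adaptation-set-size sweep.  Teachers are pre-trained once per
    (subject, repeat) and shared across fractions; the smallest fraction is
    the baseline for the paired-t comparisons."""
    if list(fractions) != sorted(fractions) or not all(0 < f < 1 for f in fractions):
        raise ValueError("fractions must be ascending and strictly inside (0, 1)")
    subjects = [int(s) for s in dataset.subjects]
    teachers: dict[tuple[int, int], EmotionNet] = {}
    for s in subjects:
        source = dataset.without_subject(s)
        for r in range(repeats):
            tc = TrainConfig(
                batch_size=train_config.batch_size,
                learning_rate=train_config.learning_rate,
                pretrain_epochs=train_config.pretrain_epochs,
                incremental_epochs=train_config.incremental_epochs,
                seed=train_config.seed + r,
            )
            teachers[(s, r)] = pretrain(source, model_config, tc)

    import math

    summaries: dict[float, dict] = {}
    n_inc: dict[float, int] = {}
    per_subject_acc: dict[float, np.ndarray] = {}
    for frac in fractions:
        folds = [
            run_fold(
                dataset,
                s,
                model_config,
                train_config,
                lwf_config,
                repeat=r,
                fraction=frac,
                teacher=teachers[(s, r)],
            )
            for s in subjects
            for r in range(repeats)
        ]
        summaries[frac] = summarize(folds)
        n_inc[frac] = math.ceil(frac * len(dataset.subject(subjects[0])))
        per_subject_acc[frac] = np.array(
            [summaries[frac]["accuracy_by_subject"][s] for s in subjects]
        )

    baseline = fractions[0]
    comparisons: dict[float, tuple[float, float]] = {}
    for frac in fractions[1:]:
        try:
            comparisons[frac] = paired_t(per_subject_acc[frac], per_subject_acc[baseline])
        except ValueError:
            comparisons[frac] = (float("nan"), float("nan"))
    return SweepResult(
        fractions=list(fractions),
        n_inc=n_inc,
        summaries=summaries,
        baseline_comparisons=comparisons,
    )
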