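"""Distillation loss arithmetic, split rule, and the three-phase training
contracts (teacher immutability, determinism, λ = 0 reduction)."""

import math

import numpy as np
import pytest

import sparseeg as s
from sparseeg.core import LabelScheme, WindowedDataset
from sparseeg.lwf import (
    DistillConfig,
    TrainConfig,
    _iter_batches,
    cross_entropy,
    finetune_lwf,
    init_student,
    lwf_loss,
    one_hot,
    pretrain,
    select_incremental,
    temperature_rescale,
)
from sparseeg.network import softmax
from sparseeg.nn import Adam


def dummy_dataset(n, n_subjects=1, seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    return WindowedDataset(
        X=rng.random((n, 1, 4)),
        ratings=np.tile([6.0, 4.0], (n, 1)),
        labels=rng.integers(0, n_classes, n),
        subject_ids=np.repeat(np.arange(n_subjects), n // n_subjects),
        trial_ids=np.arange(n),
        window_s=1.0,
        sampling_rate_hz=4.0,
        scheme=LabelScheme(),
    )


class TestTemperatureRescale:
    def test_uniform_fixed_point(self):
        for T in (0.5, 1.0, 2.0, 8.0):
            np.testing.assert_allclose(temperature_rescale([0.5, 0.5], T), [0.5, 0.5])

    def test_worked_example(self):
        np.testing.assert_allclose(temperature_rescale([0.9, 0.1], 2.0), [0.75, 0.25])

    def test_identity_at_unit_temperature(self):
        np.testing.assert_allclose(temperature_rescale([0.9, 0.1], 1.0), [0.9, 0.1])

    def test_matches_softmax_of_scaled_logits(self, rng):
        """Power-(1/T) rescaling of a softmax row equals softmax(logits/T)."""
        z = rng.standard_normal((5, 4))
        T = 2.0
        np.testing.assert_allclose(temperature_rescale(softmax(z), T), softmax(z / T), atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            temperature_rescale([0.5, 0.5], 0.0)
        with pytest.raises(ValueError):
            temperature_rescale([0.0, 0.0], 2.0)
        with pytest.raises(ValueError):
            temperature_rescale([-0.1, 1.1], 2.0)


class TestLwfLoss:
    def test_perfect_prediction_zero_loss(self):
        y_n = np.array([[1.0, 0.0], [0.0, 1.0]])
        total, l_new, l_old = lwf_loss(y_n, y_n, np.array([0, 1]), DistillConfig(0.0, 2.0))
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_uniform_rows_worked_example(self):
        """Uniform teacher and student over 2 classes: total = 1.1·ln 2."""
        u = np.full((3, 2), 0.5)
        total, l_new, l_old = lwf_loss(u, u, np.array([0, 1, 0]), DistillConfig(0.1, 2.0))
        assert l_new == pytest.approx(math.log(2), abs=1e-12)
        assert l_old == pytest.approx(math.log(2), abs=1e-12)
        assert total == pytest.approx(1.1 * math.log(2), abs=1e-10)

    def test_decomposition_exact(self, rng):
        y_n = softmax(rng.standard_normal((8, 4)))
        y_o = softmax(rng.standard_normal((8, 4)))
        y = rng.integers(0, 4, 8)
        lwf = DistillConfig(0.37, 3.0)
        total, l_new, l_old = lwf_loss(y_n, y_o, y, lwf)
        assert total == pytest.approx(l_new + lwf.lambda_relax * l_old, abs=1e-10)

    def test_distillation_term_obeys_gibbs_inequality(self, rng):
        """L_old >= entropy of the rescaled teacher row, equality iff the
        student's rescaled row equals the teacher's."""
        lwf = DistillConfig(1.0, 2.0)
        y_o = softmax(rng.standard_normal((6, 3)))
        q = temperature_rescale(y_o, lwf.temperature)
        entropy = float(-(q * np.log(q)).sum(axis=-1).mean())
        _, _, l_old_self = lwf_loss(y_o, y_o, np.zeros(6, dtype=int), lwf)
        assert l_old_self == pytest.approx(entropy, abs=1e-9)
        y_n = softmax(rng.standard_normal((6, 3)))
        _, _, l_old_other = lwf_loss(y_n, y_o, np.zeros(6, dtype=int), lwf)
        assert l_old_other > entropy


class TestSelectIncremental:
    @pytest.mark.parametrize("n,expected", [(2400, 48), (840, 17), (100, 2)])
    def test_ceiling_rule(self, n, expected):
        split = select_incremental(dummy_dataset(n), 0.02, seed=42)
        assert split.n_inc == expected
        assert len(split.test) == n - expected

    def test_partition_exact(self):
        split = select_incremental(dummy_dataset(50), 0.1, seed=1)
        combined = np.sort(np.concatenate([split.inc_indices, split.test_indices]))
        np.testing.assert_array_equal(combined, np.arange(50))

    def test_same_seed_same_indices(self):
        a = select_incremental(dummy_dataset(100), 0.05, seed=3)
        b = select_incremental(dummy_dataset(100), 0.05, seed=3)
        np.testing.assert_array_equal(a.inc_indices, b.inc_indices)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            select_incremental(dummy_dataset(10), 0.0)
        with pytest.raises(ValueError):
            select_incremental(dummy_dataset(10), 0.95)  # ceil → all samples


@pytest.fixture(scope="module")
def small_training_setup():
    """Shared tiny dataset + config for the training-contract tests."""
    from tests.conftest import make_windowed

    ds = make_windowed(n_subjects=3, n_trials=6, duration_s=6.0, shift_scale=0.5, seed=19)
    cfg = s.NetworkConfig(
        n_channels=4, window_len=100, temporal_filters=8, spatial_filters=5,
        fusion_channels=(5, 6, 7), fusion_pool=(4, 2, 2), hidden=(10, 6),
    )
    tc = TrainConfig(batch_size=32, pretrain_epochs=3, incremental_epochs=5, seed=42)
    return ds, cfg, tc


class TestPretrain:
    def test_deterministic(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        src = ds.without_subject(2)
        assert pretrain(src, cfg, tc).checksum() == pretrain(src, cfg, tc).checksum()

    def test_history_logged(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        model = pretrain(ds.without_subject(2), cfg, tc)
        assert len(model.history) == tc.pretrain_epochs
        assert {"phase", "epoch", "loss", "acc"} <= set(model.history[0])

    def test_single_class_source_rejected(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        idx = np.nonzero(ds.labels == ds.labels[0])[0]
        with pytest.raises(ValueError, match="single class"):
            pretrain(ds.take(idx), cfg, tc)


class TestStudentTeacher:
    def test_student_inherits_features_but_not_head(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        pair = init_student(teacher, seed=7)
        for k, v in pair.student.feature_state().items():
            np.testing.assert_array_equal(v, teacher.feature_state()[k])
        head_t = teacher.head_state()
        changed = [
            k for k, v in pair.student.head_state().items()
            if v.shape == head_t[k].shape and not np.array_equal(v, head_t[k])
        ]
        assert changed  # linear weights freshly drawn

    def test_same_seed_same_student(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        assert init_student(teacher, 7).student.checksum() == init_student(teacher, 7).student.checksum()

    def test_teacher_frozen_through_adaptation(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        before = teacher.checksum()
        split = select_incremental(ds.subject(2), 0.1, seed=5)
        finetune_lwf(init_student(teacher, 5), split, tc)
        assert teacher.checksum() == before

    def test_finetune_reproducible(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        split = select_incremental(ds.subject(2), 0.1, seed=5)
        a = finetune_lwf(init_student(teacher, 5), split, tc).checksum()
        b = finetune_lwf(init_student(teacher, 5), split, tc).checksum()
        assert a == b

    def test_lambda_zero_equals_plain_finetuning(self, small_training_setup):
        """With λ = 0 the LwF update is exactly the supervised fine-tuning
        update: an independent CE-only training loop with the same seeds
        reproduces the parameters bit for bit."""
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        split = select_incremental(ds.subject(2), 0.1, seed=5)

        lwf_student = finetune_lwf(
            init_student(teacher, 5, DistillConfig(lambda_relax=0.0)), split, tc
        )

        plain = init_student(teacher, 5).student
        opt = Adam(plain.param_refs(), lr=tc.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence(tc.seed, spawn_key=(0xF1,)))
        X, y = split.inc.X, split.inc.labels
        bs = min(tc.batch_size, len(X))
        for _ in range(tc.incremental_epochs):
            for idx in _iter_batches(len(X), bs, rng):
                probs = softmax(plain.forward(X[idx], training=True))
                plain.backward((probs - one_hot(y[idx], 2)) / len(idx))
                opt.step()
        assert lwf_student.checksum() == plain.checksum()

    def test_empty_incremental_set_rejected(self, small_training_setup):
        ds, cfg, tc = small_training_setup
        teacher = pretrain(ds.without_subject(2), cfg, tc)
        split = select_incremental(ds.subject(2), 0.1, seed=5)
        split.inc = split.inc.take(np.array([], dtype=int))
        with pytest.raises(ValueError):
            finetune_lwf(init_student(teacher, 5), split, tc)


def test_cross_entropy_matches_hand_computation():
    probs = np.array([[0.7, 0.3], [0.2, 0.8]])
    expected = -(math.log(0.7) + math.log(0.8)) / 2
    assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(expected, abs=1e-12)
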