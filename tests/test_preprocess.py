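"""Preprocessing stages: sample counts, filtering behaviour, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.signal import periodogram

import sparseeg as s
from sparseeg.core import EmotionRating, LabelScheme, RawTrial
from sparseeg.preprocess import (
    bandpass,
    drop_baseline,
    label,
    normalize_window,
    resample,
    run_pipeline,
    select_channels,
    window,
)


def make_trial(n_channels=4, duration_s=4.0, rate=128.0, baseline_s=0.0, data=None, names=None):
    n = round(duration_s * rate)
    if data is None:
        data = np.random.default_rng(0).standard_normal((n_channels, n))
    names = names or tuple(f"CH{i}" for i in range(n_channels))
    return RawTrial(0, 0, data, rate, names, baseline_s, EmotionRating(6, 4))


def sine_trial(freq, duration_s=60.0, rate=512.0, n_channels=4):
    t = np.arange(round(duration_s * rate)) / rate
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return make_trial(n_channels, duration_s, rate, data=data)


class TestDropBaseline:
    @pytest.mark.parametrize(
        "duration,baseline,rate,expected",
        [(63.0, 3.0, 128.0, 7680), (70.0, 10.0, 100.0, 6000)],
    )
    def test_sample_counts(self, duration, baseline, rate, expected):
        t = drop_baseline(make_trial(duration_s=duration, rate=rate, baseline_s=baseline))
        assert t.n_samples == expected
        assert t.baseline_s == 0.0

    def test_keeps_tail(self):
        raw = make_trial(duration_s=2.0, rate=10.0, baseline_s=1.0)
        t = drop_baseline(raw)
        np.testing.assert_array_equal(t.data, raw.data[:, 10:])

    def test_zero_baseline_identity(self):
        raw = make_trial(baseline_s=0.0)
        assert drop_baseline(raw) is raw

    def test_baseline_spanning_trial_rejected(self):
        with pytest.raises(ValueError):
            make_trial(duration_s=2.0, baseline_s=2.0)


class TestResample:
    def test_count_512_to_128(self):
        t = resample(make_trial(duration_s=60.0, rate=512.0), 128.0)
        assert t.n_samples == 7680
        assert t.sampling_rate_hz == 128.0

    def test_identity_rate_bit_equal(self):
        raw = make_trial(rate=128.0)
        assert resample(raw, 128.0) is raw

    def test_tone_survives_decimation(self):
        """A 10 Hz tone stays the dominant periodogram peak after 512→128 Hz."""
        t = resample(sine_trial(10.0), 128.0)
        f, p = periodogram(t.data[0], fs=128.0)
        assert abs(f[np.argmax(p)] - 10.0) < 0.1

    def test_upsampling_disabled(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample(make_trial(rate=100.0), 128.0)
        up = resample(make_trial(duration_s=2.0, rate=100.0), 200.0, allow_upsample=True)
        assert up.n_samples == 400


class TestBandpass:
    def test_stopband_attenuation(self):
        raw = sine_trial(1.0, duration_s=30.0, rate=128.0)
        out = bandpass(raw)
        assert np.sqrt((out.data**2).mean()) < 0.1 * np.sqrt((raw.data**2).mean())

    def test_passband_preserved(self):
        raw = sine_trial(10.0, duration_s=30.0, rate=128.0)
        out = bandpass(raw)
        ratio = np.sqrt((out.data**2).mean()) / np.sqrt((raw.data**2).mean())
        assert 0.9 < ratio < 1.1

    def test_zeros_map_to_zeros(self):
        raw = make_trial(data=np.zeros((4, 512)), duration_s=4.0, rate=128.0)
        np.testing.assert_allclose(bandpass(raw).data, 0.0, atol=1e-12)

    def test_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(make_trial(rate=64.0), 4.0, 45.0)


class TestSelectChannels:
    def test_subset_and_order(self):
        names = tuple(f"E{i}" for i in range(28)) + ("FP1", "FP2", "F3", "F4")
        raw = make_trial(n_channels=32, names=names)
        t = select_channels(raw)
        assert t.channel_names == ("FP1", "FP2", "F3", "F4")
        np.testing.assert_array_equal(t.data, raw.data[[28, 29, 30, 31]])

    def test_identity_order(self):
        raw = make_trial(names=("FP1", "FP2", "F3", "F4"))
        np.testing.assert_array_equal(select_channels(raw).data, raw.data)

    def test_missing_channel_error_lists_available(self):
        with pytest.raises(KeyError, match="CH0"):
            select_channels(make_trial(), ["FP1"])


class TestWindow:
    @pytest.mark.parametrize("rate,flen", [(128.0, 128), (100.0, 100)])
    def test_sixty_windows_per_minute(self, rate, flen):
        wins = window(make_trial(duration_s=60.0, rate=rate))
        assert len(wins) == 60
        assert all(w.shape == (4, flen) for w in wins)

    def test_short_trial_yields_nothing(self):
        assert window(make_trial(duration_s=0.5, rate=128.0)) == []

    def test_trailing_partial_window_discarded(self):
        wins = window(make_trial(duration_s=2.5, rate=100.0))
        assert len(wins) == 2

    def test_overlap(self):
        wins = window(make_trial(duration_s=2.0, rate=100.0), window_s=1.0, overlap_s=0.5)
        assert len(wins) == 3


class TestNormalize:
    def test_affine_endpoints(self):
        np.testing.assert_allclose(normalize_window(np.array([[2.0, 4.0, 6.0]])), [[0, 0.5, 1]])

    def test_constant_channel_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_window(np.full((1, 3), 3.0)), [[0, 0, 0]])

    def test_nonconstant_channels_span_unit_interval(self, rng):
        w = normalize_window(rng.standard_normal((4, 128)))
        np.testing.assert_allclose(w.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(w.max(axis=1), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        w = normalize_window(rng.standard_normal((4, 32)))
        np.testing.assert_allclose(normalize_window(w), w, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            (3, 16),
            elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
        )
    )
    def test_output_always_bounded(self, w):
        out = normalize_window(w)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestLabel:
    @pytest.mark.parametrize(
        "valence,arousal,mode,expected",
        [
            (3.2, 7.0, "binary_valence", 0),
            (6.0, 2.0, "binary_valence", 1),
            (6.0, 2.0, "binary_arousal", 0),
            (5.0, 5.0, "binary_valence", 1),  # ties go high
            (5.0, 5.0, "quadrant", 3),  # HVHA
            (7.0, 2.0, "quadrant", 2),  # HVLA
            (2.0, 7.0, "quadrant", 1),  # LVHA
            (2.0, 2.0, "quadrant", 0),  # LVLA
        ],
    )
    def test_examples(self, valence, arousal, mode, expected):
        assert label(EmotionRating(valence, arousal), LabelScheme(mode)) == expected

    def test_quadrant_names_order(self):
        assert LabelScheme("quadrant").class_names() == ("LVLA", "LVHA", "HVLA", "HVHA")

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            EmotionRating(9.5, 5.0)


class TestPipeline:
    def test_windows_per_trial_and_labels(self):
        raw = s.simulate_dataset(2, 3, duration_s=63.0, baseline_s=3.0, rate_hz=128.0, seed=3)
        ds = run_pipeline(raw, profile="deap_like", scheme=LabelScheme("binary_valence"))
        assert len(ds) == 2 * 3 * 60
        assert ds.X.shape == (360, 4, 128)
        assert ds.X.min() >= 0.0 and ds.X.max() <= 1.0
        # labels follow the ratings of their trials
        for t in raw:
            mask = (ds.subject_ids == t.subject_id) & (ds.trial_ids == t.trial_id)
            assert mask.sum() == 60
            assert np.all(ds.labels[mask] == int(t.rating.valence >= 5))

    def test_deterministic(self):
        raw = s.simulate_dataset(1, 2, 5.0, 1.0, 100.0, seed=3)
        p = s.preprocess.Profile("custom", 100.0, 2, 5.0, 1.0)
        a = run_pipeline(raw, p)
        b = run_pipeline(raw, p)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_stage_error_annotated_with_trial(self):
        bad = make_trial(duration_s=4.0, rate=64.0)  # 45 Hz edge >= 32 Hz Nyquist
        with pytest.raises(ValueError, match="subject 0 trial 0"):
            run_pipeline([bad], s.preprocess.Profile("custom", 64.0, 1, 4.0, 0.0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([], "deap_like")
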