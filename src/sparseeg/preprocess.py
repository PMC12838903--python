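"""Raw trials → normalized, windowed, labeled samples.

Stage order of the full pipeline: resample → drop baseline → 4–45 Hz
Butterworth bandpass (zero phase) → prefrontal channel selection → 1-s
non-overlapping windows → per-channel min–max normalization to [0, 1] →
rating-derived class labels.

Two geometry profiles are provided: ``deap_like`` (40 × 63 s trials, 3 s
baseline, 128 Hz target rate) and ``eppvr_like`` (14 × 70 s trials, 10 s
baseline, 100 Hz target rate); both yield 60 one-second windows per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .core import PREFRONTAL_CHANNELS, EmotionRating, LabelScheme, RawTrial, WindowedDataset


@dataclass(frozen=True)
class Profile:
    """Geometry of a recording campaign."""

    name: str
    target_rate_hz: float
    n_trials: int
    duration_s: float
    baseline_s: float


PROFILES = {
    "deap_like": Profile("deap_like", 128.0, 40, 63.0, 3.0),
    "eppvr_like": Profile("eppvr_like", 100.0, 14, 70.0, 10.0),
}


def drop_baseline(trial: RawTrial) -> RawTrial:
    """Remove the leading baseline segment, keeping the tail."""
    if trial.baseline_s == 0:
        return trial
    if trial.baseline_s >= trial.duration_s:
        raise ValueError("baseline covers the whole trial")
    n_base = round(trial.baseline_s * trial.sampling_rate_hz)
    return trial.with_data(trial.data[:, n_base:], baseline_s=0.0)


def resample(trial: RawTrial, target_rate_hz: float, *, allow_upsample: bool = False) -> RawTrial:
    """Anti-aliased polyphase resampling to ``target_rate_hz``.

    Upsampling is disabled by default — the pipeline only ever reduces the
    rate — and the identity rate returns the trial unchanged.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if target_rate_hz == trial.sampling_rate_hz:
        return trial
    if target_rate_hz > trial.sampling_rate_hz and not allow_upsample:
        raise ValueError(
            f"upsampling {trial.sampling_rate_hz} → {target_rate_hz} Hz is disabled"
        )
    ratio = Fraction(target_rate_hz / trial.sampling_rate_hz).limit_denominator(1000)
    out = resample_poly(trial.data, ratio.numerator, ratio.denominator, axis=1)
    n_target = round(trial.duration_s * target_rate_hz)
    out = out[:, :n_target]
    return trial.with_data(out, sampling_rate_hz=target_rate_hz)


def bandpass(trial: RawTrial, low_hz: float = 4.0, high_hz: float = 45.0, order: int = 4) -> RawTrial:
    """Butterworth bandpass of the stated design order, applied forward and
    backward (zero phase)."""
    nyq = trial.sampling_rate_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist rate {nyq}")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=trial.sampling_rate_hz, output="sos")
    return trial.with_data(sosfiltfilt(sos, trial.data, axis=1))


def select_channels(trial: RawTrial, names: Sequence[str] = PREFRONTAL_CHANNELS) -> RawTrial:
    """Reorder/subset channels to ``names``."""
    names = tuple(names)
    missing = [n for n in names if n not in trial.channel_names]
    if missing:
        raise KeyError(
            f"channels {missing} not present; available: {list(trial.channel_names)}"
        )
    idx = [trial.channel_names.index(n) for n in names]
    return trial.with_data(trial.data[idx], channel_names=names)


def window(trial: RawTrial, window_s: float = 1.0, overlap_s: float = 0.0) -> list[np.ndarray]:
    """Slice the trial into fixed-length windows; a trailing partial window
    is discarded.  A trial shorter than one window yields an empty list."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if overlap_s >= window_s:
        raise ValueError("overlap_s must be shorter than window_s")
    win_len = round(window_s * trial.sampling_rate_hz)
    step = win_len - round(overlap_s * trial.sampling_rate_hz)
    n = trial.n_samples
    return [trial.data[:, s : s + win_len] for s in range(0, n - win_len + 1, step)]


def normalize_window(w: np.ndarray) -> np.ndarray:
    """Per-channel min–max scaling to [0, 1]; a constant channel maps to 0."""
    w = np.asarray(w, dtype=np.float64)
    lo = w.min(axis=-1, keepdims=True)
    hi = w.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(w)
    np.divide(w - lo, span, out=out, where=span > 0)
    return out


def label(rating: EmotionRating, scheme: LabelScheme) -> int:
    """Class index of a rating under ``scheme`` (ties at the threshold are
    high, matching the quadrant convention)."""
    thr = scheme.threshold
    hi_v = rating.valence >= thr
    hi_a = rating.arousal >= thr
    if scheme.mode == "binary_valence":
        return int(hi_v)
    if scheme.mode == "binary_arousal":
        return int(hi_a)
    return 2 * int(hi_v) + int(hi_a)  # LVLA=0, LVHA=1, HVLA=2, HVHA=3


def run_pipeline(
    trials: Iterable[RawTrial],
    profile: str | Profile = "deap_like",
    scheme: LabelScheme | None = None,
    *,
    channels: Sequence[str] = PREFRONTAL_CHANNELS,
    window_s: float = 1.0,
) -> WindowedDataset:
    """Full preprocessing pipeline over a trial collection."""
    if isinstance(profile, str):
        profile = PROFILES[profile]
    scheme = scheme or LabelScheme()
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to preprocess")

    xs, ratings, labels, sids, tids = [], [], [], [], []
    for trial in trials:
        try:
            t = resample(trial, profile.target_rate_hz)
            t = drop_baseline(t)
            t = bandpass(t)
            t = select_channels(t, channels)
            wins = window(t, window_s=window_s)
        except Exception as exc:  # annotate with trial identity
            raise type(exc)(
                f"subject {trial.subject_id} trial {trial.trial_id}: {exc}"
            ) from exc
        y = label(trial.rating, scheme)
        for w in wins:
            xs.append(normalize_window(w))
            ratings.append((trial.rating.valence, trial.rating.arousal))
            labels.append(y)
            sids.append(trial.subject_id)
            tids.append(trial.trial_id)

    return WindowedDataset(
        X=np.stack(xs),
        ratings=np.asarray(ratings),
        labels=np.asarray(labels),
        subject_ids=np.asarray(sids),
        trial_ids=np.asarray(tids),
        window_s=window_s,
        sampling_rate_hz=profile.target_rate_hz,
        scheme=scheme,
    )
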