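"""Synthetic sparse-channel EEG with a known affective class structure.

The generator emulates the statistical features the downstream pipeline
relies on, without attempting physiological realism:

* four prefrontal channels (FP1, FP2, F3, F4);
* band-limited oscillations at theta/alpha/beta/gamma centre frequencies
  (6, 10, 20, 35 Hz by default), all inside the 4–45 Hz analysis band;
* a frontal alpha-asymmetry valence code: the alpha amplitude difference
  between F4 and F3 grows monotonically with (valence − 5);
* an arousal code: total beta+gamma amplitude grows with (arousal − 5);
* a leading baseline segment carrying no class-conditional effect;
* per-subject distribution shift (channel gains, centre-frequency jitter,
  asymmetry slope) controlled by a single ``shift_scale`` knob;
* 1/f background plus additive white noise.

Everything is a pure function of its seed: trial seeds are derived from
``(seed, subject_id, trial_id)`` through ``numpy.random.SeedSequence`` spawn
keys, so any trial can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PREFRONTAL_CHANNELS, EmotionRating, RawTrial

BAND_NAMES = ("theta", "alpha", "beta", "gamma")
BAND_CENTERS_HZ = (6.0, 10.0, 20.0, 35.0)
#: base sinusoid amplitudes per band (arbitrary units); alpha dominates so the
#: asymmetry code is recoverable from 1-s windows
BAND_AMPLITUDES = (3.0, 5.0, 2.5, 1.5)

ALPHA_BAND_HZ = (8.0, 13.0)
BETA_GAMMA_BAND_HZ = (14.0, 45.0)

DEFAULT_NOISE_SD = 1.0
DEFAULT_PINK_SCALE = 1.0

#: slope of the valence → alpha-asymmetry map and arousal → beta/gamma map,
#: per rating point away from the midpoint 5
_VALENCE_SLOPE = 0.15
_AROUSAL_SLOPE = 0.10
_MOD_CLIP = 0.9

# per-unit-shift spreads of the subject-level perturbations
_GAIN_SD = 0.15
_JITTER_SD_HZ = 0.5
_ASYMMETRY_SD = 0.3
#: resting-asymmetry offsets follow a designed, sign-balanced grid (cycled by
#: subject id) plus seeded jitter, so any simulated population exhibits the
#: inter-subject heterogeneity the benchmark is about
_ASYMMETRY_OFFSET_LEVELS = (0.45, -0.45, 0.225, -0.225)
_ASYMMETRY_OFFSET_JITTER_SD = 0.1


@dataclass(frozen=True)
class SubjectSpec:
    """Deterministic description of one simulated subject.

    All shift-related deviations (gains from 1, jitter from 0, asymmetry gain
    from 1) are proportional to the ``shift_scale`` used to draw the spec.
    """

    subject_id: int
    channel_gains: tuple[float, ...]
    freq_jitter_hz: tuple[float, ...]
    asymmetry_gain: float
    asymmetry_offset: float
    noise_sd: float
    pink_noise_scale: float
    rng_seed: int

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.channel_gains):
            raise ValueError("channel_gains must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_subject(
    subject_id: int,
    shift_scale: float,
    seed: int,
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    pink_noise_scale: float = DEFAULT_PINK_SCALE,
) -> SubjectSpec:
    """Draw a subject whose deviation from the canonical subject scales with
    ``shift_scale``.  ``shift_scale=0`` gives unit gains, zero jitter and unit
    asymmetry gain exactly.
    """
    if shift_scale < 0:
        raise ValueError("shift_scale must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_id,)))
    # raw standard-normal draws, clipped so gains stay positive for any
    # shift_scale <= 2; the deviation itself stays proportional to shift_scale
    z_gain = np.clip(rng.standard_normal(len(PREFRONTAL_CHANNELS)), -3.0, 3.0)
    z_jit = np.clip(rng.standard_normal(len(BAND_CENTERS_HZ)), -3.0, 3.0)
    z_asym = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    z_off = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return SubjectSpec(
        subject_id=subject_id,
        channel_gains=tuple(1.0 + shift_scale * _GAIN_SD * z_gain),
        freq_jitter_hz=tuple(shift_scale * _JITTER_SD_HZ * z_jit),
        asymmetry_gain=1.0 + shift_scale * _ASYMMETRY_SD * z_asym,
        asymmetry_offset=shift_scale
        * (
            _ASYMMETRY_OFFSET_LEVELS[subject_id % len(_ASYMMETRY_OFFSET_LEVELS)]
            + _ASYMMETRY_OFFSET_JITTER_SD * z_off
        ),
        noise_sd=noise_sd,
        pink_noise_scale=pink_noise_scale,
        rng_seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """1/f background via spectral shaping, flattened below 1 Hz so the
    out-of-band (sub-1 Hz) share stays small; normalized to unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _class_modulation(rating: EmotionRating, effect_size: float, subject: SubjectSpec):
    """(alpha asymmetry d, beta/gamma gain g) for the active segment.

    ``d`` combines the class-conditional valence code (scaled by the
    subject's asymmetry gain) with the subject's resting asymmetry offset;
    only the former vanishes at effect_size = 0 or valence = 5."""
    d = np.clip(
        _VALENCE_SLOPE * (rating.valence - 5.0) * effect_size * subject.asymmetry_gain
        + subject.asymmetry_offset,
        -_MOD_CLIP,
        _MOD_CLIP,
    )
    g = np.clip(_AROUSAL_SLOPE * (rating.arousal - 5.0) * effect_size, -_MOD_CLIP, _MOD_CLIP)
    return float(d), float(g)


def simulate_trial(
    subject: SubjectSpec,
    rating: EmotionRating,
    duration_s: float = 63.0,
    baseline_s: float = 3.0,
    rate_hz: float = 128.0,
    seed: int = 0,
    *,
    trial_id: int = 0,
    effect_size: float = 1.0,
) -> RawTrial:
    """Simulate one trial for ``subject``.

    The baseline segment (first ``baseline_s`` seconds) carries the band
    oscillations at their class-neutral amplitudes; the class-conditional
    amplitude modulation applies only after the baseline.
    """
    if not (duration_s > baseline_s >= 0):
        raise ValueError("need duration_s > baseline_s >= 0")
    max_f = max(c + abs(j) for c, j in zip(BAND_CENTERS_HZ, subject.freq_jitter_hz))
    if rate_hz <= 2.0 * max_f:
        raise ValueError(
            f"sampling rate {rate_hz} Hz too low for band content up to {max_f:.1f} Hz"
        )
    rng = np.random.default_rng(seed)
    n = round(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    active = t >= baseline_s
    d, g = _class_modulation(rating, effect_size, subject)
    # the resting asymmetry offset is a subject trait, present in the
    # baseline too; only the class-conditional part switches on after it
    d_base = float(np.clip(subject.asymmetry_offset, -_MOD_CLIP, _MOD_CLIP))

    data = np.zeros((len(PREFRONTAL_CHANNELS), n))
    for ci, ch in enumerate(PREFRONTAL_CHANNELS):
        x = np.zeros(n)
        for band, center, amp in zip(BAND_NAMES, BAND_CENTERS_HZ, BAND_AMPLITUDES):
            f = center + subject.freq_jitter_hz[BAND_NAMES.index(band)]
            phase = rng.uniform(0.0, 2.0 * np.pi)
            mod = base_mod = 1.0
            if band == "alpha":
                if ch == "F3":
                    mod, base_mod = 1.0 - d, 1.0 - d_base
                elif ch == "F4":
                    mod, base_mod = 1.0 + d, 1.0 + d_base
            elif band in ("beta", "gamma"):
                mod = 1.0 + g
            amplitude = np.where(active, amp * mod, amp * base_mod)
            x += amplitude * np.sin(2.0 * np.pi * f * t + phase)
        x += subject.pink_noise_scale * _pink_noise(rng, n, rate_hz)
        if subject.noise_sd > 0:
            x += rng.normal(0.0, subject.noise_sd, n)
        data[ci] = subject.channel_gains[ci] * x

    return RawTrial(
        subject_id=subject.subject_id,
        trial_id=trial_id,
        data=data,
        sampling_rate_hz=rate_hz,
        channel_names=PREFRONTAL_CHANNELS,
        baseline_s=baseline_s,
        rating=rating,
    )


def _draw_rating(rng: np.random.Generator, avoid_boundary: bool) -> float:
    """Uniform over [1, 4.5] ∪ [5.5, 9] (default) or uniform over [1, 9]."""
    if not avoid_boundary:
        return float(rng.uniform(1.0, 9.0))
    u = rng.uniform(0.0, 7.0)
    return float(1.0 + u if u < 3.5 else 2.0 + u)


def _trial_seed(seed: int, subject_id: int, trial_id: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(subject_id, trial_id))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_dataset(
    n_subjects: int = 32,
    n_trials: int = 40,
    duration_s: float = 63.0,
    baseline_s: float = 3.0,
    rate_hz: float = 128.0,
    shift_scale: float = 1.0,
    effect_size: float = 1.0,
    seed: int = 42,
    *,
    avoid_boundary: bool = True,
    noise_sd: float = DEFAULT_NOISE_SD,
    pink_noise_scale: float = DEFAULT_PINK_SCALE,
) -> list[RawTrial]:
    """Simulate a full multi-subject recording campaign.

    Ratings are drawn uniformly over the low/high halves of both scales
    (skipping the ambiguous neighbourhood of 5 unless ``avoid_boundary`` is
    False), so both classes are covered.  Defaults mirror a 32-subject,
    40-trial, 63-s campaign at 128 Hz with a 3-s baseline.
    """
    if n_subjects <= 0 or n_trials <= 0:
        raise ValueError("subject and trial counts must be positive")
    rating_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xA11CE,)))
    trials: list[RawTrial] = []
    for sid in range(n_subjects):
        spec = make_subject(
            sid, shift_scale, seed, noise_sd=noise_sd, pink_noise_scale=pink_noise_scale
        )
        for tid in range(n_trials):
            rating = EmotionRating(
                valence=_draw_rating(rating_rng, avoid_boundary),
                arousal=_draw_rating(rating_rng, avoid_boundary),
            )
            trials.append(
                simulate_trial(
                    spec,
                    rating,
                    duration_s=duration_s,
                    baseline_s=baseline_s,
                    rate_hz=rate_hz,
                    seed=_trial_seed(seed, sid, tid),
                    trial_id=tid,
                    effect_size=effect_size,
                )
            )
    return trials


def alpha_asymmetry_statistic(trial_or_window: np.ndarray, rate_hz: float) -> float:
    """Oracle statistic: alpha-band periodogram power of F4 minus F3.

    Operates on a ``(4, n)`` array in the canonical channel order; used by
    tests as an implementation-independent readout of the valence code.
    """
    from scipy.signal import periodogram

    x = np.asarray(trial_or_window)
    freqs, p = periodogram(x, fs=rate_hz)
    band = (freqs >= ALPHA_BAND_HZ[0]) & (freqs <= ALPHA_BAND_HZ[1])
    f3 = p[PREFRONTAL_CHANNELS.index("F3")][band].sum()
    f4 = p[PREFRONTAL_CHANNELS.index("F4")][band].sum()
    return float(f4 - f3)
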