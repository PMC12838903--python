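"""Core data containers shared across the pipeline.

A recording session is a collection of :class:`RawTrial` objects — continuous
multi-channel EEG segments with a self-assessed :class:`EmotionRating`
(valence and arousal, each on the standard 1–9 scale).  Preprocessing turns
trials into a :class:`WindowedDataset` of fixed-length samples with integer
class labels derived from the ratings via a :class:`LabelScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PREFRONTAL_CHANNELS = ("FP1", "FP2", "F3", "F4")

#: class order of the four-quadrant valence/arousal scheme
QUADRANT_NAMES = ("LVLA", "LVHA", "HVLA", "HVHA")


@dataclass(frozen=True)
class EmotionRating:
    """Self-assessed valence and arousal, each in [1, 9]."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"{name}={v!r} outside the 1–9 rating scale")


@dataclass
class RawTrial:
    """One trial of continuous multi-channel EEG.

    ``data`` has shape ``(n_channels, n_samples)`` in arbitrary amplitude
    units.  ``baseline_s`` seconds of pre-stimulus baseline lead the trial.
    """

    subject_id: int
    trial_id: int
    data: np.ndarray
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    baseline_s: float
    rating: EmotionRating

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.baseline_s < 0:
            raise ValueError("baseline_s must be nonnegative")
        if self.baseline_s >= self.duration_s and self.data.shape[1] > 0:
            raise ValueError("baseline_s must be shorter than the trial")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def with_data(self, data: np.ndarray, **changes) -> "RawTrial":
        """Copy of the trial with replaced signal array (and optional fields)."""
        return replace(self, data=np.asarray(data, dtype=np.float64), **changes)


@dataclass(frozen=True)
class LabelScheme:
    """Maps a rating to a class index.

    ``binary_valence`` / ``binary_arousal`` threshold one dimension into
    low (0) / high (1); ``quadrant`` combines both into the four classes
    LVLA (0), LVHA (1), HVLA (2), HVHA (3).  A rating equal to the threshold
    counts as high, matching the quadrant definitions (>= 5).
    """

    mode: str = "binary_valence"
    threshold: float = 5.0

    _MODES = ("binary_valence", "binary_arousal", "quadrant")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown label mode {self.mode!r}; choose from {self._MODES}")

    @property
    def n_classes(self) -> int:
        return 4 if self.mode == "quadrant" else 2

    def class_names(self) -> tuple[str, ...]:
        if self.mode == "quadrant":
            return QUADRANT_NAMES
        return ("low", "high")


@dataclass
class WindowedDataset:
    """Stacked fixed-length EEG samples ready for the classifier.

    ``X`` has shape ``(n, c, f)`` with every entry in [0, 1] after per-channel
    min–max normalization.  ``ratings`` is ``(n, 2)`` as (valence, arousal).
    """

    X: np.ndarray
    ratings: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    window_s: float
    sampling_rate_hz: float
    scheme: LabelScheme = field(default_factory=LabelScheme)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        n = self.X.shape[0]
        for name in ("ratings", "labels", "subject_ids", "trial_ids"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match X ({n} samples)")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def window_len(self) -> int:
        return self.X.shape[2]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def take(self, idx: np.ndarray | Sequence[int]) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            X=self.X[idx],
            ratings=self.ratings[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            trial_ids=self.trial_ids[idx],
            window_s=self.window_s,
            sampling_rate_hz=self.sampling_rate_hz,
            scheme=self.scheme,
        )

    def subject(self, subject_id: int) -> "WindowedDataset":
        return self.take(np.nonzero(self.subject_ids == subject_id)[0])

    def without_subject(self, subject_id: int) -> "WindowedDataset":
        return self.take(np.nonzero(self.subject_ids != subject_id)[0])

    @staticmethod
    def concatenate(parts: Sequence["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return WindowedDataset(
            X=np.concatenate([p.X for p in parts]),
            ratings=np.concatenate([p.ratings for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            trial_ids=np.concatenate([p.trial_ids for p in parts]),
            window_s=first.window_s,
            sampling_rate_hz=first.sampling_rate_hz,
            scheme=first.scheme,
        )
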