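"""Core data model: EEG recordings, sedation-score events, cohort metadata.

A :class:`Recording` holds a channels-by-samples matrix in microvolts, the
sampling rate, normalized 10-20 channel labels, a sorted list of MOAA/S
(Modified Observer's Assessment of Alertness/Sedation) events, and optional
cohort metadata (drug regimen, remifentanil flag, age, sex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AnnotationError, ChannelError

DRUGS = ("propofol", "sevoflurane", "dexmedetomidine")
SEXES = ("male", "female")

#: Electrodes the downstream pipeline requires (frontal bipolar montage).
REQUIRED_CHANNELS = ("Fp1", "F7", "Fp2", "F8")

_CANONICAL_1020 = [
    "Fp1", "Fp2", "Fpz", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6", "T7", "T8",
    "P3", "P4", "P7", "P8", "Pz", "O1", "O2", "Oz", "A1", "A2",
]
_CANONICAL_LOOKUP = {name.lower(): name for name in _CANONICAL_1020}


def normalize_channel_label(label: str) -> str:
    """Map a channel label to its canonical 10-20 capitalization.

    Matching is case-insensitive ("FP1" -> "Fp1"); labels outside the 10-20
    set are stripped of whitespace but otherwise returned unchanged.
    Idempotent by construction.
    """
    key = label.strip().lower()
    return _CANONICAL_LOOKUP.get(key, label.strip())


@dataclass(frozen=True)
class MOAASEvent:
    """One MOAA/S assessment: time (s from recording start) and score 0-5."""

    time_s: float
    score: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.score) <= 5):
            raise AnnotationError(
                f"MOAA/S score must be in 0..5, got {self.score}"
            )
        if self.time_s < 0:
            raise AnnotationError(f"event time must be >= 0, got {self.time_s}")


@dataclass(frozen=True)
class CohortMeta:
    """Per-recording cohort covariates."""

    drug: str
    remifentanil: bool
    age_years: float
    sex: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise AnnotationError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.sex not in SEXES:
            raise AnnotationError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if not (18 <= self.age_years <= 70):
            warnings.warn(
                f"age_years={self.age_years} outside the 18-70 y cohort range",
                stacklevel=2,
            )

    def as_dict(self) -> dict:
        return {
            "drug": self.drug,
            "remifentanil": bool(self.remifentanil),
            "age_years": float(self.age_years),
            "sex": self.sex,
            "subject_id": self.subject_id,
        }


@dataclass
class Recording:
    """A continuous multi-channel EEG recording in microvolts."""

    id: str
    signal: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: list[str]
    events: list[MOAASEvent] = field(default_factory=list)
    meta: CohortMeta | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ChannelError("signal must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise AnnotationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = [normalize_channel_label(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ChannelError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ChannelError("channel labels must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise AnnotationError("signal contains non-finite samples")
        for ev in self.events:
            if ev.time_s > self.duration_s:
                raise AnnotationError(
                    f"event at {ev.time_s} s beyond recording end {self.duration_s} s"
                )
        self.events = sorted(self.events, key=lambda e: e.time_s)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by (normalized) label."""
        label = normalize_channel_label(label)
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ChannelError(f"channel {label!r} not present") from None
        return self.signal[idx]

    def require_channels(self, labels=REQUIRED_CHANNELS) -> None:
        """Raise :class:`ChannelError` naming every absent required label."""
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise ChannelError(f"missing required channel(s): {', '.join(missing)}")

    def with_signal(self, signal: np.ndarray, fs=None, channel_labels=None) -> "Recording":
        """Copy with a replaced signal (and optionally fs / labels)."""
        return replace(
            self,
            signal=signal,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels if channel_labels is None else channel_labels),
        )
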