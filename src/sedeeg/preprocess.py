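"""Raw recording -> labeled, artifact-screened 4-s epochs.

Pipeline order: frontal bipolar re-reference (Fp1-F7, Fp2-F8), zero-phase
second-order Butterworth band-pass 0.5-25 Hz, polyphase resampling to
250 Hz, one-minute pre-assessment segments labeled awake (MOAA/S 5, 4) or
sedated (MOAA/S 1, 0), division into fifteen non-overlapping 4-s epochs,
and amplitude/flat artifact rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SamplingError
from .recording import CohortMeta, Recording

log = logging.getLogger(__name__)

#: MOAA/S score -> binary label; scores 2 and 3 are discarded.
LABEL_MAP = {0: "sedated", 1: "sedated", 4: "awake", 5: "awake"}

BIPOLAR_PAIRS = (("Fp1", "F7"), ("Fp2", "F8"))
BIPOLAR_LABELS = ["Fp1-F7", "Fp2-F8"]


@dataclass(frozen=True)
class PreprocessConfig:
    band_hz: tuple = (0.5, 25.0)
    filter_order: int = 2
    fs_target_hz: float = 250.0
    segment_s: float = 60.0
    epoch_s: float = 4.0
    amp_reject_uv: float = 500.0
    flat_reject: bool = True
    #: peak |x| below which a channel counts as flat over a whole epoch.
    #: Zero-phase IIR filtering never preserves exact zeros, so "0 uV"
    #: is detected as sub-threshold rather than bit-exact zero.
    flat_eps_uv: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError(f"band_hz must be increasing and positive, got {self.band_hz}")
        if hi >= self.fs_target_hz / 2:
            raise ConfigError("band high edge must be below the target Nyquist frequency")
        if self.segment_s % self.epoch_s != 0:
            raise ConfigError("segment_s must be divisible by epoch_s")

    @property
    def epochs_per_segment(self) -> int:
        return int(self.segment_s / self.epoch_s)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.fs_target_hz))


@dataclass
class Epoch:
    """One 4-s, 250-Hz slab of the two bipolar channels with its label."""

    data: np.ndarray  # (2, samples_per_epoch), microvolts
    label: str
    recording_id: str
    segment_index: int
    epoch_index: int
    meta: CohortMeta | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.label not in ("awake", "sedated"):
            raise ConfigError(f"epoch label must be awake/sedated, got {self.label!r}")


def make_bipolar(recording: Recording) -> Recording:
    """Re-reference to the frontal bipolar montage Fp1-F7 and Fp2-F8."""
    recording.require_channels()
    chans = [recording.channel(a) - recording.channel(b) for a, b in BIPOLAR_PAIRS]
    return recording.with_signal(np.vstack(chans), channel_labels=BIPOLAR_LABELS)


def filter_resample(recording: Recording, config: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Zero-phase Butterworth band-pass, then polyphase resample to 250 Hz.

    The forward-backward (filtfilt) application doubles the effective filter
    order but has exactly zero group delay. Resampling uses anti-aliased
    polyphase decimation even though the 25 Hz band edge already suppresses
    aliasing.
    """
    lo, hi = config.band_hz
    if recording.fs < 2 * hi:
        raise SamplingError(
            f"fs={recording.fs} Hz too low for a {hi} Hz band edge (need >= {2 * hi})"
        )
    sos = sps.butter(config.filter_order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)

    if abs(recording.fs - config.fs_target_hz) < 1e-9:
        out, fs_out = filtered, recording.fs
    else:
        frac = Fraction(config.fs_target_hz / recording.fs).limit_denominator(10000)
        out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
        fs_out = recording.fs * frac.numerator / frac.denominator
    return recording.with_signal(out, fs=fs_out)


def extract_segments(recording: Recording, config: PreprocessConfig = PreprocessConfig()):
    """Emit the one-minute window [t-60, t) before each scorable assessment.

    Scores 2 and 3 are discarded; events earlier than one segment length
    into the recording are skipped with a logged warning. Windows are
    half-open: the sample at the assessment instant is excluded.
    """
    fs = recording.fs
    n_seg = int(round(config.segment_s * fs))
    segments = []
    for ev in recording.events:
        if ev.score not in LABEL_MAP:
            continue
        if ev.time_s < config.segment_s:
            log.warning(
                "%s: event at %.1f s precedes a full %.0f-s window; skipped",
                recording.id, ev.time_s, config.segment_s,
            )
            continue
        stop = int(round(ev.time_s * fs))
        start = stop - n_seg
        segments.append((recording.signal[:, start:stop], LABEL_MAP[ev.score]))
    if not segments:
        log.warning("%s: no qualifying MOAA/S events", recording.id)
    return segments


def epoch_segment(segment, label, recording_id, segment_index,
                  config: PreprocessConfig = PreprocessConfig(), meta=None) -> list[Epoch]:
    """Split a 60-s segment into fifteen non-overlapping 4-s epochs."""
    n_ep = config.samples_per_epoch
    n = segment.shape[1]
    if n % n_ep != 0:
        raise ConfigError(f"segment length {n} not a multiple of epoch length {n_ep}")
    return [
        Epoch(
            data=segment[:, k * n_ep : (k + 1) * n_ep],
            label=label,
            recording_id=recording_id,
            segment_index=segment_index,
            epoch_index=k,
            meta=meta,
        )
        for k in range(n // n_ep)
    ]


def reject_artifacts(epochs, config: PreprocessConfig = PreprocessConfig()):
    """Screen epochs: reject |x| > 500 uV (movement) or a flat channel.

    The criterion is cross-channel: any channel tripping either rule rejects
    the whole epoch. Returns ``(kept, rejected)`` where ``rejected`` pairs
    each epoch with the reason ``"amplitude"`` or ``"flat"``.
    """
    kept, rejected = [], []
    for ep in epochs:
        peak = np.abs(ep.data).max(axis=1)
        if np.any(peak > config.amp_reject_uv):
            rejected.append((ep, "amplitude"))
        elif config.flat_reject and np.any(peak < config.flat_eps_uv):
            rejected.append((ep, "flat"))
        else:
            kept.append(ep)
    return kept, rejected


def preprocess_recording(recording: Recording, config: PreprocessConfig = PreprocessConfig()):
    """Full per-recording pipeline; returns ``(kept, rejected)`` epochs."""
    rec = make_bipolar(recording)
    rec = filter_resample(rec, config)
    epochs = []
    for seg_idx, (seg, label) in enumerate(extract_segments(rec, config)):
        epochs.extend(
            epoch_segment(seg, label, rec.id, seg_idx, config, meta=rec.meta)
        )
    return reject_artifacts(epochs, config)
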