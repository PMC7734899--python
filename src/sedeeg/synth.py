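"""Synthetic anesthesia-EEG generator.

Emulates the statistical structure the pipeline assumes: two-state frontal
EEG — awake plateaus with mixed alpha/beta rhythms versus sedated plateaus
with delta dominance and optional burst suppression — sampled on four
frontal electrodes, annotated with MOAA/S assessments placed so that a full
60-s pre-assessment window exists, and carrying cohort covariates (three
age strata, two sexes, three hypnotic drugs with an optional remifentanil
flag).

Each recording alternates awake (MOAA/S 5) and sedated (MOAA/S 0 or 1)
plateaus. Signals are sums of band-limited Gaussian processes shaped to a
per-state spectral template plus a 1/f (pink) fraction, scaled to a
physiologic RMS (15 uV awake, 25 uV sedated), with additive sensor noise.
This is phenomenological surrogate data, not a biophysical neural-mass
model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .recording import CohortMeta, MOAASEvent, Recording

#: Band edges matching the feature module: delta, theta, alpha, sigma, beta.
_BAND_EDGES = [(0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 16.0), (16.0, 25.0)]


@dataclass(frozen=True)
class SpectralTemplate:
    """Relative band powers (delta, theta, alpha, sigma, beta) + pink fraction."""

    band_weights: tuple
    pink_noise_fraction: float = 0.2
    rms_uv: float = 15.0

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.size != 5 or np.any(w < 0) or not np.any(w > 0):
            raise ConfigError("band_weights must be 5 nonnegative values, not all zero")
        if not (0 <= self.pink_noise_fraction <= 1):
            raise ConfigError("pink_noise_fraction must be in [0, 1]")


#: Defaults mimic anesthesia slow-wave dominance vs. awake mixed rhythms.
AWAKE_TEMPLATE = SpectralTemplate((0.15, 0.15, 0.35, 0.15, 0.20), rms_uv=15.0)
SEDATED_TEMPLATE = SpectralTemplate((0.60, 0.20, 0.10, 0.05, 0.05), rms_uv=25.0)


@dataclass(frozen=True)
class BurstSuppressionParams:
    suppression_amplitude_uv: float = 0.5   # RMS during suppression
    burst_amplitude_uv: float = 40.0        # RMS during bursts
    mean_suppression_s: float = 2.0
    mean_burst_s: float = 1.0
    bs_probability_when_sedated: float = 0.3

    def __post_init__(self) -> None:
        if self.suppression_amplitude_uv < 0 or self.burst_amplitude_uv < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.mean_suppression_s <= 0 or self.mean_burst_s <= 0:
            raise ConfigError("durations must be > 0")


#: Age strata used by the cross-group robustness design.
DEFAULT_AGE_STRATA = [(18.0, 35.0, 1 / 3), (35.0, 50.0, 1 / 3), (50.0, 70.0, 1 / 3)]


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 6
    sessions_per_subject: int = 1
    #: plateaus per recording (alternating awake/sedated, awake first)
    n_plateaus: int = 4
    plateau_s: float = 70.0
    drugs: tuple = ("propofol", "sevoflurane", "dexmedetomidine")
    remifentanil_fraction: float = 0.0
    #: blend factor pulling the two state templates together for
    #: remifentanil recordings (0 = no shrink, 1 = identical templates)
    remi_contrast_shrink: float = 0.5
    age_strata: tuple = tuple(tuple(s) for s in DEFAULT_AGE_STRATA)
    awake_template: SpectralTemplate = AWAKE_TEMPLATE
    sedated_template: SpectralTemplate = SEDATED_TEMPLATE
    bs_params: BurstSuppressionParams = BurstSuppressionParams()
    #: strength of the age/sex multiplicative tilt on band weights
    age_tilt: float = 0.0
    sex_tilt: float = 0.0
    snr_db: float = 30.0
    fs_out: float = 250.0
    seed: int = 0
    #: emit sedated scores from {0,1}; set True to also emit 2-4 transition
    #: scores so the discard rule is exercised
    emit_transition_scores: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.fs_out < 100:
            raise ConfigError("fs_out must be >= 100 Hz")
        if self.plateau_s < 60:
            raise ConfigError("plateau_s must be >= 60 s so a full pre-event window exists")
        weights = [s[2] for s in self.age_strata]
        if abs(sum(weights) - 1) > 1e-9:
            raise ConfigError("age strata weights must sum to 1")


CHANNELS = ["Fp1", "F7", "Fp2", "F8"]


def _pink_noise(n, fs, rng) -> np.ndarray:
    """Band-limited 1/f noise (power slope -1 on log-log axes), unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spectrum = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    shape = np.zeros_like(freqs)
    band = (freqs >= 0.5) & (freqs <= 30.0)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spectrum * shape, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else np.zeros(n)  # degenerate for very short spans


def generate_state_epoch(template: SpectralTemplate, duration_s, fs, rng) -> np.ndarray:
    """One channel of state-conditioned surrogate EEG.

    Sum of band-limited Gaussian processes with relative powers matching
    ``band_weights``, mixed with a pink-noise fraction, scaled to the
    template RMS.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be > 0")
    n = int(round(duration_s * fs))
    w = np.asarray(template.band_weights, dtype=float)
    w = w / w.sum()
    banded = np.zeros(n)
    pad = int(2 * fs)  # settle filter transients outside the returned span
    for (lo, hi), wi in zip(_BAND_EDGES, w):
        if wi == 0:
            continue
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        comp = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
        comp /= np.std(comp)
        banded += np.sqrt(wi) * comp
    if np.std(banded) > 0:
        banded /= np.std(banded)
    p = template.pink_noise_fraction
    x = np.sqrt(1 - p) * banded + (np.sqrt(p) * _pink_noise(n, fs, rng) if p > 0 else 0.0)
    if np.std(x) > 0:
        x = x / np.std(x)
    return template.rms_uv * x


def _burst_suppression_plateau(bs: BurstSuppressionParams, sedated: SpectralTemplate,
                               duration_s, fs, rng, n_channels) -> np.ndarray:
    """Multi-channel burst-suppression plateau.

    Burst/suppression span boundaries are shared across channels (as on a
    real scalp) while the within-span processes are channel-specific, so
    the bipolar difference keeps the alternating structure.
    """
    n = int(round(duration_s * fs))
    spans = []
    pos = 0
    in_burst = bool(rng.integers(2))
    while pos < n:
        mean_s = bs.mean_burst_s if in_burst else bs.mean_suppression_s
        span = max(int(round(rng.exponential(mean_s) * fs)), int(0.25 * fs))
        span = min(span, n - pos)
        spans.append((pos, pos + span, in_burst))
        pos += span
        in_burst = not in_burst
    out = np.empty((n_channels, n))
    for ch in range(n_channels):
        for a, b, burst in spans:
            if burst:
                seg = generate_state_epoch(
                    replace(sedated, rms_uv=bs.burst_amplitude_uv), (b - a) / fs, fs, rng
                )
                out[ch, a:b] = seg[: b - a]
            else:
                out[ch, a:b] = bs.suppression_amplitude_uv * rng.standard_normal(b - a)
    return out


def _tilt_template(template: SpectralTemplate, tilt: float) -> SpectralTemplate:
    """Shift relative power from fast bands to delta by a factor (1 + tilt)."""
    w = np.asarray(template.band_weights, dtype=float).copy()
    w[0] *= max(1 + tilt, 0.05)
    w[3:] *= max(1 - tilt, 0.05)
    return replace(template, band_weights=tuple(w / w.sum()))


def _blend(a: SpectralTemplate, b: SpectralTemplate, frac: float) -> SpectralTemplate:
    wa = np.asarray(a.band_weights) / np.sum(a.band_weights)
    wb = np.asarray(b.band_weights) / np.sum(b.band_weights)
    w = (1 - frac) * wa + frac * (wa + wb) / 2
    rms = (1 - frac) * a.rms_uv + frac * (a.rms_uv + b.rms_uv) / 2
    return replace(a, band_weights=tuple(w), rms_uv=rms)


def _recording_rng(seed, subject, session) -> np.random.Generator:
    """One independent stream per recording for reproducible generation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), subject, session]))


def generate_recording(config: GeneratorConfig, subject: int, session: int,
                       meta: CohortMeta) -> Recording:
    rng = _recording_rng(config.seed, subject, session)
    fs = config.fs_out
    awake, sedated = config.awake_template, config.sedated_template

    if config.age_tilt != 0:
        lo = min(s[0] for s in config.age_strata)
        hi = max(s[1] for s in config.age_strata)
        age_norm = (meta.age_years - lo) / (hi - lo) - 0.5
        sedated = _tilt_template(sedated, config.age_tilt * age_norm)
        awake = _tilt_template(awake, -config.age_tilt * age_norm)
    if config.sex_tilt != 0 and meta.sex == "female":
        sedated = _tilt_template(sedated, config.sex_tilt)
        awake = _tilt_template(awake, -config.sex_tilt)
    if meta.remifentanil and config.remi_contrast_shrink > 0:
        frac = config.remi_contrast_shrink
        awake, sedated = _blend(awake, sedated, frac), _blend(sedated, awake, frac)

    plateaus, events = [], []
    t = 0.0
    for k in range(config.n_plateaus):
        is_awake = k % 2 == 0
        template = awake if is_awake else sedated
        use_bs = (
            not is_awake
            and rng.random() < config.bs_params.bs_probability_when_sedated
        )
        if use_bs:
            plateau = _burst_suppression_plateau(
                config.bs_params, sedated, config.plateau_s, fs, rng, len(CHANNELS)
            )
        else:
            # shared plateau process + channel-specific variation
            base = generate_state_epoch(template, config.plateau_s, fs, rng)
            chans = [
                0.8 * base + 0.6 * generate_state_epoch(template, config.plateau_s, fs, rng)
                for _ in CHANNELS
            ]
            plateau = np.vstack(chans)
        noise_rms = plateau.std() * 10 ** (-config.snr_db / 20)
        plateau = plateau + noise_rms * rng.standard_normal(plateau.shape)
        plateaus.append(plateau)
        t += config.plateau_s
        if is_awake:
            score = 5
        elif config.emit_transition_scores and rng.random() < 0.25:
            score = int(rng.integers(2, 5))
        else:
            score = int(rng.integers(0, 2))
        events.append(MOAASEvent(time_s=t, score=score))

    signal = np.concatenate(plateaus, axis=1)
    # make the final event strictly inside the recording
    events[-1] = MOAASEvent(time_s=events[-1].time_s - 1 / fs, score=events[-1].score)
    return Recording(
        id=f"s{subject:03d}r{session:02d}",
        signal=signal,
        fs=fs,
        channel_labels=list(CHANNELS),
        events=events,
        meta=meta,
    )


def _sample_meta(config: GeneratorConfig, subject: int, session: int,
                 rng: np.random.Generator) -> CohortMeta:
    # age- and sex-stratified cohort: strata cycle deterministically over
    # subjects (as in a stratified enrolment), ages uniform within stratum
    stratum = config.age_strata[subject % len(config.age_strata)]
    age = float(rng.uniform(stratum[0], stratum[1]))
    return CohortMeta(
        drug=str(rng.choice(config.drugs)),
        remifentanil=bool(rng.random() < config.remifentanil_fraction),
        age_years=age,
        sex=("male", "female")[subject % 2],
        subject_id=f"s{subject:03d}",
    )


def generate_cohort(config: GeneratorConfig) -> list[Recording]:
    """Generate the full cohort; identical config+seed gives identical output."""
    recordings = []
    for subject in range(config.n_subjects):
        meta_rng = _recording_rng(config.seed, subject, 10_000)
        for session in range(config.sessions_per_subject):
            meta = _sample_meta(config, subject, session, meta_rng)
            recordings.append(generate_recording(config, subject, session, meta))
    return recordings


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpan:
    kind: str      # "movement" | "flat"
    start_s: float
    stop_s: float


def inject_artifacts(recording: Recording, n_movement: int, n_flat: int,
                     rng: np.random.Generator, segment_s: float = 60.0,
                     epoch_s: float = 4.0):
    """Insert movement (>500 uV) and flat (zeroed) 4-s spans into epoch slots.

    Slots are aligned to the epoch grid of the qualifying pre-assessment
    windows so that downstream rejection excises exactly the injected
    epochs. Flat spans are zeroed with a 2-s guard margin on each side so
    that band-pass filter ringing inside the logged span stays below the
    flat-detection threshold. Returns ``(recording, artifact_log)``.
    """
    from .preprocess import LABEL_MAP

    fs = recording.fs
    slots = []
    for ev in recording.events:
        if ev.score not in LABEL_MAP or ev.time_s < segment_s:
            continue
        t0 = ev.time_s - segment_s
        slots.extend(t0 + k * epoch_s for k in range(int(segment_s / epoch_s)))
    n_total = n_movement + n_flat
    if n_total == 0:
        return recording, []
    # keep chosen slots >= 3 slots apart so guard margins never overlap
    order = rng.permutation(len(slots))
    chosen = []
    for idx in order:
        if all(abs(slots[idx] - slots[j]) >= 3 * epoch_s for j in chosen):
            chosen.append(idx)
        if len(chosen) == n_total:
            break
    if len(chosen) < n_total:
        raise ConfigError(
            f"not enough room for {n_total} disjoint artifact spans "
            f"({len(slots)} slots available)"
        )
    signal = recording.signal.copy()
    log_entries = []
    fp_rows = [recording.channel_labels.index(c) for c in ("Fp1", "Fp2")]
    for i, idx in enumerate(chosen):
        t0 = slots[idx]
        a, b = int(round(t0 * fs)), int(round((t0 + epoch_s) * fs))
        if i < n_movement:
            tt = np.arange(b - a) / fs
            burst = 800.0 * np.sin(2 * np.pi * 2.0 * tt)
            for row in fp_rows:  # frontal electrodes only: survives bipolar subtraction
                signal[row, a:b] += burst
            log_entries.append(ArtifactSpan("movement", t0, t0 + epoch_s))
        else:
            guard = int(round(2.0 * fs))
            signal[:, max(a - guard, 0) : min(b + guard, signal.shape[1])] = 0.0
            log_entries.append(ArtifactSpan("flat", t0, t0 + epoch_s))
    out = recording.with_signal(signal)
    return out, log_entries
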