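"""The 44 quantitative EEG features computed per 4-s epoch.

Features are computed separately on each bipolar channel and fused by the
element-wise median across channels. The canonical order is frozen in
:data:`FEATURE_NAMES`: items 1-12 time domain, 13-36 frequency domain,
37-44 entropy domain.

Conventions: kurtosis is the non-excess standardized fourth moment
(Gaussian -> 3); all entropies are in bits (log base 2) except the
normalized spectral/state/permutation entropies, which lie in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats

from .errors import InputError

#: Frequency bands (Hz): delta, theta, alpha, sigma (spindle), beta.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 25.0),
}
TOTAL_BAND = (0.5, 25.0)

#: Canonical 44-feature order (frozen; versioned with the package).
FEATURE_NAMES = [
    "neo",                    # 1
    "hjorth_activity",        # 2
    "hjorth_mobility",        # 3
    "hjorth_complexity",      # 4
    "rms",                    # 5
    "kurtosis",               # 6
    "skewness",               # 7
    "am_mean", "am_sd", "am_skew", "am_kurt",   # 8-11
    "bsr",                    # 12
    "p_delta", "p_theta", "p_alpha", "p_sigma", "p_beta", "p_total",  # 13-18
    "rel_delta", "rel_theta", "rel_alpha", "rel_sigma", "rel_beta",   # 19-23
    "theta_delta_ratio", "alpha_delta_ratio",
    "sigma_delta_ratio", "beta_delta_ratio",    # 24-27
    "alpha_theta_ratio", "sigma_theta_ratio", "beta_theta_ratio",     # 28-30
    "fm_mean", "fm_sd", "fm_skew", "fm_kurt",   # 31-34
    "sef95", "peak_freq",     # 35-36
    "svd_entropy",            # 37
    "spectral_entropy",       # 38
    "state_entropy",          # 39
    "sample_entropy",         # 40
    "renyi_entropy",          # 41
    "shannon_entropy",        # 42
    "permutation_entropy",    # 43
    "fractal_dimension",      # 44
]
assert len(FEATURE_NAMES) == 44

PROVENANCE_COLUMNS = ["recording_id", "segment_index", "epoch_index", "label"]
META_COLUMNS = ["subject_id", "drug", "remifentanil", "age_years", "sex"]


@dataclass(frozen=True)
class FeatureConfig:
    """Hyper-parameters of the feature extractors (all configurable)."""

    sampen_m: int = 2
    sampen_r: float = 0.2          # times the epoch SD
    perm_order: int = 3
    perm_delay: int = 1
    svd_dim: int = 10
    svd_delay: int = 1
    renyi_order: float = 2.0
    hist_bins: int = 32
    higuchi_kmax: int = 8
    bsr_threshold_uv: float = 5.0
    bsr_min_s: float = 0.5
    am_fm_trim: float = 0.05       # fraction trimmed from each edge
    psd_window_s: float = 2.0
    psd_overlap: float = 0.5


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def nonlinear_energy(x) -> float:
    """Mean Teager/nonlinear energy psi[x](n) = x(n)^2 - x(n-1) x(n+1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InputError("nonlinear energy needs at least 3 samples")
    return float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))


def hjorth_parameters(x):
    """Hjorth activity (variance), mobility, and complexity."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InputError("Hjorth parameters need at least 3 samples")
    activity = float(np.var(x))
    if activity == 0:
        return 0.0, np.nan, np.nan
    dx = np.diff(x)
    ddx = np.diff(dx)
    mobility = float(np.sqrt(np.var(dx) / np.var(x)))
    mob_dx = np.sqrt(np.var(ddx) / np.var(dx)) if np.var(dx) > 0 else np.nan
    complexity = float(mob_dx / mobility) if mobility > 0 else np.nan
    return activity, mobility, complexity


def moment_statistics(x):
    """RMS amplitude, kurtosis (non-excess), and skewness."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InputError("moment statistics need at least 4 samples")
    rms = float(np.sqrt(np.mean(x**2)))
    if np.var(x) == 0:
        return rms, np.nan, np.nan
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    skew = float(stats.skew(x, bias=True))
    return rms, kurt, skew


def am_fm_statistics(x, fs, config: FeatureConfig = DEFAULT_CONFIG):
    """Moments of the Hilbert envelope (AM) and instantaneous frequency (FM).

    The analytic signal's envelope magnitude gives AM; the unwrapped-phase
    derivative times fs/2pi gives FM, clipped to the 0.5-25 Hz analysis
    band. Five percent of samples at each edge are trimmed before the
    statistics to suppress Hilbert end effects.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise InputError("AM/FM statistics need at least 64 samples")
    if np.all(x == 0):
        return (0.0, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan, np.nan)
    analytic = sps.hilbert(x)
    trim = int(round(config.am_fm_trim * x.size))

    am = np.abs(analytic)[trim : x.size - trim]
    fm = np.diff(np.unwrap(np.angle(analytic))) * fs / (2 * np.pi)
    fm = np.clip(fm, TOTAL_BAND[0], TOTAL_BAND[1])[trim : fm.size - trim]

    def four(v):
        if np.var(v) == 0:
            return float(np.mean(v)), 0.0, 0.0, 0.0
        return (
            float(np.mean(v)),
            float(np.std(v)),
            float(stats.skew(v, bias=True)),
            float(stats.kurtosis(v, fisher=False, bias=True)),
        )

    return (*four(am), *four(fm))


def burst_suppression_ratio(x, fs, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Percentage of time in suppression (|x| < 5 uV for >= 0.5 s)."""
    x = np.asarray(x, dtype=float)
    quiet = np.abs(x) < config.bsr_threshold_uv
    min_run = int(round(config.bsr_min_s * fs))
    suppressed = 0
    # run-length encode the quiet mask
    edges = np.flatnonzero(np.diff(quiet.astype(int)))
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges + 1, quiet.size]
    for a, b in zip(starts, stops):
        if quiet[a] and (b - a) >= min_run:
            suppressed += b - a
    return 100.0 * suppressed / x.size


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

@dataclass
class PSDEstimate:
    """Welch PSD restricted to the 0.5-25 Hz reporting band."""

    frequencies: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray          # uV^2/Hz, >= 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise InputError("PSD frequencies must be strictly increasing")
        if np.any(self.psd < 0):
            raise InputError("PSD densities must be nonnegative")


def estimate_psd(x, fs, config: FeatureConfig = DEFAULT_CONFIG) -> PSDEstimate:
    """Welch estimate: 2-s Hann windows, 50% overlap, 0.5 Hz resolution."""
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(config.psd_window_s * fs)), x.size)
    noverlap = int(round(nperseg * config.psd_overlap))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    mask = (f >= TOTAL_BAND[0]) & (f <= TOTAL_BAND[1])
    return PSDEstimate(frequencies=f[mask], psd=p[mask])


def _band_power(psd: PSDEstimate, lo, hi) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] (edges shared between
    adjacent bands, so the band powers partition the total exactly)."""
    f, p = psd.frequencies, psd.psd
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def band_powers_and_ratios(psd: PSDEstimate) -> dict:
    """Absolute band powers, relative powers, and the seven band ratios."""
    powers = {name: _band_power(psd, lo, hi) for name, (lo, hi) in BANDS.items()}
    total = sum(powers.values())
    out = {f"p_{k}": v for k, v in powers.items()}
    out["p_total"] = total
    for k, v in powers.items():
        out[f"rel_{k}"] = v / total if total > 0 else np.nan
    for num in ("theta", "alpha", "sigma", "beta"):
        out[f"{num}_delta_ratio"] = (
            powers[num] / powers["delta"] if powers["delta"] > 0 else np.nan
        )
    for num in ("alpha", "sigma", "beta"):
        out[f"{num}_theta_ratio"] = (
            powers[num] / powers["theta"] if powers["theta"] > 0 else np.nan
        )
    return out


def spectral_edge_and_peak(psd: PSDEstimate):
    """SEF95 (95% spectral edge, linearly interpolated) and peak frequency.

    Peak ties break to the lowest frequency.
    """
    f, p = psd.frequencies, psd.psd
    cum = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(f))])
    total = cum[-1]
    if total <= 0:
        return np.nan, np.nan
    target = 0.95 * total
    idx = int(np.searchsorted(cum, target))
    if idx == 0:
        sef = float(f[0])
    else:
        frac = (target - cum[idx - 1]) / (cum[idx] - cum[idx - 1])
        sef = float(f[idx - 1] + frac * (f[idx] - f[idx - 1]))
    peak = float(f[int(np.argmax(p))])
    return sef, peak


# ---------------------------------------------------------------------------
# entropy domain
# ---------------------------------------------------------------------------

def svd_entropy(x, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Entropy (bits) of normalized singular values of the delay embedding."""
    x = np.asarray(x, dtype=float)
    d, tau = config.svd_dim, config.svd_delay
    span = (d - 1) * tau + 1
    if x.size < span + 1:
        raise InputError(f"SVD entropy needs at least {span + 1} samples")
    if np.ptp(x) == 0:
        return 0.0  # rank <= 1: a single (or no) nonzero singular value
    traj = sliding_window_view(x, span)[:, ::tau]
    sv = np.linalg.svd(traj, compute_uv=False)
    s = sv.sum()
    if s == 0:
        return 0.0
    p = sv / s
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _normalized_spectral_entropy(psd: PSDEstimate, f_lo, f_hi) -> float:
    f, p = psd.frequencies, psd.psd
    mask = (f >= f_lo) & (f <= f_hi)
    p = p[mask]
    total = p.sum()
    if total <= 0 or p.size < 2:
        return np.nan
    q = p / total
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)) / np.log(mask.sum()))


def spectral_entropy(psd: PSDEstimate) -> float:
    """Shannon entropy of the normalized PSD over 0.5-25 Hz, scaled to [0,1]."""
    return _normalized_spectral_entropy(psd, *TOTAL_BAND)


def state_entropy(psd: PSDEstimate) -> float:
    """Spectral entropy restricted to 0.8-25 Hz (renormalized in-band)."""
    return _normalized_spectral_entropy(psd, 0.8, TOTAL_BAND[1])


def sample_entropy(x, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """SampEn(m=2, r=0.2 SD): -ln(A/B) with Chebyshev distance.

    Both template lengths use the same index set (i <= N-m-1) and
    self-matches are excluded. Returns NaN when no m+1 matches exist or
    the signal has zero variance.
    """
    x = np.asarray(x, dtype=float)
    m = config.sampen_m
    if x.size < 100:
        raise InputError("sample entropy needs at least 100 samples")
    sd = np.std(x)
    if sd == 0:
        return np.nan
    r = config.sampen_r * sd
    n_templates = x.size - m  # same index set for both template lengths
    # Chebyshev distance built lag by lag: D_k = max(|x_i+k - x_j+k|)
    dist = np.zeros((n_templates, n_templates))
    for k in range(m):
        a_k = x[k : k + n_templates]
        np.maximum(dist, np.abs(np.subtract.outer(a_k, a_k)), out=dist)
    b = (int((dist <= r).sum()) - n_templates) // 2
    a_m = x[m : m + n_templates]
    np.maximum(dist, np.abs(np.subtract.outer(a_m, a_m)), out=dist)
    a = (int((dist <= r).sum()) - n_templates) // 2
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def shannon_renyi_entropy(x, config: FeatureConfig = DEFAULT_CONFIG):
    """Shannon and order-2 Renyi entropies (bits) of the amplitude histogram."""
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise InputError("histogram entropies need at least 100 samples")
    if np.ptp(x) == 0:
        return 0.0, 0.0
    counts, _ = np.histogram(x, bins=config.hist_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    shannon = float(-np.sum(p * np.log2(p)))
    alpha = config.renyi_order
    renyi = float(np.log2(np.sum(p**alpha)) / (1 - alpha))
    return shannon, renyi


def permutation_entropy(x, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Normalized permutation entropy of order-3 ordinal patterns, in [0,1].

    Ties rank the earlier sample lower (stable argsort).
    """
    x = np.asarray(x, dtype=float)
    m, tau = config.perm_order, config.perm_delay
    if x.size < 50:
        raise InputError("permutation entropy needs at least 50 samples")
    span = (m - 1) * tau + 1
    windows = sliding_window_view(x, span)[:, ::tau]
    order = np.argsort(windows, axis=1, kind="stable")
    base = m ** np.arange(m - 1, -1, -1)
    codes = order @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(math.factorial(m)))


def fractal_dimension(x, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Higuchi fractal dimension with k_max = 8."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise InputError("Higuchi FD needs at least 100 samples")
    if np.ptp(x) == 0:
        return np.nan
    ks = np.arange(1, config.higuchi_kmax + 1)
    lk = np.empty(ks.size)
    for i, k in enumerate(ks):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(dist * norm / k)
        lk[i] = np.mean(lengths)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# per-epoch extraction
# ---------------------------------------------------------------------------

def channel_features(x, fs, config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """All 44 features for one channel, in canonical order."""
    out = {}
    out["neo"] = nonlinear_energy(x)
    (out["hjorth_activity"], out["hjorth_mobility"],
     out["hjorth_complexity"]) = hjorth_parameters(x)
    out["rms"], out["kurtosis"], out["skewness"] = moment_statistics(x)
    (out["am_mean"], out["am_sd"], out["am_skew"], out["am_kurt"],
     out["fm_mean"], out["fm_sd"], out["fm_skew"], out["fm_kurt"]) = am_fm_statistics(
        x, fs, config
    )
    out["bsr"] = burst_suppression_ratio(x, fs, config)
    psd = estimate_psd(x, fs, config)
    out.update(band_powers_and_ratios(psd))
    out["sef95"], out["peak_freq"] = spectral_edge_and_peak(psd)
    out["svd_entropy"] = svd_entropy(x, config)
    out["spectral_entropy"] = spectral_entropy(psd)
    out["state_entropy"] = state_entropy(psd)
    out["sample_entropy"] = sample_entropy(x, config)
    out["shannon_entropy"], out["renyi_entropy"] = shannon_renyi_entropy(x, config)
    out["permutation_entropy"] = permutation_entropy(x, config)
    out["fractal_dimension"] = fractal_dimension(x, config)
    return np.array([out[name] for name in FEATURE_NAMES], dtype=float)


def extract_feature_vector(epoch, fs=250.0, config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """44-feature vector for one epoch: per-channel features, channel median.

    With two channels the median equals the mean of the pair; NaN in one
    channel falls back to the other channel's value (nan-median), NaN in
    both propagates.
    """
    data = (
        np.asarray(epoch, dtype=float)
        if isinstance(epoch, np.ndarray)
        else np.asarray(epoch.data, dtype=float)
    )
    per_channel = np.vstack([channel_features(ch, fs, config) for ch in data])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature columns
        return np.nanmedian(per_channel, axis=0)


def extract_features(epochs, fs=250.0, config: FeatureConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Feature matrix: one row per epoch, canonical feature columns plus
    provenance (recording_id, segment_index, epoch_index, label) and any
    cohort metadata carried on the epochs."""
    rows = []
    for ep in epochs:
        row = {
            "recording_id": ep.recording_id,
            "segment_index": ep.segment_index,
            "epoch_index": ep.epoch_index,
            "label": ep.label,
        }
        if ep.meta is not None:
            row.update(ep.meta.as_dict())
        row.update(dict(zip(FEATURE_NAMES, extract_feature_vector(ep, fs, config))))
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(df: pd.DataFrame):
    """Split a feature DataFrame into (X, y, groups) for model fitting.

    y is 1 for sedated, 0 for awake; groups are recording ids.
    """
    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    y = (df["label"] == "sedated").to_numpy(dtype=int)
    groups = df["recording_id"].to_numpy()
    return X, y, groups
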