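"""Feature extractors: brute-force oracle equivalence and analytic limits."""

import math

import numpy as np
import pytest

from sedeeg.features import (
    BANDS,
    FEATURE_NAMES,
    PSDEstimate,
    am_fm_statistics,
    band_powers_and_ratios,
    burst_suppression_ratio,
    channel_features,
    estimate_psd,
    extract_feature_vector,
    fractal_dimension,
    hjorth_parameters,
    moment_statistics,
    nonlinear_energy,
    permutation_entropy,
    sample_entropy,
    shannon_renyi_entropy,
    spectral_edge_and_peak,
    spectral_entropy,
    state_entropy,
    svd_entropy,
)

FS = 250.0


def tone(freq, dur=4.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def neo_oracle(x):
    return sum(x[n] ** 2 - x[n - 1] * x[n + 1] for n in range(1, len(x) - 1)) / (len(x) - 2)


def sampen_oracle(x, m=2, r_factor=0.2):
    r = r_factor * np.std(x)
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -math.log(a / b) if a and b else float("nan")


def permen_oracle(x, m=3):
    from collections import Counter

    patterns = Counter()
    for i in range(len(x) - m + 1):
        w = x[i : i + m]
        order = tuple(sorted(range(m), key=lambda k: (w[k], k)))
        patterns[order] += 1
    total = sum(patterns.values())
    h = -sum(c / total * math.log2(c / total) for c in patterns.values())
    return h / math.log2(math.factorial(m))


def hist_entropy_oracle(x, bins=32, renyi_order=2):
    lo, hi = min(x), max(x)
    counts = [0] * bins
    for v in x:
        idx = min(int((v - lo) / (hi - lo) * bins), bins - 1)
        counts[idx] += 1
    ps = [c / len(x) for c in counts if c]
    shannon = -sum(p * math.log2(p) for p in ps)
    renyi = math.log2(sum(p**renyi_order for p in ps)) / (1 - renyi_order)
    return shannon, renyi


def svd_entropy_oracle(x, d=10):
    rows = [x[i : i + d] for i in range(len(x) - d + 1)]
    sv = np.linalg.svd(np.array(rows), compute_uv=False)
    p = sv / sv.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@pytest.mark.parametrize("seed", range(10))
def test_counting_entropies_match_oracles(seed):
    r = np.random.default_rng(seed)
    x = r.standard_normal(150) * r.uniform(1, 30)
    assert sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-9, nan_ok=True)
    assert permutation_entropy(x) == pytest.approx(permen_oracle(x), abs=1e-9)
    sh, ry = shannon_renyi_entropy(x)
    osh, ory = hist_entropy_oracle(x)
    assert sh == pytest.approx(osh, abs=1e-9)
    assert ry == pytest.approx(ory, abs=1e-9)
    assert svd_entropy(x) == pytest.approx(svd_entropy_oracle(x), rel=1e-6)
    assert nonlinear_energy(x) == pytest.approx(neo_oracle(x), rel=1e-9)


def test_hjorth_matches_definition(rng):
    x = rng.standard_normal(1000)
    act, mob, comp = hjorth_parameters(x)
    dx, ddx = np.diff(x), np.diff(np.diff(x))
    assert act == pytest.approx(np.var(x))
    assert mob == pytest.approx(np.sqrt(np.var(dx) / np.var(x)))
    assert comp == pytest.approx(np.sqrt(np.var(ddx) / np.var(dx)) / mob)


# ---------------------------------------------------------------------------
# analytic limits
# ---------------------------------------------------------------------------

def test_neo_hand_arithmetic():
    assert nonlinear_energy([1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert nonlinear_energy(np.full(10, 3.7)) == pytest.approx(0.0)


def test_hjorth_sinusoid_complexity_one():
    _, _, comp = hjorth_parameters(tone(10))
    assert comp == pytest.approx(1.0, abs=1e-2)


def test_hjorth_scale_behavior(rng):
    x = rng.standard_normal(500)
    a1, m1, c1 = hjorth_parameters(x)
    a2, m2, c2 = hjorth_parameters(3.0 * x)
    assert a2 == pytest.approx(9 * a1)
    assert m2 == pytest.approx(m1)
    assert c2 == pytest.approx(c1)


def test_moments_two_point_and_parity(rng):
    x = np.tile([1.0, -1.0], 100)
    rms, kurt, skew = moment_statistics(x)
    assert (rms, skew, kurt) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))
    y = rng.standard_normal(1000) ** 3
    r1, k1, s1 = moment_statistics(y)
    r2, k2, s2 = moment_statistics(-y)
    assert r1 == pytest.approx(r2) and k1 == pytest.approx(k2) and s1 == pytest.approx(-s2)


def test_gaussian_kurtosis_near_three(rng):
    _, kurt, _ = moment_statistics(rng.standard_normal(100_000))
    assert kurt == pytest.approx(3.0, abs=0.1)


class TestAmFm:
    def test_pure_tone(self):
        stats = am_fm_statistics(tone(10, amp=20.0), FS)
        am_mean, am_sd, fm_mean, fm_sd = stats[0], stats[1], stats[4], stats[5]
        assert am_mean == pytest.approx(20.0, rel=0.02)
        assert am_sd < 0.5
        assert fm_mean == pytest.approx(10.0, rel=0.01)
        assert fm_sd < 0.5

    def test_chirp_mean_instantaneous_frequency(self):
        from scipy.signal import chirp

        t = np.arange(int(4 * FS)) / FS
        x = chirp(t, f0=5, f1=15, t1=4.0)
        fm_mean = am_fm_statistics(x, FS)[4]
        assert fm_mean == pytest.approx(10.0, rel=0.05)

    def test_sinusoidal_amplitude_modulation_depth(self):
        t = np.arange(int(8 * FS)) / FS
        x = (1 + 0.5 * np.sin(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 10 * t)
        stats = am_fm_statistics(x, FS)
        assert stats[1] / stats[0] == pytest.approx(0.5 / np.sqrt(2), rel=0.10)

    def test_zero_signal(self):
        stats = am_fm_statistics(np.zeros(1000), FS)
        assert stats[:4] == (0.0, 0.0, 0.0, 0.0)
        assert all(np.isnan(v) for v in stats[4:])


class TestBSR:
    def test_full_suppression(self):
        assert burst_suppression_ratio(np.zeros(1000), FS) == 100.0

    def test_half_suppression(self):
        x = np.concatenate([np.zeros(500), tone(10, dur=2.0, amp=50.0)])
        assert burst_suppression_ratio(x, FS) == pytest.approx(50.0, abs=1.0)

    def test_short_gap_not_counted(self):
        x = tone(10, dur=4.0, amp=50.0)
        x[500 : 500 + 75] = 0.0  # 0.3 s < 0.5 s minimum
        assert burst_suppression_ratio(x, FS) == 0.0


class TestPSD:
    def test_tone_power_concentrated(self):
        psd = estimate_psd(tone(10), FS)
        mask = (psd.frequencies >= 9) & (psd.frequencies <= 11)
        assert np.trapezoid(psd.psd[mask], psd.frequencies[mask]) >= 0.95 * np.trapezoid(
            psd.psd, psd.frequencies
        )

    def test_white_noise_band_power_tracks_bandwidth(self, rng):
        x = rng.standard_normal(int(120 * FS))
        bp = band_powers_and_ratios(estimate_psd(x, FS))
        for name, (lo, hi) in BANDS.items():
            expected = (hi - lo) / (25.0 - 0.5)
            assert bp[f"rel_{name}"] == pytest.approx(expected, rel=0.15)

    def test_parseval_on_band_limited_noise(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(8, [1.0, 24.0], btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(int(60 * FS)))
        psd = estimate_psd(x, FS)
        integral = np.trapezoid(psd.psd, psd.frequencies)
        assert integral == pytest.approx(np.var(x), rel=0.10)

    def test_relative_powers_partition_to_one(self, rng):
        bp = band_powers_and_ratios(estimate_psd(rng.standard_normal(1000), FS))
        total_rel = sum(bp[f"rel_{b}"] for b in BANDS)
        assert total_rel == pytest.approx(1.0, abs=1e-6)

    def test_band_tones_land_in_their_band(self):
        bp = band_powers_and_ratios(estimate_psd(tone(10, dur=8.0), FS))
        assert bp["rel_alpha"] >= 0.95
        bp2 = band_powers_and_ratios(estimate_psd(tone(2, dur=8.0), FS))
        assert bp2["rel_delta"] > 0.9 and bp2["rel_beta"] <= 0.02


class TestSpectralEdge:
    def test_tone(self):
        sef, peak = spectral_edge_and_peak(estimate_psd(tone(10, dur=8.0), FS))
        assert 9.5 <= sef <= 11.0
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_uniform_spectrum_closed_form(self, rng):
        """Flat 0.5-25 Hz spectrum: SEF95 = 0.5 + 0.95 * 24.5 = 23.775."""
        x = rng.standard_normal(int(120 * FS))
        sef, _ = spectral_edge_and_peak(estimate_psd(x, FS))
        assert sef == pytest.approx(23.775, abs=1.0)

    def test_peak_tie_breaks_low(self):
        f = np.arange(0.5, 25.5, 0.5)
        p = np.ones_like(f)
        p[[10, 20]] = 7.0
        sef, peak = spectral_edge_and_peak(PSDEstimate(f, p))
        assert peak == f[10]


class TestEntropies:
    def test_svd_limits(self, rng):
        assert svd_entropy(np.full(500, 2.5)) == 0.0
        assert svd_entropy(tone(10)) == pytest.approx(1.0, abs=0.2)
        assert svd_entropy(rng.standard_normal(1000)) >= 0.8 * np.log2(10)

    def test_spectral_entropy_limits(self, rng):
        assert spectral_entropy(estimate_psd(tone(10, dur=8.0), FS)) <= 0.3
        assert spectral_entropy(estimate_psd(rng.standard_normal(4000), FS)) >= 0.9

    def test_state_entropy_excludes_slowest_band(self):
        f = np.arange(0.5, 25.5, 0.5)
        p = np.ones_like(f)
        p[0] = 1e4  # power piled below 0.8 Hz
        assert state_entropy(PSDEstimate(f, p)) > spectral_entropy(PSDEstimate(f, p))

    def test_sampen_periodic_is_zero(self):
        assert sample_entropy(np.tile([1.0, 2.0], 100)) == 0.0

    def test_sampen_orders_noise_above_sine(self, rng):
        noise = rng.standard_normal(1000)
        s = tone(10)
        s = s / s.std() * noise.std()
        assert sample_entropy(noise) > sample_entropy(s)

    def test_shannon_five_bits_on_32_levels(self):
        x = np.tile(np.arange(32.0), 10)
        sh, ry = shannon_renyi_entropy(x)
        assert sh == pytest.approx(5.0) and ry == pytest.approx(5.0)

    def test_renyi_never_exceeds_shannon(self, rng):
        for _ in range(10):
            x = rng.standard_normal(500) * rng.uniform(0.1, 50)
            sh, ry = shannon_renyi_entropy(x)
            assert ry <= sh + 1e-12

    def test_permutation_limits(self, rng):
        assert permutation_entropy(np.arange(100.0)) == 0.0
        assert permutation_entropy(rng.uniform(size=10_000)) >= 0.99

    def test_permutation_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(500)
        assert permutation_entropy(np.exp(x)) == pytest.approx(
            permutation_entropy(x), abs=1e-12
        )


class TestFractalDimension:
    def test_line(self):
        assert fractal_dimension(np.arange(1000.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise(self):
        x = np.random.default_rng(42).standard_normal(1000)
        assert fractal_dimension(x) == pytest.approx(2.0, abs=0.15)

    def test_orders_noise_above_sine(self, rng):
        assert fractal_dimension(rng.standard_normal(1000)) > fractal_dimension(tone(10))


class TestFeatureVector:
    def test_identical_channels_equal_single_channel(self, rng):
        x = rng.standard_normal(1000) * 20
        vec = extract_feature_vector(np.vstack([x, x]))
        np.testing.assert_allclose(vec, channel_features(x, FS), rtol=1e-12)

    def test_two_channel_median_is_mean(self, rng):
        a = rng.standard_normal(1000) * 20
        b = rng.standard_normal(1000) * 10
        vec = extract_feature_vector(np.vstack([a, b]))
        expected = (channel_features(a, FS) + channel_features(b, FS)) / 2
        np.testing.assert_allclose(vec, expected, rtol=1e-9)

    def test_nan_channel_falls_back_to_other(self, rng):
        good = rng.standard_normal(1000) * 20
        flat = np.full(1000, 1.0)  # constant: NaN mobility/complexity etc.
        vec = extract_feature_vector(np.vstack([good, flat]))
        idx = FEATURE_NAMES.index("hjorth_mobility")
        assert vec[idx] == pytest.approx(hjorth_parameters(good)[1])

    def test_determinism(self, rng):
        data = rng.standard_normal((2, 1000)) * 15
        v1 = extract_feature_vector(data.copy())
        v2 = extract_feature_vector(data.copy())
        assert np.array_equal(v1, v2, equal_nan=True)

    def test_full_vector_finite_on_synthetic_epoch(self):
        from sedeeg.synth import SEDATED_TEMPLATE, generate_state_epoch

        r = np.random.default_rng(0)
        data = np.vstack(
            [generate_state_epoch(SEDATED_TEMPLATE, 4.0, FS, r) for _ in range(2)]
        )
        vec = extract_feature_vector(data)
        assert vec.shape == (44,)
        assert np.all(np.isfinite(vec))

    def test_amplitude_scale_behavior_table(self, rng):
        """Scaling by c: activity x c^2, rms x c, band powers x c^2; shape
        and entropy features invariant."""
        x = rng.standard_normal((2, 1000)) * 20
        v1 = extract_feature_vector(x)
        v2 = extract_feature_vector(3.0 * x)
        idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
        assert v2[idx["hjorth_activity"]] == pytest.approx(9 * v1[idx["hjorth_activity"]])
        assert v2[idx["rms"]] == pytest.approx(3 * v1[idx["rms"]])
        assert v2[idx["neo"]] == pytest.approx(9 * v1[idx["neo"]])
        for b in BANDS:
            assert v2[idx[f"p_{b}"]] == pytest.approx(9 * v1[idx[f"p_{b}"]], rel=1e-9)
        invariant = (
            ["hjorth_mobility", "hjorth_complexity", "kurtosis", "skewness",
             "sef95", "peak_freq", "svd_entropy", "spectral_entropy",
             "state_entropy", "sample_entropy", "shannon_entropy",
             "renyi_entropy", "permutation_entropy", "fractal_dimension", "bsr"]
            + [f"rel_{b}" for b in BANDS]
        )
        for name in invariant:
            assert v2[idx[name]] == pytest.approx(v1[idx[name]], rel=1e-6, abs=1e-9), name
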