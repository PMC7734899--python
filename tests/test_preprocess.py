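import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedeeg.errors import ConfigError, SamplingError
from sedeeg.preprocess import (
    Epoch,
    epoch_segment,
    extract_segments,
    filter_resample,
    make_bipolar,
    preprocess_recording,
    reject_artifacts,
)
from sedeeg.recording import MOAASEvent, Recording
from sedeeg.synth import GeneratorConfig, generate_cohort, inject_artifacts

CH4 = ["Fp1", "F7", "Fp2", "F8"]


def _rec(signal, fs=250.0, events=(), channels=CH4):
    return Recording(id="t", signal=signal, fs=fs, channel_labels=list(channels),
                     events=list(events))


class TestBipolar:
    def test_identical_electrodes_cancel(self):
        sig = np.tile(np.sin(np.arange(1000) / 10), (4, 1))
        out = make_bipolar(_rec(sig))
        assert np.allclose(out.signal, 0)
        assert out.channel_labels == ["Fp1-F7", "Fp2-F8"]

    def test_linearity(self):
        t = np.arange(1000) / 250
        s = np.sin(2 * np.pi * 5 * t)
        sig = np.vstack([s, -s, np.zeros_like(s), np.zeros_like(s)])
        out = make_bipolar(_rec(sig))
        assert np.allclose(out.signal[0], 2 * s)

    def test_matches_elementwise_oracle(self, rng):
        sig = rng.standard_normal((4, 500))
        out = make_bipolar(_rec(sig))
        assert np.array_equal(out.signal[0], sig[0] - sig[1])
        assert np.array_equal(out.signal[1], sig[2] - sig[3])


class TestFilterResample:
    def test_stopband_tone_attenuated(self):
        fs = 5000.0
        t = np.arange(int(10 * fs)) / fs
        tone = np.sin(2 * np.pi * 50 * t)
        rec = _rec(np.tile(tone, (4, 1)), fs=fs)
        out = filter_resample(rec)
        mid = out.signal[0][500:-500]  # avoid edge transients
        # forward-backward 2nd-order response leaves ~5.5% at one octave
        # above the 25 Hz edge; assert the stop-band suppresses below 8%
        assert np.sqrt(np.mean(mid**2)) < 0.08 * np.sqrt(np.mean(tone**2))

    def test_zero_phase_on_passband_tone(self):
        fs = 250.0
        t = np.arange(int(8 * fs)) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        out = filter_resample(_rec(np.tile(tone, (4, 1)), fs=fs))
        y = out.signal[0]
        lags = np.arange(-20, 21)
        xc = [np.dot(tone[200:-200], np.roll(y, l)[200:-200]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_output_length_and_rate(self):
        fs = 5000.0
        rec = _rec(np.zeros((4, int(10 * fs))) + 1e-12, fs=fs)
        rec.signal[:, 0] = 1.0
        out = filter_resample(rec)
        assert out.fs == 250.0
        assert out.n_samples == 2500

    def test_too_low_rate_rejected(self):
        with pytest.raises(SamplingError):
            filter_resample(_rec(np.zeros((4, 100)), fs=40.0))

    def test_spectrally_near_idempotent(self, rng):
        """Re-filtering band-limited noise changes the 1-20 Hz PSD by <15% RMS
        (the gentle order-2 pass-band rolls off near both band edges)."""
        from sedeeg.features import estimate_psd

        fs = 250.0
        rec = _rec(rng.standard_normal((4, int(60 * fs))), fs=fs)
        once = filter_resample(rec)
        twice = filter_resample(once)
        p1 = estimate_psd(once.signal[0], fs)
        p2 = estimate_psd(twice.signal[0], fs)
        mask = (p1.frequencies >= 1) & (p1.frequencies <= 20)
        rel = np.sqrt(np.mean((p2.psd[mask] - p1.psd[mask]) ** 2)) / np.sqrt(
            np.mean(p1.psd[mask] ** 2)
        )
        assert rel < 0.15


class TestSegments:
    def _long_rec(self, events):
        sig = np.random.default_rng(0).standard_normal((2, int(600 * 250)))
        return Recording(id="t", signal=sig, fs=250.0,
                         channel_labels=["Fp1-F7", "Fp2-F8"], events=list(events))

    def test_label_rule_and_discard(self):
        rec = self._long_rec([MOAASEvent(100, 5), MOAASEvent(300, 2), MOAASEvent(500, 0)])
        segs = extract_segments(rec)
        assert [lbl for _, lbl in segs] == ["awake", "sedated"]

    def test_early_event_skipped(self):
        rec = self._long_rec([MOAASEvent(30, 5)])
        assert extract_segments(rec) == []

    def test_segment_sample_count(self):
        rec = self._long_rec([MOAASEvent(100, 4)])
        (seg, _), = extract_segments(rec)
        assert seg.shape == (2, 15000)

    def test_half_open_window_excludes_assessment_sample(self):
        rec = self._long_rec([MOAASEvent(100, 5)])
        (seg, _), = extract_segments(rec)
        assert np.array_equal(seg, rec.signal[:, 10000:25000])


class TestEpoching:
    def test_sixty_seconds_gives_fifteen_epochs(self, rng):
        seg = rng.standard_normal((2, 15000))
        eps = epoch_segment(seg, "awake", "r", 0)
        assert len(eps) == 15
        assert [e.epoch_index for e in eps] == list(range(15))

    def test_first_epoch_is_first_thousand_samples(self, rng):
        seg = rng.standard_normal((2, 15000))
        eps = epoch_segment(seg, "awake", "r", 0)
        assert np.array_equal(eps[0].data, seg[:, :1000])

    def test_concatenation_recovers_segment(self, rng):
        seg = rng.standard_normal((2, 15000))
        eps = epoch_segment(seg, "sedated", "r", 0)
        assert np.array_equal(np.concatenate([e.data for e in eps], axis=1), seg)

    def test_non_divisible_segment_rejected(self, rng):
        with pytest.raises(ConfigError):
            epoch_segment(rng.standard_normal((2, 14999)), "awake", "r", 0)


class TestReject:
    def _epoch(self, data, label="awake"):
        return Epoch(data=data, label=label, recording_id="r",
                     segment_index=0, epoch_index=0)

    def test_amplitude_rule(self, rng):
        data = rng.standard_normal((2, 1000)) * 20
        data[1, 500] = 600.0
        kept, rejected = reject_artifacts([self._epoch(data)])
        assert kept == [] and rejected[0][1] == "amplitude"

    def test_flat_rule(self, rng):
        data = rng.standard_normal((2, 1000)) * 20
        data[1] = 0.0
        kept, rejected = reject_artifacts([self._epoch(data)])
        assert kept == [] and rejected[0][1] == "flat"

    def test_clean_epochs_kept(self, rng):
        eps = [self._epoch(rng.standard_normal((2, 1000)) * 20) for _ in range(5)]
        kept, rejected = reject_artifacts(eps)
        assert len(kept) == 5 and rejected == []

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        """kept and rejected always partition the input."""
        r = np.random.default_rng(seed)
        eps = []
        for _ in range(6):
            d = r.standard_normal((2, 1000)) * r.uniform(1, 400)
            if r.random() < 0.3:
                d[int(r.integers(2))] = 0.0
            eps.append(self._epoch(d))
        kept, rejected = reject_artifacts(eps)
        assert len(kept) + len(rejected) == len(eps)
        ids = {id(e) for e in kept} | {id(e) for e, _ in rejected}
        assert len(ids) == len(eps)


def test_injected_artifacts_are_exactly_the_rejected_epochs():
    """End-to-end: 3 movement + 2 flat injections -> exactly 5 rejections."""
    rec = generate_cohort(GeneratorConfig(n_subjects=1, n_plateaus=4, seed=13))[0]
    rec2, log = inject_artifacts(rec, 3, 2, np.random.default_rng(4))
    kept, rejected = preprocess_recording(rec2)
    n_segments = len([e for e in rec.events if e.score in (0, 1, 4, 5)])
    assert len(kept) + len(rejected) == 15 * n_segments
    assert len(rejected) == 5
    reasons = sorted(r for _, r in rejected)
    assert reasons == ["amplitude"] * 3 + ["flat"] * 2
    # rejected epochs sit exactly at the logged spans
    injected = set()
    qualifying = [e for e in rec.events if e.score in (0, 1, 4, 5)]
    for span in log:
        for si, ev in enumerate(qualifying):
            t0 = ev.time_s - 60.0
            if t0 - 1e-6 <= span.start_s < ev.time_s:
                injected.add((si, int(round((span.start_s - t0) / 4.0))))
    got = {(ep.segment_index, ep.epoch_index) for ep, _ in rejected}
    assert got == injected


def test_epoch_count_invariant_without_artifacts():
    rec = generate_cohort(GeneratorConfig(n_subjects=1, n_plateaus=4, seed=17))[0]
    kept, rejected = preprocess_recording(rec)
    qualifying = [e for e in rec.events if e.score in (0, 1, 4, 5)]
    assert len(kept) + len(rejected) == 15 * len(qualifying)
    assert {e.label for e in kept} <= {"awake", "sedated"}
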