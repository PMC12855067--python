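"""Welch estimator, normalization arithmetic and peak recovery."""

import numpy as np
import pytest

import somnispike as sp
from somnispike.event_spectral import (GRID_HZ, NormalizedSpectrum,
                                       SpectralError, cohort_peak_summary,
                                       event_psd, event_spectrum,
                                       extract_peaks, normalize,
                                       recording_event_spectra, reference_psd)
from somnispike.types import (ARTIFACT, Channel, Hypnogram, SignalRecording,
                              ValidationError, make_events)

FS = 100.0


def _rec(eeg, fs=FS):
    return SignalRecording([Channel("EEG_frontal", "EEG_frontal", eeg),
                            Channel("EMG", "EMG", np.zeros_like(eeg))], fs)


def _sine_rec(freq, duration_s=4.0, pad_s=30.0, amp=1.0):
    n_pad = int(pad_s * FS)
    t = np.arange(int(duration_s * FS)) / FS
    x = np.zeros(2 * n_pad + len(t))
    x[n_pad:n_pad + len(t)] = amp * np.sin(2 * np.pi * freq * t)
    return _rec(x), pad_s / 1.0, pad_s + duration_s


class TestEventPSD:
    def test_pure_sine_peak_on_padded_grid(self):
        rec, on, off = _sine_rec(6.73)
        f, p = event_psd(rec, on, off)
        assert abs(f[np.argmax(p)] - 6.73) <= 0.05

    def test_white_noise_has_no_spurious_line(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(10):
            rec = _rec(rng.standard_normal(int(12 * FS)))
            f, p = event_psd(rec, 1.0, 11.0)
            sel = (f > 1) & (f < 45)
            if np.max(p[sel]) > 3 * np.median(p[sel]):
                hits += 1
        assert hits <= 2

    def test_zero_segment_gives_zero_psd(self):
        rec = _rec(np.zeros(int(20 * FS)))
        f, p = event_psd(rec, 5.0, 9.0)
        assert np.allclose(p, 0.0)

    def test_too_short_event_rejected(self):
        rec = _rec(np.zeros(int(20 * FS)))
        with pytest.raises(SpectralError):
            event_psd(rec, 5.0, 5.2)

    def test_parseval_consistency(self):
        """Total PSD power within 5% of time-domain variance."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(40 * FS))
        rec = _rec(x)
        f, p = event_psd(rec, 0.0, 40.0)
        var_spec = np.trapezoid(p, f)
        var_time = np.var(x[: int(40 * FS)])
        assert abs(var_spec - var_time) / var_time < 0.05


class TestReference:
    def test_reference_matches_long_segment_on_stationary_noise(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(600 * FS))
        rec = _rec(x)
        hyp = Hypnogram(labels=np.array(["SWS"] * 60))
        f_r, ref = reference_psd(rec, hyp)
        f_e, ev = event_psd(rec, 0.0, 600.0)
        sel = (f_r > 1) & (f_r < 45)
        ratio = ev[sel] / ref[sel]
        # compare band-averaged (0.5-Hz bands) to suppress bin-level noise
        band = ratio[: len(ratio) // 16 * 16].reshape(-1, 16).mean(axis=1)
        assert np.all((band > 0.8) & (band < 1.2))

    def test_artifact_epochs_excluded_from_reference(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(600 * FS))
        labels = np.array(["SWS"] * 60, dtype="<U8")
        labels[30] = ARTIFACT
        contaminated = x.copy()
        contaminated[300 * 100:310 * 100] += 500.0  # huge transient in epoch 30
        rec_dirty = _rec(contaminated)
        _, ref_dirty = reference_psd(rec_dirty, Hypnogram(labels=labels))
        _, ref_clean = reference_psd(_rec(x), Hypnogram(labels=labels))
        assert np.allclose(ref_dirty, ref_clean, rtol=0.05, atol=1e-12)

    def test_all_artifact_rejected(self):
        rec = _rec(np.zeros(int(60 * FS)))
        hyp = Hypnogram(labels=np.array([ARTIFACT] * 6))
        with pytest.raises(SpectralError):
            reference_psd(rec, hyp)


class TestNormalization:
    def _flat(self):
        f = np.fft.rfftfreq(1024, 1 / FS)
        return f, np.ones_like(f)

    def test_identity_ratio_is_flat(self):
        f, p = self._flat()
        spec = normalize(f, p, f, p.copy())
        assert np.allclose(spec.normalized, 100.0 / len(GRID_HZ))
        assert spec.normalized.sum() == pytest.approx(100.0)

    def test_boosted_band_scales_share(self):
        # a x10 boost over a band wider than the grid spacing raises that
        # band's normalized share tenfold relative to the flat share
        f, p = self._flat()
        boosted = p.copy()
        sel = np.abs(f - 10.0) < 0.25
        boosted[sel] *= 10
        spec = normalize(f, boosted, f, p)
        k = np.argmin(np.abs(GRID_HZ - 10.0))
        k_flat = np.argmin(np.abs(GRID_HZ - 20.0))
        assert spec.normalized[k] / spec.normalized[k_flat] == \
            pytest.approx(10.0, rel=0.05)

    def test_zero_reference_bin_floored(self):
        f, p = self._flat()
        ref = p.copy()
        ref[np.argmin(np.abs(f - 10.0))] = 0.0
        spec = normalize(f, p, f, ref)
        assert np.all(np.isfinite(spec.normalized))

    def test_grid_mismatch_rejected(self):
        f, p = self._flat()
        with pytest.raises(ValidationError):
            normalize(f, p, f[:-1], p[:-1])

    def test_scale_invariance_of_normalized_spectrum(self):
        """Multiplying the raw recording by a constant leaves the normalized
        spectrum unchanged."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(120 * FS))
        t = np.arange(int(2 * FS)) / FS
        x[3000:3000 + len(t)] += 5 * np.sin(2 * np.pi * 6.73 * t)
        hyp = Hypnogram(labels=np.array(["SWS"] * 12))
        s1 = event_spectrum(_rec(x), hyp, 30.0, 32.0)
        s2 = event_spectrum(_rec(123.4 * x), hyp, 30.0, 32.0)
        assert np.allclose(s1.normalized, s2.normalized, rtol=1e-8)


class TestPeaks:
    def _spec_from(self, y):
        return NormalizedSpectrum(grid_hz=GRID_HZ.copy(),
                                  normalized=y / y.sum() * 100,
                                  native_f=GRID_HZ, raw_psd=y, reference_psd=y)

    def test_noiseless_sine_peak_within_002(self):
        rec, on, off = _sine_rec(6.73, duration_s=3.0)
        f, p = event_psd(rec, on, off)
        spec = normalize(f, p, f, np.ones_like(p))
        p1, p2 = extract_peaks(spec)
        assert abs(p1 - 6.73) <= 0.02
        assert p2 is None

    def test_two_component_event_recovers_both_peaks(self):
        t = np.arange(int(2 * FS)) / FS
        seg = np.sin(2 * np.pi * 6.73 * t) + 0.45 * np.sin(2 * np.pi * 13.28 * t)
        x = np.zeros(int(70 * FS))
        x[int(30 * FS):int(30 * FS) + len(seg)] = seg
        f, p = event_psd(_rec(x), 30.0, 32.0)
        spec = normalize(f, p, f, np.ones_like(p))
        p1, p2 = extract_peaks(spec)
        assert abs(p1 - 6.73) <= 0.15
        assert abs(p2 - 13.28) <= 0.15

    def test_flat_spectrum_has_no_peaks(self):
        spec = self._spec_from(np.ones_like(GRID_HZ))
        p1, p2 = extract_peaks(spec)
        assert p1 is None and p2 is None


class TestCohortSummary:
    def _fake_spec(self, peak):
        y = np.ones_like(GRID_HZ)
        y += 5 * np.exp(-0.5 * ((GRID_HZ - peak) / 0.3) ** 2)
        return NormalizedSpectrum(grid_hz=GRID_HZ.copy(),
                                  normalized=y / y.sum() * 100,
                                  native_f=GRID_HZ, raw_psd=y, reference_psd=y)

    def test_identical_mice_have_zero_sem(self):
        spec = self._fake_spec(6.7)
        spec.peak1_hz = 6.7
        out = cohort_peak_summary({"m1": [spec], "m2": [spec]})
        assert out["population_mean_event_peak1_hz"] == pytest.approx(6.7, abs=0.05)
        assert out["population_mean_event_peak1_hz_sem"] == 0.0

    def test_mouse_without_events_excluded(self):
        spec = self._fake_spec(6.7)
        spec.peak1_hz = 6.7
        with pytest.warns(UserWarning, match="no events"):
            out = cohort_peak_summary({"m1": [spec], "m2": []})
        assert list(out["per_mouse"]["mouse"]) == ["m1"]
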