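"""Detrending, resampling, FFT spectra and physiological peak attribution."""

import numpy as np
import pytest

from especkle.config import AcquisitionConfig, PhysiologyParams
from especkle.contrast import roi_contrast_series
from especkle.datatypes import ContrastSeries, PowerSpectrum
from especkle.simulate import simulate_stack
from especkle.spectral import (
    RateEstimator,
    attribute_peaks,
    detrend,
    power_spectrum,
    resample_double,
)


def _series(t, k, **kw):
    return ContrastSeries(t=np.asarray(t, float), k=np.asarray(k, float), **kw)


class TestDetrend:
    def test_constant_series_zeroed(self):
        s = detrend(_series(np.arange(10.0), np.full(10, 0.4)))
        assert np.allclose(s.k, 0.0, atol=1e-12)

    def test_pure_line_zeroed(self):
        t = np.linspace(0, 5, 40)
        s = detrend(_series(t, 2 * t + 5))
        assert np.max(np.abs(s.k)) < 1e-9

    def test_sinusoid_survives_line_removal(self):
        """A trend-free oscillation passes through detrending unchanged."""
        t = np.linspace(0, 10, 400)
        raw = 0.05 * np.sin(2 * np.pi * 1.3 * t)
        # orthogonalize against {1, t} so the oscillation itself carries no
        # trend component; detrending must then remove exactly the added line
        wave = raw - np.polyval(np.polyfit(t, raw, 1), t)
        s = detrend(_series(t, wave + 0.7 * t + 2))
        assert np.sqrt(np.mean((s.k - wave) ** 2)) < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend(_series([0, 1, 2], [1, 2, 3]))


class TestResampleDouble:
    def test_uniform_input_reproduced_at_even_indices(self):
        t = np.arange(10) * 0.5
        k = np.sin(t)
        out = resample_double(_series(t, k))
        assert len(out) == 19
        assert np.allclose(out.k[::2], k, atol=1e-12)
        assert np.allclose(np.diff(out.t), out.t[1] - out.t[0])

    def test_length_contract(self):
        out = resample_double(_series([0, 1, 2, 3], [1, 2, 1, 2]))
        assert len(out) == 7

    def test_jittered_sinusoid_peak_at_true_frequency(self):
        rng = np.random.default_rng(1)
        f0, fs, dur = 1.3, 10.0, 40.0
        t = np.arange(dur * fs) / fs
        t = np.sort(t + rng.normal(0, 0.05 / fs * 5, len(t)))
        t = t[np.concatenate([[True], np.diff(t) > 0])]
        s = _series(t, np.sin(2 * np.pi * f0 * t))
        spec = power_spectrum(resample_double(detrend(s)))
        peak = spec.freq[1:][np.argmax(spec.power[1:])]
        assert abs(peak - f0) <= spec.resolution

    def test_records_source_nyquist(self):
        t = np.arange(20) * 0.2  # 5 Hz sampling
        out = resample_double(_series(t, np.ones(20)))
        assert out.source_nyquist == pytest.approx(2.5)

    def test_duplicate_timestamps_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _series([0, 1, 1, 2], [1, 2, 3, 4])


class TestPowerSpectrum:
    def test_pure_tone_at_paper_cardiac_frequency(self):
        """3.5 Hz tone, 21.4 fps, 60 s: argmax lands within one bin of 3.5 Hz."""
        fs, dur = 21.4, 60.0
        t = np.arange(int(fs * dur)) / fs
        s = _series(t, 0.02 * np.sin(2 * np.pi * 3.5 * t) + 0.5)
        spec = power_spectrum(resample_double(detrend(s)))
        peak = spec.freq[1:][np.argmax(spec.power[1:])]
        assert abs(peak - 3.5) <= spec.resolution

    def test_zero_series_all_zero_power(self):
        t = np.arange(16) * 0.1
        spec = power_spectrum(_series(t, np.zeros(16)))
        assert np.allclose(spec.power, 0.0)

    def test_nonuniform_rejected(self):
        t = np.array([0, 0.1, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="resample"):
            power_spectrum(_series(t, np.ones(8)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(_series(np.arange(6) * 0.1, np.ones(6)))


def _spectrum_with_peaks(peak_freqs, fs=20.0, dur=100.0, amp=1.0):
    """Build a spectrum whose only structure is tones at the given frequencies."""
    t = np.arange(int(fs * dur)) / fs
    k = sum(amp * np.sin(2 * np.pi * f * t + 0.3 * i) for i, f in enumerate(peak_freqs))
    k = k + np.random.default_rng(0).normal(0, 1e-3, len(t))
    return power_spectrum(resample_double(detrend(_series(t, k))))


class TestAttributePeaks:
    def test_conversion_is_exact_sixty_times_frequency(self):
        spec = _spectrum_with_peaks([0.38, 1.83])
        rep = attribute_peaks(spec)
        assert rep.estimates
        for e in rep.estimates:
            assert e.rate == e.frequency * 60  # exact arithmetic

    @pytest.mark.parametrize(
        "freq,kind,rate",
        [(2.5, "cardiac", 150.0), (0.13, "respiratory", 7.8)],
    )
    def test_reported_rates(self, freq, kind, rate):
        spec = _spectrum_with_peaks([freq], dur=200.0)
        est = attribute_peaks(spec).primary(kind)
        assert est is not None
        assert est.rate == pytest.approx(rate, abs=spec.resolution * 60)

    def test_uncertainty_is_half_bin(self):
        spec = _spectrum_with_peaks([1.5])
        est = attribute_peaks(spec).primary("cardiac")
        assert est.uncertainty == pytest.approx(spec.resolution * 60 / 2)

    def test_empty_band_flagged(self):
        spec = _spectrum_with_peaks([2.0])  # nothing respiratory
        rep = attribute_peaks(spec)
        assert rep.primary("respiratory") is None
        assert "respiratory" in rep.skipped_bands

    def test_secondary_candidates_listed(self):
        spec = _spectrum_with_peaks([1.83, 2.13], amp=1.0)
        rep = attribute_peaks(spec)
        cardiac = [e for e in rep.estimates if e.kind == "cardiac"]
        assert len(cardiac) >= 2
        assert sum(e.is_primary for e in cardiac) == 1

    def test_overlapping_bands_rejected(self):
        spec = _spectrum_with_peaks([1.5])
        with pytest.raises(ValueError, match="disjoint"):
            attribute_peaks(spec, cardiac_band=(0.8, 4.0), respiratory_band=(0.1, 1.0))

    def test_band_beyond_spectrum_rejected(self):
        spec = _spectrum_with_peaks([1.5], fs=4.0)
        spec = PowerSpectrum(
            freq=spec.freq, power=spec.power,
            source_duration=spec.source_duration, source_nyquist=None,
        )
        with pytest.raises(ValueError, match="beyond the spectrum"):
            attribute_peaks(spec, cardiac_band=(1.0, 10.0))

    def test_aliasing_guard_blocks_undersampled_cardiac_band(self):
        """A 3.5 Hz (210 bpm) rhythm sampled at 5 fps must not produce a
        cardiac call: the band exceeds the source Nyquist of 2.5 Hz."""
        fs = 5.0
        t = np.arange(int(fs * 60)) / fs
        k = 0.05 * np.sin(2 * np.pi * 3.5 * t) + 0.5  # aliases to 1.5 Hz
        spec = power_spectrum(resample_double(detrend(_series(t, k))))
        rep = attribute_peaks(spec, cardiac_band=(1.0, 4.0))
        assert rep.primary("cardiac") is None
        assert "Nyquist" in rep.skipped_bands["cardiac"]


class TestNullBehaviour:
    def test_white_noise_rarely_yields_estimates(self):
        """Under the no-physiology null the peak gate stays quiet (>=90% of
        seeds emit no estimate; calibrated from the exponential statistics
        of periodogram bins)."""
        quiet = 0
        seeds = range(40)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            t = np.arange(600) / 10.0
            s = _series(t, rng.normal(0.5, 0.02, 600))
            spec = power_spectrum(resample_double(detrend(s)))
            rep = attribute_peaks(spec)
            quiet += not rep.estimates
        assert quiet >= 36


class TestRecoveryFromSimulation:
    def test_cardiac_rate_recovered_across_seeds(self):
        """At modulation depth 0.2 with default detector noise, the cardiac
        estimate lands within one spectral bin of truth in >= 18/20 seeds."""
        ok = 0
        for seed in range(20):
            acq = AcquisitionConfig(
                exposure_time=1e-2, nominal_frame_rate=12, wavelengths=(660,),
                frame_count=240, frame_shape=(64, 64),
            )
            phys = PhysiologyParams(
                heart_rate=150, respiratory_rate=30,
                cardiac_modulation_depth=0.2, respiratory_modulation_depth=0.0,
            )
            stacks, _ = simulate_stack(acq, phys, seed=seed)
            series = roi_contrast_series(stacks[660], (16, 48, 16, 48), 7)
            est = RateEstimator().fit(series)
            bin_bpm = est.spectrum_.resolution * 60
            if est.cardiac_rate_ is not None and abs(est.cardiac_rate_ - 150) <= bin_bpm:
                ok += 1
        assert ok >= 18
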