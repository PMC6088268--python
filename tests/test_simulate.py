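"""Simulator statistics: speckle distribution, contrast physics, determinism."""

import numpy as np
import pytest
from scipy import stats

from especkle.config import EXPOSURE_PRESETS, AcquisitionConfig, PhysiologyParams
from especkle.contrast import contrast_map, roi_contrast_series
from especkle.datatypes import SpeckleStack
from especkle.simulate import (
    _integrated_speckle_frame,
    _pupil_mask,
    expected_contrast,
    honeycomb_pattern,
    overlay_fiber_pattern,
    simulate_stack,
)
from especkle.spectral import RateEstimator

ROI = (32, 96, 32, 96)


def _small_acq(**kw):
    defaults = dict(
        exposure_time=1e-2, nominal_frame_rate=10, wavelengths=(660,),
        frame_count=4, frame_shape=(64, 64),
    )
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


class TestContrastModel:
    def test_monotone_decreasing_in_exposure(self):
        """For fixed tau_c, longer exposures blur more speckle: K decreases."""
        ks = [expected_contrast(T, 5e-3) for T in EXPOSURE_PRESETS]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_faster_flow_lowers_contrast(self):
        """Halving tau_c (faster scatterers) lowers K at every preset."""
        for T in EXPOSURE_PRESETS:
            assert expected_contrast(T, 2.5e-3) < expected_contrast(T, 5e-3)

    def test_limits(self):
        assert expected_contrast(1e-6, 1.0) == pytest.approx(1.0, abs=1e-5)
        assert expected_contrast(1.0, 1e-5) < 0.01

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            expected_contrast(0.0, 1e-3)


class TestSpeckleStatistics:
    def test_negative_exponential_intensity(self):
        """Noise-free fully developed speckle intensity is ~exponential.

        Kolmogorov-Smirnov against the fitted exponential at >= 1e4 pixels.
        """
        mask = _pupil_mask((128, 128))
        frame = _integrated_speckle_frame(
            np.random.default_rng(3), mask, tau_c=1.0, exposure_time=5e-4
        )
        x = frame.ravel()
        assert len(x) >= 10_000
        p = stats.kstest(x, "expon", args=(0, x.mean())).pvalue
        assert p > 0.01

    def test_static_speckle_contrast_near_one(self, static_stack):
        """T << tau_c keeps the speckle frozen: window contrast ~ 1 +/- 0.1."""
        stack, _ = static_stack
        k = np.nanmean(contrast_map(stack.frames[0], 7).values)
        assert abs(k - 1.0) <= 0.1

    def test_simulated_contrast_monotone_in_exposure(self):
        """Measured frame contrast decreases across the four exposure presets."""
        ks = []
        for T in EXPOSURE_PRESETS:
            acq = _small_acq(
                exposure_time=T, nominal_frame_rate=min(10.0, 0.9 / T),
                frame_count=2, frame_shape=(128, 128),
            )
            phys = PhysiologyParams(
                cardiac_modulation_depth=0, respiratory_modulation_depth=0
            )
            stacks, _ = simulate_stack(acq, phys, seed=4)
            ks.append(np.nanmean(contrast_map(stacks[660].frames[0], 7).values))
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_fast_flow_roi_darker_than_slow(self):
        """Smaller tau_c (faster flow) gives lower mean K, as in perfusion maps."""
        out = {}
        for tau in (2e-3, 8e-3):
            acq = _small_acq(exposure_time=2e-2, nominal_frame_rate=10,
                             frame_shape=(128, 128), frame_count=2)
            phys = PhysiologyParams(
                cardiac_modulation_depth=0, respiratory_modulation_depth=0,
                baseline_correlation_time=tau,
            )
            stacks, _ = simulate_stack(acq, phys, seed=5)
            out[tau] = np.nanmean(contrast_map(stacks[660].frames[0], 7).values)
        assert out[2e-3] < out[8e-3]


class TestSimulateStack:
    def test_seeded_determinism(self):
        """Identical seed and inputs give bit-identical stacks and truth."""
        acq = _small_acq(wavelengths=(660, 830))
        phys = PhysiologyParams()
        a, ta = simulate_stack(acq, phys, seed=9)
        b, tb = simulate_stack(acq, phys, seed=9)
        for wl in (660, 830):
            assert np.array_equal(a[wl].frames, b[wl].frames)
            assert np.array_equal(a[wl].timestamps, b[wl].timestamps)
        assert np.array_equal(ta.per_frame_tau_c, tb.per_frame_tau_c)

    def test_different_seeds_differ(self):
        acq = _small_acq()
        phys = PhysiologyParams()
        a, _ = simulate_stack(acq, phys, seed=1)
        b, _ = simulate_stack(acq, phys, seed=2)
        assert not np.array_equal(a[660].frames, b[660].frames)

    def test_intensities_within_bit_depth(self):
        acq = _small_acq()
        stacks, _ = simulate_stack(acq, PhysiologyParams(), seed=0)
        f = stacks[660].frames
        assert f.min() >= 0 and f.max() <= 4095

    def test_ground_truth_lengths_match(self):
        acq = _small_acq(frame_count=7)
        _, truth = simulate_stack(acq, PhysiologyParams(), seed=0)
        assert len(truth.per_frame_tau_c) == 7
        assert truth.per_frame_chromophores.shape == (7, 2)
        assert len(truth.timestamps) == 7

    def test_occlusion_raises_contrast_inside_window(self, occlusion_series):
        """Contrast steps up when flow stops and back down after release."""
        s = occlusion_series
        base = s.k[s.t < 25].mean()
        occ = s.k[(s.t >= 30) & (s.t < 50)].mean()
        post = s.k[s.t >= 55].mean()
        assert occ > base * 1.2
        assert post < occ

    def test_zero_modulation_yields_no_rate(self):
        """Without cardiac/respiratory modulation the spectrum is featureless."""
        acq = _small_acq(nominal_frame_rate=10, frame_count=200, frame_shape=(64, 64))
        phys = PhysiologyParams(
            cardiac_modulation_depth=0, respiratory_modulation_depth=0
        )
        stacks, _ = simulate_stack(acq, phys, seed=12)
        series = roi_contrast_series(stacks[660], (16, 48, 16, 48), 7)
        est = RateEstimator().fit(series)
        assert est.cardiac_rate_ is None
        assert est.respiratory_rate_ is None

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(frame_shape=(8, 8))
        with pytest.raises(ValueError):
            AcquisitionConfig(exposure_time=0.2, nominal_frame_rate=10)
        with pytest.raises(ValueError):
            PhysiologyParams(heart_rate=500)
        acq = _small_acq(frame_count=10, nominal_frame_rate=10)  # 1 s recording
        with pytest.raises(ValueError):
            simulate_stack(
                acq, PhysiologyParams(occlusion_window=(0.5, 30.0)), seed=0
            )


class TestFiberOverlay:
    def test_identity_limit(self, static_stack):
        """Vanishing modulation depth leaves frames unchanged up to rounding."""
        stack, _ = static_stack
        out = overlay_fiber_pattern(stack, 8, 1e-9)
        assert np.max(np.abs(out.frames.astype(int) - stack.frames.astype(int))) <= 1

    def test_sixfold_spectral_peaks(self):
        """Spacing-8 honeycomb puts six symmetric peaks at 1/8 cycles/px."""
        from scipy.ndimage import label

        pat = honeycomb_pattern((128, 128), 8, 0.6)
        F = np.abs(np.fft.fft2(pat - pat.mean()))
        fr = np.fft.fftfreq(128)
        rad = np.sqrt(fr[:, None] ** 2 + fr[None, :] ** 2)
        ring = np.abs(rad - 0.125) < 0.015
        strong = F > 0.1 * F.max()
        # all strong components live on the 1/8 ring, clustered in six spots
        # (off-axis gratings leak into a few adjacent bins on this grid)
        assert np.all(ring[strong])
        _, n_clusters = label(np.fft.fftshift(strong))
        assert n_clusters == 6

    def test_pattern_static_over_time(self):
        """The overlay is frame-invariant: applied to a constant stack, the
        pattern component has exactly zero temporal variance per pixel."""
        frames = np.full((5, 32, 32), 1000, dtype=np.uint16)
        stack = SpeckleStack(
            frames=frames, timestamps=np.arange(5.0), wavelength=660,
            exposure_time=1e-2,
        )
        out = overlay_fiber_pattern(stack, 8, 0.5)
        assert np.all(out.frames.var(axis=0) == 0)
        assert out.metadata["fiber_core_spacing_px"] == 8

    def test_bad_parameters_rejected(self, static_stack):
        stack, _ = static_stack
        with pytest.raises(ValueError):
            overlay_fiber_pattern(stack, 2, 0.5)
        with pytest.raises(ValueError):
            overlay_fiber_pattern(stack, 8, 1.5)
        with pytest.raises(ValueError):
            overlay_fiber_pattern(stack, 8, 0.0)
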