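"""Validated configuration models for acquisition, physiology and filtering.

All models round-trip losslessly through JSON (``model_dump_json`` /
``model_validate_json``), which is the on-disk configuration format used by
the command-line interface.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, model_validator

#: Exposure presets used by the endoscopic probe (seconds).
EXPOSURE_PRESETS = (5e-4, 1e-3, 1e-2, 2e-2)


class AcquisitionConfig(BaseModel):
    """Camera/illumination settings for one recording.

    Parameters mirror the endoscopic speckle instrument: a 12-bit CCD
    behind a fiber bundle, illuminated by red (660 nm) and near-infrared
    (830 nm) laser diodes that may alternate frame-by-frame.
    """

    exposure_time: float = 2e-2  # seconds; must not exceed the frame period
    nominal_frame_rate: float = 10.0  # frames/second (per wavelength stream)
    wavelengths: Tuple[int, ...] = (660, 830)  # nm
    frame_count: int = 100  # frames per wavelength stream
    frame_shape: Tuple[int, int] = (128, 128)  # (rows, cols) pixels
    bit_depth: int = 12
    interleaved: bool = False
    timestamp_jitter_sd: Optional[float] = None  # seconds; default 5% of period
    read_noise_sd: float = 2.0  # DN, Gaussian read noise
    shot_noise: bool = True  # Poisson photon noise
    mean_level_fraction: float = 0.15  # mean intensity as fraction of full scale;
    # low enough that the exponential intensity tail rarely saturates 12 bits

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionConfig":
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.nominal_frame_rate <= 0:
            raise ValueError("nominal_frame_rate must be positive")
        if self.exposure_time > 1.0 / self.nominal_frame_rate + 1e-12:
            raise ValueError(
                "exposure_time must not exceed the frame period "
                f"({self.exposure_time} s > {1.0 / self.nominal_frame_rate} s)"
            )
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if min(self.frame_shape) < 16:
            raise ValueError(
                "frame_shape too small to carry a speckle grain; need >= 16x16"
            )
        if self.bit_depth < 8 or self.bit_depth > 16:
            raise ValueError("bit_depth must be within [8, 16]")
        if not self.wavelengths:
            raise ValueError("at least one wavelength is required")
        if not 0 < self.mean_level_fraction < 1:
            raise ValueError("mean_level_fraction must be in (0, 1)")
        return self

    @property
    def frame_period(self) -> float:
        """Seconds between consecutive frames of one wavelength stream."""
        return 1.0 / self.nominal_frame_rate

    @property
    def jitter_sd(self) -> float:
        """Timestamp jitter SD; defaults to 5% of the frame period."""
        if self.timestamp_jitter_sd is not None:
            return self.timestamp_jitter_sd
        return 0.05 * self.frame_period

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


class PhysiologyParams(BaseModel):
    """Ground-truth physiology driving the simulated speckle decorrelation.

    The correlation time ``baseline_correlation_time`` (tau_c) is inversely
    related to red-blood-cell speed; cardiac and respiratory activity
    modulate it sinusoidally.  An optional occlusion window slows flow
    (raising tau_c) and drives the chromophore trajectory according to
    ``occlusion_mode``: ``arterial`` starves the tissue of oxygenated blood
    (Delta HbO2 falls), while ``arteriovenous`` traps venous return so both
    oxy-hemoglobin and total hemoglobin rise (venous pooling).
    """

    heart_rate: float = 180.0  # beats/min
    respiratory_rate: float = 45.0  # breaths/min
    cardiac_modulation_depth: float = 0.3  # fraction of tau_c
    respiratory_modulation_depth: float = 0.2  # fraction of tau_c
    baseline_correlation_time: float = 5e-3  # seconds (tau_c)
    occlusion_window: Optional[Tuple[float, float]] = None  # (t_start, t_end) s
    occlusion_mode: Literal["arterial", "arteriovenous"] = "arterial"
    occlusion_tau_factor: float = 3.0  # fold-increase of tau_c while occluded
    hbo2_baseline: float = 0.0  # mM (relative units)
    hb_baseline: float = 0.0  # mM (relative units)
    occlusion_delta_magnitude: float = 0.3  # mM, asymptotic |Delta C| change
    occlusion_time_constant: float = 5.0  # s, exponential approach of deltas

    @model_validator(mode="after")
    def _check(self) -> "PhysiologyParams":
        if not 30 <= self.heart_rate <= 300:
            raise ValueError("heart_rate must be within [30, 300] bpm")
        if not 5 <= self.respiratory_rate <= 80:
            raise ValueError("respiratory_rate must be within [5, 80] breaths/min")
        for name in ("cardiac_modulation_depth", "respiratory_modulation_depth"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.baseline_correlation_time <= 0:
            raise ValueError("baseline_correlation_time must be positive")
        if self.occlusion_window is not None:
            t0, t1 = self.occlusion_window
            if not 0 <= t0 < t1:
                raise ValueError("occlusion_window must satisfy 0 <= t_start < t_end")
        if self.occlusion_tau_factor < 1:
            raise ValueError("occlusion_tau_factor must be >= 1 (flow slows)")
        return self

    @property
    def cardiac_frequency(self) -> float:
        """Cardiac modulation frequency in Hz."""
        return self.heart_rate / 60.0

    @property
    def respiratory_frequency(self) -> float:
        """Respiratory modulation frequency in Hz."""
        return self.respiratory_rate / 60.0


class FilterSpec(BaseModel):
    """Radially symmetric 2-D Butterworth low-pass specification.

    ``cutoff`` is the -3 dB spatial frequency in cycles/pixel and must lie
    below the Nyquist frequency (0.5 cycles/pixel).
    """

    cutoff: float
    order: int = 4
    domain: Literal["2D-frequency"] = "2D-frequency"

    @model_validator(mode="after")
    def _check(self) -> "FilterSpec":
        if not 0 < self.cutoff < 0.5:
            raise ValueError("cutoff must lie in (0, 0.5) cycles/pixel")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        return self


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration (simulate-or-load through report)."""

    acquisition: AcquisitionConfig = AcquisitionConfig()
    physiology: PhysiologyParams = PhysiologyParams()
    roi: Optional[Tuple[int, int, int, int]] = None  # (r0, r1, c0, c1), half-open
    window_size: int = 7
    filter_spec: Optional[FilterSpec] = None  # None -> auto-detect bundle
    auto_filter: bool = True
    cardiac_band: Tuple[float, float] = (1.0, 4.0)  # Hz
    respiratory_band: Tuple[float, float] = (0.1, 1.0)  # Hz
    min_shift_sd: float = 3.0
    min_duration: float = 5.0  # seconds
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        for band in (self.cardiac_band, self.respiratory_band):
            if band[0] <= 0 or band[1] <= band[0]:
                raise ValueError("bands must satisfy 0 < lo < hi")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        return self
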