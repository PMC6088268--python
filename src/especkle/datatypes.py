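"""In-memory containers for speckle stacks, contrast products and results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

import numpy as np


@dataclass
class SpeckleStack:
    """Time-ordered raw speckle frames at one wavelength.

    Attributes
    ----------
    frames : ndarray, shape (time, rows, cols)
        Raw detector counts (DN).
    timestamps : ndarray, shape (time,)
        Acquisition time of each frame, seconds, strictly increasing.
    wavelength : int
        Illumination wavelength in nm.
    exposure_time : float
        Camera exposure T in seconds.
    bit_depth : int
        Detector bit depth; intensities lie in [0, 2**bit_depth - 1].
    metadata : dict
        Free-form provenance (simulator parameters, file origins, ...).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    wavelength: int
    exposure_time: float
    bit_depth: int = 12
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, rows, cols) array")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError(
                f"timestamp count {len(self.timestamps)} does not match "
                f"frame count {self.frames.shape[0]}"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        full_scale = 2**self.bit_depth - 1
        if self.frames.min() < 0 or self.frames.max() > full_scale:
            raise ValueError(f"intensities must lie in [0, {full_scale}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class ContrastMap:
    """Spatial speckle-contrast image K = sigma / mean per pixel."""

    values: np.ndarray
    wavelength: Optional[int] = None
    window_size: int = 7
    source_frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contrast map must be 2-D")


@dataclass
class ContrastSeries:
    """ROI-averaged contrast versus time.

    ``roi`` is (row_min, row_max, col_min, col_max) with half-open bounds.
    ``source_nyquist`` records half the mean sampling rate of the series
    the data originally came from; interpolation cannot raise it, so peak
    attribution refuses bands that extend beyond it.
    """

    t: np.ndarray
    k: np.ndarray
    roi: Optional[Tuple[int, int, int, int]] = None
    wavelength: Optional[int] = None
    source_nyquist: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.t.shape != self.k.shape or self.t.ndim != 1:
            raise ValueError("t and k must be 1-D arrays of equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def mean_rate(self) -> float:
        """Mean sampling rate in Hz."""
        if len(self.t) < 2:
            raise ValueError("need at least two samples for a sampling rate")
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])


@dataclass
class PowerSpectrum:
    """One-sided magnitude-squared spectrum of a uniform contrast series."""

    freq: np.ndarray
    power: np.ndarray
    source_duration: float
    source_nyquist: Optional[float] = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq.shape != self.power.shape:
            raise ValueError("freq and power must have equal length")
        if np.any(self.freq < 0) or np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be non-negative and strictly increasing")

    @property
    def resolution(self) -> float:
        """Frequency bin width in Hz."""
        return float(self.freq[1] - self.freq[0])


@dataclass
class RateEstimate:
    """A spectral peak attributed to cardiac or respiratory origin."""

    kind: str  # "cardiac" | "respiratory"
    frequency: float  # Hz
    rate: float  # per-minute (bpm or breaths/min); always frequency * 60
    peak_power: float
    band: Tuple[float, float]
    uncertainty: float  # +/- per-minute, from spectral resolution
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("cardiac", "respiratory"):
            raise ValueError("kind must be 'cardiac' or 'respiratory'")
        if not self.band[0] <= self.frequency <= self.band[1]:
            raise ValueError("frequency must lie within its band")
        if self.rate != self.frequency * 60:
            raise ValueError("rate must equal frequency * 60 exactly")


@dataclass
class OcclusionCall:
    """A detected flow-stop episode in a contrast series."""

    onset: float  # seconds
    release: Optional[float]  # seconds, absent if recording ends occluded
    baseline_level: float
    occluded_level: float
    effect_size: float  # (occluded - baseline) / baseline_sd

    def __post_init__(self) -> None:
        if self.release is not None and not self.onset < self.release:
            raise ValueError("onset must precede release")


@dataclass
class OxygenationResult:
    """Ratiometric oxygenation map plus chromophore-change time series."""

    ratio_map: Optional[np.ndarray]
    delta_hbo2: np.ndarray
    delta_hb: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.delta_hbo2 = np.asarray(self.delta_hbo2, dtype=float)
        self.delta_hb = np.asarray(self.delta_hb, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if not (len(self.delta_hbo2) == len(self.delta_hb) == len(self.t)):
            raise ValueError("delta series and t must have equal length")

    @property
    def delta_total(self) -> np.ndarray:
        """Total-hemoglobin change; identically delta_hbo2 + delta_hb."""
        return self.delta_hbo2 + self.delta_hb


@dataclass
class GroundTruth:
    """Hidden simulator state used as the oracle in recovery tests."""

    params: Any  # PhysiologyParams
    per_frame_tau_c: np.ndarray
    per_frame_chromophores: np.ndarray  # shape (n, 2): (dHbO2, dHb)
    timestamps: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.per_frame_tau_c) != n or len(self.per_frame_chromophores) != n:
            raise ValueError("per-frame arrays must match frame count")


@dataclass
class RateReport:
    """All rate estimates found in a spectrum, grouped by attribution."""

    estimates: List[RateEstimate]
    skipped_bands: Dict[str, str] = field(default_factory=dict)

    def primary(self, kind: str) -> Optional[RateEstimate]:
        for e in self.estimates:
            if e.kind == kind and e.is_primary:
                return e
        return None
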