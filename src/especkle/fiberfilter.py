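"""Removal of the static fiber-bundle honeycomb pattern.

A flexible imaging bundle stamps a periodic core pattern onto every frame.
Because the pattern is a narrow-band carrier well above the perfusion
content, a radially symmetric 2-D Butterworth low-pass applied in the
frequency domain suppresses it while leaving low-frequency sample
structure essentially untouched.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .config import FilterSpec


class NoPatternError(RuntimeError):
    """Raised when no periodic bundle pattern is detectable in a frame."""


def butterworth_transfer(
    shape: Tuple[int, int], cutoff: float, order: int
) -> np.ndarray:
    """Radial Butterworth low-pass H(f) = 1 / (1 + (f/cutoff)^(2*order)).

    ``cutoff`` in cycles/pixel; H(0) = 1 exactly, so the mean is preserved.
    """
    fr = np.fft.fftfreq(shape[0])
    fc = np.fft.fftfreq(shape[1])
    rad = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    return 1.0 / (1.0 + (rad / cutoff) ** (2 * order))


def remove_fiber_pattern(frame: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the Butterworth low-pass to one frame; returns float array."""
    x = np.asarray(frame, dtype=float)
    if x.ndim != 2 or min(x.shape) < 16:
        raise ValueError("frame must be 2-D with both dimensions >= 16")
    h = butterworth_transfer(x.shape, spec.cutoff, spec.order)
    return np.fft.ifft2(np.fft.fft2(x) * h).real


def radial_power_profile(
    frame: np.ndarray, n_bins: int = 64
) -> Tuple[np.ndarray, np.ndarray]:
    """Radially averaged 2-D power spectrum of a Hann-windowed frame.

    Returns (bin center frequencies in cycles/pixel, mean power per bin)
    over (0, 0.5]; the DC bin is excluded.
    """
    x = np.asarray(frame, dtype=float)
    wr = np.hanning(x.shape[0])[:, None]
    wc = np.hanning(x.shape[1])[None, :]
    spec = np.abs(np.fft.fft2((x - x.mean()) * wr * wc)) ** 2
    fr = np.fft.fftfreq(x.shape[0])
    fc = np.fft.fftfreq(x.shape[1])
    rad = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    idx = np.digitize(rad.ravel(), edges) - 1
    keep = (idx >= 0) & (idx < n_bins) & (rad.ravel() > 0)
    sums = np.bincount(idx[keep], weights=spec.ravel()[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = counts > 0
    profile = np.full(n_bins, np.nan)
    profile[valid] = sums[valid] / counts[valid]
    return centers[valid], profile[valid]


def estimate_core_spacing(
    frame: np.ndarray,
    min_freq: float = 0.03,
    peak_db_above_median: float = 6.0,
) -> float:
    """Dominant non-DC radial spatial frequency of a bundle-bearing frame.

    Searches the radially averaged power spectrum above ``min_freq`` for
    local maxima; the strongest must exceed the radial-spectrum median by
    ``peak_db_above_median`` dB, otherwise :class:`NoPatternError` is
    raised and the caller may skip filtering.  Returns the peak frequency
    in cycles/pixel (the reciprocal of the core spacing).
    """
    freqs, profile = radial_power_profile(np.asarray(frame, dtype=float))
    sel = freqs >= min_freq
    f, p = freqs[sel], profile[sel]
    if len(p) < 5:
        raise NoPatternError("spectrum too short to search for a bundle peak")
    floor = np.median(p)
    p_db = 10.0 * np.log10(np.maximum(p, 1e-300))
    peaks, _ = find_peaks(p_db, prominence=3.0)
    if len(peaks) == 0:
        raise NoPatternError("no pattern detected")
    best = peaks[np.argmax(p[peaks])]
    if 10.0 * np.log10(p[best] / floor) < peak_db_above_median:
        raise NoPatternError("no pattern detected")
    return float(f[best])


class FiberPatternFilter(BaseEstimator, TransformerMixin):
    """Butterworth low-pass that auto-tunes itself to the bundle frequency.

    Parameters
    ----------
    cutoff : float or None
        Cutoff in cycles/pixel.  ``None`` (default) auto-detects the bundle
        carrier frequency during ``fit`` and sets the cutoff to half of it.
    order : int, default 4
        Butterworth order.

    Attributes (after fit)
    ----------------------
    pattern_detected_ : bool
    bundle_frequency_ : float or None -- detected carrier, cycles/pixel
    core_spacing_ : float or None -- 1 / bundle_frequency_, pixels
    cutoff_ : float or None -- resolved cutoff; None means pass-through
    """

    def __init__(self, cutoff: Optional[float] = None, order: int = 4):
        self.cutoff = cutoff
        self.order = order

    def fit(self, X: np.ndarray, y=None) -> "FiberPatternFilter":
        X = np.asarray(X, dtype=float)
        frame = X.mean(axis=0) if X.ndim == 3 else X
        self.bundle_frequency_ = None
        self.core_spacing_ = None
        if self.cutoff is not None:
            FilterSpec(cutoff=self.cutoff, order=self.order)  # validate
            self.cutoff_ = self.cutoff
            self.pattern_detected_ = True
            return self
        try:
            f = estimate_core_spacing(frame)
        except NoPatternError:
            self.pattern_detected_ = False
            self.cutoff_ = None
            return self
        self.pattern_detected_ = True
        self.bundle_frequency_ = f
        self.core_spacing_ = 1.0 / f
        self.cutoff_ = 0.5 * f
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("FiberPatternFilter must be fitted before transform")
        X = np.asarray(X, dtype=float)
        if self.cutoff_ is None:  # nothing to remove
            return X
        spec = FilterSpec(cutoff=self.cutoff_, order=self.order)
        if X.ndim == 2:
            return remove_fiber_pattern(X, spec)
        if X.ndim == 3:
            h = butterworth_transfer(X.shape[1:], spec.cutoff, spec.order)
            return np.fft.ifft2(np.fft.fft2(X, axes=(1, 2)) * h, axes=(1, 2)).real
        raise ValueError("expected a 2-D frame or 3-D stack")
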