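"""Spatial speckle-contrast estimation.

Speckle contrast K is the ratio of the standard deviation to the mean of
intensity within a local window.  Moving scatterers (red blood cells) blur
the speckle during the exposure and lower K, so low K marks fast flow.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple, Union

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ContrastMap, ContrastSeries, SpeckleStack

log = logging.getLogger(__name__)


def _validate_window(window_size: int) -> None:
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")


def _contrast_values(frame: np.ndarray, window_size: int) -> np.ndarray:
    """K = sample sd / mean over centered windows, reflective borders."""
    x = np.asarray(frame, dtype=float)
    n = window_size * window_size
    m1 = uniform_filter(x, window_size, mode="reflect")
    m2 = uniform_filter(x * x, window_size, mode="reflect")
    # sample (N-1) variance; clip tiny negatives from rounding
    var = np.clip(m2 - m1 * m1, 0.0, None) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(var) / m1
    k[m1 == 0] = np.nan
    return k


class SpatialContrast(BaseEstimator, TransformerMixin):
    """Sliding-window speckle-contrast transformer.

    Parameters
    ----------
    window_size : odd int, default 7
        Side of the square window; 5/7/9 trade spatial resolution against
        K-estimator variance.

    The transformer is stateless; ``fit`` only validates parameters.
    ``transform`` maps a 2-D frame to its contrast map, or a 3-D stack to a
    stack of contrast maps.
    """

    def __init__(self, window_size: int = 7):
        self.window_size = window_size

    def fit(self, X=None, y=None) -> "SpatialContrast":
        _validate_window(self.window_size)
        self.n_features_in_ = 0  # stateless image transformer
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        _validate_window(self.window_size)
        X = np.asarray(X)
        if X.ndim == 2:
            if min(X.shape) < self.window_size:
                raise ValueError("frame smaller than the contrast window")
            return _contrast_values(X, self.window_size)
        if X.ndim == 3:
            return np.stack([_contrast_values(f, self.window_size) for f in X])
        raise ValueError("expected a 2-D frame or 3-D stack")


def contrast_map(
    frame: np.ndarray,
    window_size: int = 7,
    wavelength: Optional[int] = None,
    source_frame_index: int = 0,
) -> ContrastMap:
    """Compute the spatial contrast map of a single frame.

    Per pixel, K = (sample standard deviation / mean) over the centered
    window_size x window_size neighborhood, with reflective padding so the
    output aligns pixel-for-pixel with the input.  Pixels whose window mean
    is zero carry NaN.
    """
    values = SpatialContrast(window_size).fit().transform(np.asarray(frame))
    if values.ndim != 2:
        raise ValueError("contrast_map expects a single 2-D frame")
    return ContrastMap(
        values=values,
        wavelength=wavelength,
        window_size=window_size,
        source_frame_index=source_frame_index,
    )


def roi_contrast_series(
    stack: SpeckleStack,
    roi: Tuple[int, int, int, int],
    window_size: int = 7,
) -> ContrastSeries:
    """ROI-averaged contrast versus time.

    For each frame the contrast map is evaluated over the half-open ROI
    (row_min, row_max, col_min, col_max) and averaged with NaN pixels
    excluded; an all-NaN ROI yields a NaN sample (logged).  The half-window
    margin around the ROI is taken from the frame where available, so ROI
    pixels see their true neighborhoods rather than reflected ones.
    """
    r0, r1, c0, c1 = roi
    rows, cols = stack.frame_shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"roi {roi} empty or outside frame {stack.frame_shape}")
    h = window_size // 2
    rr0, rr1 = max(0, r0 - h), min(rows, r1 + h)
    cc0, cc1 = max(0, c0 - h), min(cols, c1 + h)
    est = SpatialContrast(window_size).fit()
    k = np.empty(stack.n_frames)
    n_all_nan = 0
    for i in range(stack.n_frames):
        kmap = est.transform(stack.frames[i, rr0:rr1, cc0:cc1])
        sub = kmap[r0 - rr0 : r1 - rr0, c0 - cc0 : c1 - cc0]
        if np.all(np.isnan(sub)):
            k[i] = np.nan
            n_all_nan += 1
        else:
            k[i] = np.nanmean(sub)
    if n_all_nan:
        log.warning("%d frames had an all-NaN ROI contrast", n_all_nan)
    ts = stack.timestamps
    nyq = None
    if len(ts) > 1:
        nyq = 0.5 * (len(ts) - 1) / (ts[-1] - ts[0])
    return ContrastSeries(
        t=ts.copy(),
        k=k,
        roi=roi,
        wavelength=stack.wavelength,
        source_nyquist=nyq,
    )


def roi_intensity_series(
    stack: SpeckleStack, roi: Tuple[int, int, int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean raw intensity over the ROI per frame (Beer-Lambert channel)."""
    r0, r1, c0, c1 = roi
    rows, cols = stack.frame_shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"roi {roi} empty or outside frame {stack.frame_shape}")
    vals = stack.frames[:, r0:r1, c0:c1].astype(float).mean(axis=(1, 2))
    return stack.timestamps.copy(), vals
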