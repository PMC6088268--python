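"""Detection of vascular occlusion onset and release in a contrast series.

Stopping flow lengthens the speckle correlation time, so contrast steps
up at occlusion and back down at release.  The detector fits a
three-segment piecewise-constant model (baseline / occluded / released)
by exhaustive two-change-point search (O(n^2) over candidate pairs, fine
at recording scale) and accepts the middle segment only if it exceeds the
baseline by a configurable number of baseline standard deviations for a
minimum duration.  Respiratory spikes are suppressed by a moving median
before fitting.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator

from .datatypes import ContrastSeries, OcclusionCall

log = logging.getLogger(__name__)

#: Minimum samples per fitted segment.
MIN_SEGMENT_SAMPLES = 3


def _despike(t: np.ndarray, y: np.ndarray, width_seconds: float) -> np.ndarray:
    """Moving median over a window of the given duration (odd sample count)."""
    dt = np.median(np.diff(t))
    n = max(3, int(round(width_seconds / dt)))
    if n % 2 == 0:
        n += 1
    n = min(n, len(y) if len(y) % 2 else len(y) - 1)
    return median_filter(y, size=n, mode="nearest")


def _refine_boundary(
    t: np.ndarray,
    y_raw: np.ndarray,
    idx: int,
    level_before: float,
    level_after: float,
    width_seconds: float,
    bounds: tuple,
) -> int:
    """Re-place one change point on the raw series near its coarse position.

    Within +/- half the despiking width around ``idx``, choose the split
    minimizing the squared error of the raw samples against the two fixed
    segment levels.
    """
    dt = np.median(np.diff(t))
    half = max(1, int(round(0.5 * width_seconds / dt)))
    lo = max(bounds[0], idx - half)
    hi = min(bounds[1], idx + half)
    if lo >= hi:
        return idx
    window = slice(max(0, lo - half), min(len(y_raw), hi + half))
    seg = y_raw[window]
    offset = window.start
    best_idx, best_cost = idx, np.inf
    for s in range(lo, hi + 1):
        a = seg[: s - offset] - level_before
        b = seg[s - offset :] - level_after
        cost = float(a @ a + b @ b)
        if cost < best_cost:
            best_cost, best_idx = cost, s
    return best_idx


def detect_occlusion(
    series: ContrastSeries,
    min_shift_sd: float = 3.0,
    min_duration: float = 5.0,
    spike_period: Optional[float] = None,
) -> Optional[OcclusionCall]:
    """Find a single occlusion episode as a transient level increase.

    Parameters
    ----------
    series : ContrastSeries
        ROI-averaged contrast versus time; NaN gaps above 20% reject it.
    min_shift_sd : float, default 3
        Required separation of the occluded level from the baseline, in
        baseline standard deviations.
    min_duration : float, default 5 s
        Minimum duration of the occluded segment.
    spike_period : float, optional
        Expected respiratory spike period in seconds; the despiking
        moving-median window is 3x this value (5 s when not supplied).

    Returns
    -------
    OcclusionCall or None
        Onset/release interpolated to the midpoint between the bracketing
        samples; None when no admissible step is found.
    """
    t_all, y_all = series.t, series.k
    nan_frac = np.mean(~np.isfinite(y_all))
    if nan_frac > 0.2:
        raise ValueError(f"series has {nan_frac:.0%} NaN samples (> 20%)")
    finite = np.isfinite(y_all)
    t, y_raw = t_all[finite], y_all[finite]
    n = len(y_raw)
    duration = t[-1] - t[0]
    if n < 20 or duration < 3 * min_duration:
        raise ValueError(
            "series too short: need >= 20 samples and duration >= 3*min_duration"
        )
    width = 3.0 * spike_period if spike_period is not None else 5.0
    y = _despike(t, y_raw, width)

    # prefix sums for O(1) segment means / SSEs
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(a: int, b: int) -> float:  # [a, b)
        m = b - a
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / m

    best = None
    m = MIN_SEGMENT_SAMPLES
    for i in range(m, n - 2 * m + 1):
        if t[i] - t[0] <= 0:
            continue
        for j in range(i + m, n - m + 1):
            if t[j - 1] - t[i] < min_duration:
                continue
            total = sse(0, i) + sse(i, j) + sse(j, n)
            if best is None or total < best[0]:
                best = (total, i, j)
    # a 3-sample median keeps step edges sharp but removes single-sample
    # modulation spikes that could steal a boundary sample during refinement
    y_ref = median_filter(y_raw, size=3, mode="nearest")

    def _call_from(i: int, j: int) -> Optional[OcclusionCall]:
        base = y[:i]
        base_mean = float(base.mean())
        base_sd = float(base.std(ddof=1))
        occ_mean = float(y[i:j].mean())
        if base_sd == 0:
            base_sd = max(abs(base_mean) * 1e-12, 1e-15)
        effect = (occ_mean - base_mean) / base_sd
        if effect < min_shift_sd or t[j - 1] - t[i] < min_duration:
            return None
        onset = 0.5 * (t[i - 1] + t[i])
        release: Optional[float] = None
        if j < n:
            rel_mean = float(y[j:].mean())
            # the tail must actually return toward baseline to count as release
            if rel_mean <= occ_mean - 1.0 * base_sd:
                release = 0.5 * (t[j - 1] + t[j])
        return OcclusionCall(
            onset=float(onset),
            release=release,
            baseline_level=base_mean,
            occluded_level=occ_mean,
            effect_size=float(effect),
        )

    call = None
    if best is not None:
        _, i, j = best
        # the moving median blurs the step over ~width/2; refine each boundary
        # on the raw series with the fitted levels held fixed
        levels = (y[:i].mean(), y[i:j].mean(), y[j:].mean())
        i = _refine_boundary(t, y_ref, i, levels[0], levels[1], width, (m, j - m))
        # keep the occluded segment at least min_duration long while refining
        j_lo = i + m
        while j_lo < n - m and t[j_lo - 1] - t[i] < min_duration:
            j_lo += 1
        j = _refine_boundary(t, y_ref, j, levels[1], levels[2], width, (j_lo, n - m))
        call = _call_from(i, j)
    if call is not None:
        return call
    # a recording that ends occluded has a single change point; fall back to
    # the best two-segment (step-up, no release) fit
    best2 = None
    for i in range(m, n - m + 1):
        if t[n - 1] - t[i] < min_duration:
            continue
        total = sse(0, i) + sse(i, n)
        if best2 is None or total < best2[0]:
            best2 = (total, i)
    if best2 is None:
        return None
    i = best2[1]
    i = _refine_boundary(t, y_ref, i, y[:i].mean(), y[i:].mean(), width, (m, n - m))
    return _call_from(i, n)


class OcclusionDetector(BaseEstimator):
    """Three-segment change-point occlusion detector.

    Attributes (after fit)
    ----------------------
    call_ : OcclusionCall or None
    onset_, release_ : float or None -- seconds
    """

    def __init__(
        self,
        min_shift_sd: float = 3.0,
        min_duration: float = 5.0,
        spike_period: Optional[float] = None,
    ):
        self.min_shift_sd = min_shift_sd
        self.min_duration = min_duration
        self.spike_period = spike_period

    def fit(self, X: ContrastSeries, y=None) -> "OcclusionDetector":
        self.call_ = detect_occlusion(
            X,
            min_shift_sd=self.min_shift_sd,
            min_duration=self.min_duration,
            spike_period=self.spike_period,
        )
        self.onset_ = self.call_.onset if self.call_ else None
        self.release_ = self.call_.release if self.call_ else None
        return self
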