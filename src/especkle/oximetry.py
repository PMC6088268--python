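"""Dual-wavelength ratiometric oximetry via the modified Beer-Lambert law.

Oxy- and deoxy-hemoglobin absorb differently on either side of the
~800 nm isosbestic point: at 660 nm deoxy-hemoglobin dominates, at 830 nm
oxy-hemoglobin does.  The ratio of backscattered intensities at the two
wavelengths therefore tracks tissue oxygenation, and changes in optical
density resolve into chromophore concentration changes through a 2x2
linear system:

    dOD(lambda, t) = -ln(I(lambda, t) / I(lambda, ref))
                   = L * [eps_HbO2(lambda), eps_Hb(lambda)] . [dC_HbO2, dC_Hb]

With the lumped pathlength factor L = 1 the outputs are in relative
units, which is all a single-geometry endoscopic recording supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.base import BaseEstimator

from .datatypes import OxygenationResult, SpeckleStack

log = logging.getLogger(__name__)


@dataclass
class ExtinctionTable:
    """Molar absorptivities per (mM * mm) for HbO2 and Hb per wavelength.

    Default values follow the standard compiled hemoglobin absorption
    spectra (molar extinction in 1/(cm*M) scaled to 1/(mm*mM)).  The table
    must straddle the isosbestic point: Hb dominates at 660 nm and HbO2 at
    830 nm.
    """

    coeffs: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {
            660: (0.03196, 0.322656),  # (eps_HbO2, eps_Hb)
            830: (0.09740, 0.069304),
        }
    )
    pathlength_factor: float = 1.0  # lumped L * DPF; 1 -> relative units

    def __post_init__(self) -> None:
        for wl, (e_oxy, e_deoxy) in self.coeffs.items():
            if e_oxy <= 0 or e_deoxy <= 0:
                raise ValueError(f"extinction values at {wl} nm must be positive")
        if 660 in self.coeffs and self.coeffs[660][1] <= self.coeffs[660][0]:
            raise ValueError("at 660 nm eps_Hb must exceed eps_HbO2")
        if 830 in self.coeffs and self.coeffs[830][0] <= self.coeffs[830][1]:
            raise ValueError("at 830 nm eps_HbO2 must exceed eps_Hb")
        if self.pathlength_factor <= 0:
            raise ValueError("pathlength_factor must be positive")

    def coefficients(self, wavelength: int) -> Tuple[float, float]:
        return self.coeffs[wavelength]

    def matrix(self, wavelengths: Tuple[int, int] = (660, 830)) -> np.ndarray:
        """Extinction matrix E with rows per wavelength, columns (HbO2, Hb)."""
        return np.array([self.coeffs[wl] for wl in wavelengths], dtype=float)


DEFAULT_EXTINCTION = ExtinctionTable()


def pair_frames(
    stack660: SpeckleStack, stack830: SpeckleStack, max_lag: float
) -> List[Tuple[int, int]]:
    """Greedy nearest-timestamp pairing of two wavelength streams.

    Candidate pairs are taken in order of increasing |dt|; each frame is
    used at most once and pairs with |dt| > max_lag are never formed.
    Raises if no admissible pair exists.  Returns pairs sorted by the
    660 nm frame index.
    """
    if stack660.n_frames == 0 or stack830.n_frames == 0:
        raise ValueError("both stacks must be nonempty")
    t660, t830 = stack660.timestamps, stack830.timestamps
    cands = [
        (abs(t660[i] - t830[j]), i, j)
        for i in range(len(t660))
        for j in range(len(t830))
        if abs(t660[i] - t830[j]) <= max_lag
    ]
    cands.sort()
    used_i: set = set()
    used_j: set = set()
    pairs: List[Tuple[int, int]] = []
    for _, i, j in cands:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    if not pairs:
        raise ValueError(
            "wavelength streams unalignable: no frame pairs within "
            f"max_lag={max_lag} s"
        )
    n_dropped = min(stack660.n_frames, stack830.n_frames) - len(pairs)
    if n_dropped:
        log.info("pair_frames dropped %d frames beyond max_lag", n_dropped)
    return sorted(pairs)


def oxygenation_map(
    frame660: np.ndarray, frame830: np.ndarray, smoothing_window: int = 5
) -> np.ndarray:
    """Per-pixel ratio of locally smoothed 660/830 nm intensities.

    Both frames are mean-smoothed over ``smoothing_window`` (odd) before
    the ratio; pixels where the smoothed 830 nm intensity is zero are NaN.
    The raw ratio is returned; rendering (e.g. red = well oxygenated) is a
    presentation choice left to the plotting layer.
    """
    a = np.asarray(frame660, dtype=float)
    b = np.asarray(frame830, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if smoothing_window % 2 == 0 or smoothing_window < 1:
        raise ValueError("smoothing_window must be odd and >= 1")
    if smoothing_window > 1:
        a = uniform_filter(a, smoothing_window, mode="reflect")
        b = uniform_filter(b, smoothing_window, mode="reflect")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    ratio[b == 0] = np.nan
    return ratio


def chromophore_deltas(
    series660: np.ndarray,
    series830: np.ndarray,
    reference_index: int = 0,
    table: Optional[ExtinctionTable] = None,
    t: Optional[np.ndarray] = None,
    reference_window: int = 1,
) -> OxygenationResult:
    """Chromophore concentration changes from two intensity time series.

    For each sample, dOD(lambda) = -ln(I / I_ref) at both wavelengths is
    inverted through the extinction matrix to give (dC_HbO2, dC_Hb); their
    sum is the total-hemoglobin change.  Nonpositive intensities give NaN
    samples (counted and logged); deltas at the reference sample are zero
    by construction when ``reference_window`` is 1.

    ``reference_window`` averages that many samples starting at
    ``reference_index`` into the reference intensity.  Speckle makes the
    ROI mean of a single frame noisy, and the 2x2 inversion amplifies
    reference noise into a common offset of every delta; averaging a short
    pre-event baseline suppresses it.
    """
    if table is None:
        table = DEFAULT_EXTINCTION
    i660 = np.asarray(series660, dtype=float)
    i830 = np.asarray(series830, dtype=float)
    if i660.shape != i830.shape or i660.ndim != 1 or len(i660) < 2:
        raise ValueError("series must be equal-length 1-D arrays with >= 2 samples")
    if not 0 <= reference_index < len(i660):
        raise ValueError("reference_index out of range")
    if reference_window < 1 or reference_index + reference_window > len(i660):
        raise ValueError("reference_window out of range")
    if t is None:
        t = np.arange(len(i660), dtype=float)
    E = table.pathlength_factor * table.matrix((660, 830))
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular; degenerate table")
    bad = (i660 <= 0) | (i830 <= 0)
    ref = slice(reference_index, reference_index + reference_window)
    ref660 = float(i660[ref].mean())
    ref830 = float(i830[ref].mean())
    if ref660 <= 0 or ref830 <= 0:
        raise ValueError("reference sample has nonpositive intensity")
    with np.errstate(divide="ignore", invalid="ignore"):
        od = -np.stack([np.log(i660 / ref660), np.log(i830 / ref830)])
    deltas = np.linalg.solve(E, od)  # shape (2, n)
    deltas[:, bad] = np.nan
    if bad.any():
        log.warning("%d samples had nonpositive intensity -> NaN", int(bad.sum()))
    return OxygenationResult(
        ratio_map=None, delta_hbo2=deltas[0], delta_hb=deltas[1], t=np.asarray(t, float)
    )


class BeerLambertSolver(BaseEstimator):
    """Modified Beer-Lambert inversion as a fittable estimator.

    ``fit`` takes X of shape (n_samples, 2) holding the ROI-mean
    intensities [I660, I830] and stores the chromophore-change series as
    fitted attributes.

    Attributes (after fit)
    ----------------------
    result_ : OxygenationResult
    delta_hbo2_, delta_hb_, delta_total_ : ndarray
    """

    def __init__(
        self,
        table: Optional[ExtinctionTable] = None,
        reference_index: int = 0,
        reference_window: int = 1,
    ):
        self.table = table
        self.reference_index = reference_index
        self.reference_window = reference_window

    def fit(self, X: np.ndarray, y=None, t: Optional[np.ndarray] = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_samples, 2): [I660, I830]")
        self.result_ = chromophore_deltas(
            X[:, 0], X[:, 1], reference_index=self.reference_index,
            table=self.table, t=t, reference_window=self.reference_window,
        )
        self.delta_hbo2_ = self.result_.delta_hbo2
        self.delta_hb_ = self.result_.delta_hb
        self.delta_total_ = self.result_.delta_total
        return self
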