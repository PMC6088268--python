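"""Extraction of cardiac and respiratory rates from a contrast series.

The processing chain mirrors standard practice for pulse extraction from
slow optical time series: remove the linear trend (DC and drift), linearly
interpolate onto a uniform grid at twice the mean sampling frequency,
apply a Hann taper and a real FFT, then attribute the dominant spectral
peaks inside physiologically motivated bands (respiration 0.1-1 Hz,
cardiac 1-4 Hz by default) to per-minute rates via rate = 60 * frequency.

Peak attribution refuses any band that extends beyond the Nyquist
frequency of the ORIGINAL sampling: interpolation doubles the grid but
cannot recover rhythms faster than half the true frame rate, so e.g. a
210 bpm heart cannot be reported from a 5 fps recording.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks, get_window
from sklearn.base import BaseEstimator

from .datatypes import ContrastSeries, PowerSpectrum, RateEstimate, RateReport

log = logging.getLogger(__name__)

#: Peak must exceed this multiple of the band's median power to count.
DEFAULT_SNR_MIN = 15.0


def detrend(series: ContrastSeries) -> ContrastSeries:
    """Subtract the least-squares linear trend (slope and intercept)."""
    if len(series) < 4:
        raise ValueError("detrend requires at least 4 samples")
    if not np.all(np.isfinite(series.k)):
        raise ValueError("series contains non-finite samples; drop them first")
    coef = np.polyfit(series.t, series.k, 1)
    k = series.k - np.polyval(coef, series.t)
    return ContrastSeries(
        t=series.t.copy(),
        k=k,
        roi=series.roi,
        wavelength=series.wavelength,
        source_nyquist=series.source_nyquist,
    )


def resample_double(series: ContrastSeries) -> ContrastSeries:
    """Linearly interpolate onto a uniform grid at double the mean rate.

    The output spans [t0, t_end] with 2N - 1 points, so for an
    already-uniform input every original sample reappears at the even
    output indices.  The original Nyquist frequency is recorded on the
    output (``source_nyquist``); interpolation cannot raise it.
    """
    if len(series) < 4:
        raise ValueError("resample requires at least 4 samples")
    if np.any(np.diff(series.t) == 0):
        raise ValueError("duplicate timestamps")
    n_out = 2 * len(series) - 1
    t_new = np.linspace(series.t[0], series.t[-1], n_out)
    k_new = np.interp(t_new, series.t, series.k)
    nyq = series.source_nyquist
    if nyq is None:
        nyq = 0.5 * series.mean_rate
    return ContrastSeries(
        t=t_new,
        k=k_new,
        roi=series.roi,
        wavelength=series.wavelength,
        source_nyquist=nyq,
    )


def power_spectrum(series: ContrastSeries, window: str = "hann") -> PowerSpectrum:
    """One-sided magnitude-squared FFT spectrum of a uniform series."""
    if len(series) < 8:
        raise ValueError("power_spectrum requires at least 8 samples")
    dt = np.diff(series.t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("series is not uniform; apply resample_double first")
    taper = get_window(window, len(series))
    spec = np.fft.rfft(series.k * taper)
    power = np.abs(spec) ** 2
    freq = np.fft.rfftfreq(len(series), d=float(dt[0]))
    return PowerSpectrum(
        freq=freq,
        power=power,
        source_duration=float(series.t[-1] - series.t[0]),
        source_nyquist=series.source_nyquist,
    )


def _band_peaks(
    spectrum: PowerSpectrum,
    band: Tuple[float, float],
    snr_min: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima inside a band passing the SNR gate.

    Returns (frequencies, powers, all-band powers).  The gate requires a
    peak to exceed ``snr_min`` times the band's median power, which keeps
    the false-call probability low when the band holds only noise.
    """
    in_band = (spectrum.freq >= band[0]) & (spectrum.freq <= band[1])
    in_band[0] = False  # DC never participates
    idx = np.flatnonzero(in_band)
    if len(idx) < 3:
        return np.array([]), np.array([]), spectrum.power[idx]
    lo = max(idx[0] - 1, 1)
    hi = min(idx[-1] + 2, len(spectrum.power))
    seg = spectrum.power[lo:hi]
    floor = np.median(spectrum.power[idx])
    peaks, _ = find_peaks(seg)
    if len(peaks) == 0:
        return np.array([]), np.array([]), spectrum.power[idx]
    pk = peaks + lo
    keep = in_band[pk] & (spectrum.power[pk] >= snr_min * max(floor, 1e-300))
    pk = pk[keep]
    return spectrum.freq[pk], spectrum.power[pk], spectrum.power[idx]


def attribute_peaks(
    spectrum: PowerSpectrum,
    cardiac_band: Tuple[float, float] = (1.0, 4.0),
    respiratory_band: Tuple[float, float] = (0.1, 1.0),
    snr_min: float = DEFAULT_SNR_MIN,
    previous: Optional[dict] = None,
) -> RateReport:
    """Attribute band-restricted spectral peaks to per-minute rates.

    The highest admissible local maximum in each band becomes the primary
    estimate (rate = 60 * frequency exactly); further admissible maxima are
    listed as secondary candidates.  If two maxima are within 5% power, the
    one closer to ``previous[kind]`` (Hz) wins when supplied, otherwise the
    higher frequency.  A band whose upper edge exceeds the source Nyquist
    frequency yields no estimate and is flagged (aliased rhythms are not
    reported); a band beyond the spectrum itself is an error.
    """
    if not (cardiac_band[1] <= respiratory_band[0] or respiratory_band[1] <= cardiac_band[0]):
        raise ValueError("cardiac and respiratory bands must be disjoint")
    fmax = spectrum.freq[-1]
    report = RateReport(estimates=[])
    half_bin = spectrum.resolution * 60.0 / 2.0
    for kind, band in (("cardiac", cardiac_band), ("respiratory", respiratory_band)):
        if band[0] <= 0 or band[1] <= band[0]:
            raise ValueError(f"invalid {kind} band {band}")
        if spectrum.source_nyquist is not None and band[1] > spectrum.source_nyquist + 1e-9:
            report.skipped_bands[kind] = (
                f"band upper edge {band[1]:.3g} Hz exceeds the source Nyquist "
                f"frequency {spectrum.source_nyquist:.3g} Hz; rhythms in this "
                "band are undetectable (aliased) at this frame rate"
            )
            log.warning("%s band skipped: %s", kind, report.skipped_bands[kind])
            continue
        if band[1] > fmax + 1e-12:
            raise ValueError(
                f"{kind} band {band} extends beyond the spectrum ({fmax:.3g} Hz)"
            )
        freqs, powers, _ = _band_peaks(spectrum, band, snr_min)
        if len(freqs) == 0:
            report.skipped_bands[kind] = "no peak above the prominence threshold"
            continue
        order = np.argsort(powers)[::-1]
        best = order[0]
        # near-tie resolution within 5% power
        ties = [i for i in order if powers[i] >= 0.95 * powers[best]]
        if len(ties) > 1:
            if previous and kind in previous:
                best = min(ties, key=lambda i: abs(freqs[i] - previous[kind]))
            else:
                best = max(ties, key=lambda i: freqs[i])
        for i in order:
            report.estimates.append(
                RateEstimate(
                    kind=kind,
                    frequency=float(freqs[i]),
                    rate=float(freqs[i]) * 60,
                    peak_power=float(powers[i]),
                    band=band,
                    uncertainty=half_bin,
                    is_primary=bool(i == best),
                )
            )
    return report


class RateEstimator(BaseEstimator):
    """Cardiac/respiratory rate extraction from a contrast series.

    Runs detrend -> uniform resampling at double frequency -> Hann-tapered
    FFT -> band-restricted peak attribution.

    Parameters
    ----------
    cardiac_band, respiratory_band : (Hz, Hz)
    window : str, FFT taper name (default "hann")
    snr_min : float, peak gate in multiples of the band median power

    Attributes (after fit)
    ----------------------
    spectrum_ : PowerSpectrum
    report_ : RateReport
    cardiac_rate_ : float or None -- bpm
    respiratory_rate_ : float or None -- breaths/min
    """

    def __init__(
        self,
        cardiac_band: Tuple[float, float] = (1.0, 4.0),
        respiratory_band: Tuple[float, float] = (0.1, 1.0),
        window: str = "hann",
        snr_min: float = DEFAULT_SNR_MIN,
    ):
        self.cardiac_band = cardiac_band
        self.respiratory_band = respiratory_band
        self.window = window
        self.snr_min = snr_min

    def fit(self, X: ContrastSeries, y=None) -> "RateEstimator":
        finite = np.isfinite(X.k)
        if not finite.all():
            log.warning("dropping %d non-finite samples", int((~finite).sum()))
            X = ContrastSeries(
                t=X.t[finite], k=X.k[finite], roi=X.roi,
                wavelength=X.wavelength, source_nyquist=X.source_nyquist,
            )
        uniform = resample_double(detrend(X))
        self.spectrum_ = power_spectrum(uniform, window=self.window)
        self.report_ = attribute_peaks(
            self.spectrum_,
            cardiac_band=self.cardiac_band,
            respiratory_band=self.respiratory_band,
            snr_min=self.snr_min,
        )
        card = self.report_.primary("cardiac")
        resp = self.report_.primary("respiratory")
        self.cardiac_rate_ = card.rate if card else None
        self.respiratory_rate_ = resp.rate if resp else None
        return self
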