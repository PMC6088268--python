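# Methods

This note documents the models, parameter choices and numerical details
behind `especkle`, and what the synthetic recordings do and do not show
about real endoscopic data.

## Speckle synthesis

Each frame is fully developed speckle: a complex circular-Gaussian field
whose Fourier support is a disk of radius 0.30 cycles/pixel, giving a
speckle grain of about 2 px (grain diameter defined as the first zero of
the field autocorrelation, ≈ 0.61/radius). Because the field is Gaussian,
the single-point intensity is exactly negative-exponential, the defining
first-order statistic of polarized speckle.

Temporal decorrelation during the exposure is modeled with an AR(1) chain
over N = 10 sub-exposure steps: the Fourier coefficients evolve as
`E_{k+1} = rho E_k + sqrt(1 - rho^2) eta` with `rho = exp(-dt/tau_c)`,
which realizes the Lorentzian field correlation `g1(t) = exp(-t/tau_c)`.
The recorded frame is the mean intensity of the sub-fields. In the
continuum limit this yields the triangular-weighted exposure integral

    K^2 = (e^{-2x} - 1 + 2x) / (2 x^2),   x = T / tau_c,

while the package's pure model function `expected_contrast` implements
the classic form `K^2 = (tau_c/2T)(1 - exp(-2T/tau_c))`. The two differ
quantitatively at large `T/tau_c` but are both strictly monotone in
`T/tau_c`; the analysis chain never assumes either form, and the model
function is deliberately a swappable single-purpose function.

Measured window contrast of simulated static speckle is ~0.93–0.95 rather
than exactly 1: pixels two grains apart are slightly correlated and the
sample standard deviation of exponential variates is biased low at window
size 7. This matches what real LASCA cameras show and stays within the
0.9–1.1 band the tests require.

## Physiology and detector model

The correlation time is modulated multiplicatively,

    tau_c(t) = tau_c0 * [1 + d_c sin(2 pi f_c t) + d_r sin(2 pi f_r t)],

with defaults `tau_c0 = 5 ms`, cardiac depth `d_c = 0.3`, respiratory
depth `d_r = 0.2` — strong enough to mimic the clearly visible spectral
peaks of in-vivo recordings while keeping the contrast series far from
clipping. During an occlusion window tau_c is multiplied by 3 (flow
slows, contrast rises). The chromophore trajectory approaches its
occluded asymptote exponentially (time constant 5 s, magnitude 0.3 mM in
relative units): arterial mode lowers ΔHbO2 and raises ΔHb (the trapped
blood deoxygenates); arteriovenous mode raises ΔHbO2 and total hemoglobin
(venous pooling). Mean frame intensity at each wavelength follows the
Beer–Lambert forward model with the same extinction table the inversion
uses, so oximetry recovery is testable against ground truth.

Detection: mean level 15% of the 12-bit full scale (so the exponential
intensity tail almost never saturates), Poisson shot noise, Gaussian read
noise of 2 DN, rounding to integers, clipping to [0, 4095]. Frame
timestamps are nominal times plus Gaussian jitter of 5% of the frame
period (clipped at 40% so timestamps stay strictly increasing). With two
wavelengths the streams are offset by half a frame period, mirroring
alternating-laser acquisition.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical inputs are bit-identical.

## Spatial contrast

`K = sample std (N−1) / mean` over a centered odd window (default 7×7,
configurable 5/7/9), computed with box filters; borders are padded by
reflection with the edge pixel repeated, so maps align pixel-for-pixel
with frames. Windows with zero mean give NaN, and ROI averaging skips
NaN pixels (an all-NaN ROI sample is NaN and logged). The implementation
is tested for exact agreement (1e-10) with an explicit per-pixel loop
and for scale invariance at 1e-12.

## Fiber-bundle filtering

The bundle carrier is detected on the radially averaged 2-D power
spectrum of the (time-averaged, Hann-windowed) frame: the strongest local
maximum above 0.03 cycles/px must exceed the radial median by 6 dB,
otherwise "no pattern" is signalled and filtering is skipped. The cutoff
defaults to half the detected carrier frequency; the filter is a radially
symmetric frequency-domain Butterworth low-pass
`H(f) = 1 / (1 + (f/cutoff)^{2 order})` of order 4, unit DC gain (mean
preserved), applied per raw frame before contrast computation. At the
default settings the carrier of an 8 px-spacing honeycomb drops by ~50 dB
while content below 0.02 cycles/px is attenuated < 1 dB. Note the filter
also removes high-frequency speckle structure — filtered contrast values
are only comparable to other filtered contrast values, which is how the
pipeline uses them.

## Rate extraction

Detrending subtracts the least-squares line (removes DC and slow drift,
including occlusion ramps). Resampling interpolates linearly onto a
uniform grid of 2N−1 points spanning the original time range — double
the mean sampling frequency — so uniform inputs are reproduced exactly at
even indices. The spectrum is the one-sided squared magnitude of the
Hann-tapered real FFT.

Peak attribution searches each band (defaults: respiration 0.1–1 Hz,
cardiac 1–4 Hz) for local maxima exceeding 15× the band's median power.
That gate was calibrated on the null: periodogram bins of a featureless
series are approximately exponential, so the expected false-call
probability per band is `m * 2^-15` for m in-band bins (~0.5% at desk
scale); genuine modulation peaks exceed the gate by orders of magnitude.
The strongest admissible maximum is the primary estimate
(`rate = 60 × frequency`, uncertainty ± half a bin in per-minute units);
further admissible maxima are reported as secondary candidates. Ties
within 5% power prefer a caller-supplied previous frequency, else the
higher frequency.

Interpolation cannot create information above half the original frame
rate, so the resampled series carries its source Nyquist frequency and
any band whose upper edge exceeds it is refused with an explicit
"aliased" flag — e.g. a cardiac band of 1–4 Hz on a 5 fps recording.

## Oximetry

The default extinction table (per mM per mm, from the standard compiled
hemoglobin spectra) is {660 nm: (0.03196, 0.32266), 830 nm: (0.09740,
0.06930)} as (eps_HbO2, eps_Hb); construction enforces the defining sign
structure (Hb dominant at 660, HbO2 at 830). The lumped pathlength factor
defaults to 1, so all outputs are relative concentration changes — a
single-geometry endoscopic recording cannot support absolute
quantitation.

Frames from the two wavelength streams are paired greedily by nearest
timestamp (each frame used once, pairs beyond `max_lag` dropped and
counted). The oxygenation map is the per-pixel ratio of locally
mean-smoothed intensities I660/I830; its rendering direction is a
presentation choice. Concentration changes invert the 2×2 extinction
system from ΔOD = −ln(I/I_ref); the reference is the first sample by
default, configurable by index, and optionally an average of
`reference_window` samples — the ROI mean of a single speckle frame
carries ~1–2% noise that the ill-conditioned inversion amplifies into
offsets of ~0.2 relative-mM, and a short averaged baseline suppresses
this. The inversion is exact to 1e-9 on round-trip tests and invariant
to per-channel gains.

## Occlusion detection

Respiratory spikes are suppressed by a moving median of width 3× the
expected spike period (5 s when unknown), then an exhaustive two-change-
point search (O(n²), fine at recording scale) minimizes the SSE of a
three-segment piecewise-constant fit with at least 3 samples per segment
and a minimum occluded duration of 5 s. Boundaries are then refined on a
3-sample median of the raw series with the fitted levels held fixed,
because the wide despiking median blurs edges by up to ~1.5 samples.
A call requires the occluded level to exceed the baseline by ≥ 3 baseline
standard deviations; the release segment must drop back toward baseline,
otherwise the recording is treated as ending occluded, for which a
two-segment (no-release) fit is the fallback. Onset and release are the
midpoints between bracketing samples, so they shift exactly with any
time-origin shift.

Known limitation: when a deep modulation trough coincides with the onset,
the first occluded frame can be contrast-ambiguous and the detected onset
may shift by ~1.5 sample intervals for some seeds — a property of the
signal, not of the fit.

## Problem sizes and defaults

Simulated frames default to 128×128 px at 12-bit depth (pixel pitch left
symbolic — the probe's physical scale is not modeled). The end-to-end
rate checks use 60–120 s recordings at 10–21.4 fps (1200–1284 frames);
the occlusion protocol uses 104 frames at 1.6 fps; property tests run at
64×64 or on constructed series. A full recording simulation takes a few
seconds on one CPU.

## What the simulator does not capture

No wave-optics propagation, fiber-core sampling physics, polarization or
layered-tissue Monte Carlo; no motion artifacts, probe drift or contact
pressure changes; chromophore dynamics are smooth exponentials rather
than pulsatile; speckle grain and modulation depths are spatially
uniform. Passing tests therefore demonstrate correctness of the
processing chain under controlled statistics that mimic real recordings'
first- and second-order structure — not robustness to every in-vivo
nuisance.
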