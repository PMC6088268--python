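"""Synthetic dual-wavelength speckle acquisition with known ground truth.

The generator emulates an endoscopic laser speckle recording: each frame is
fully developed speckle produced by low-pass filtering a complex circular
Gaussian field (speckle grain about two pixels), temporally decorrelated
during the exposure by an AR(1) chain whose correlation time tau_c tracks
the simulated physiology.  Cardiac and respiratory activity modulate tau_c
sinusoidally; a vascular occlusion multiplies tau_c (flow slows, contrast
rises) and drives a chromophore trajectory whose Beer-Lambert attenuation
shapes the mean intensity at each wavelength.  Detection is modeled as
Poisson shot noise plus Gaussian read noise, quantized to the configured
bit depth.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from .config import AcquisitionConfig, PhysiologyParams
from .datatypes import GroundTruth, SpeckleStack

#: Number of sub-exposure integration steps of the AR(1) speckle chain.
N_SUBSTEPS = 10

#: Pupil radius in cycles/pixel.  The speckle grain diameter (first zero of
#: the field autocorrelation, ~0.61/radius) is then about 2 px.
PUPIL_RADIUS = 0.30


def expected_contrast(exposure_time: float, tau_c: float) -> float:
    """Speckle contrast K for exposure T and correlation time tau_c.

    Uses the Lorentzian-velocity-spectrum model

        K^2 = (tau_c / 2T) * (1 - exp(-2T / tau_c)),

    the canonical single-exposure LASCA relation.  K -> 1 as T/tau_c -> 0
    (static scatterers) and K -> 0 as T/tau_c -> inf (fast flow).
    """
    if exposure_time <= 0 or tau_c <= 0:
        raise ValueError("exposure_time and tau_c must be positive")
    x = 2.0 * exposure_time / tau_c
    # expm1 keeps precision when x is tiny (T << tau_c)
    return math.sqrt(-math.expm1(-x) / x)


def _pupil_mask(shape: Tuple[int, int]) -> np.ndarray:
    """Boolean low-pass pupil in FFT layout selecting |f| <= PUPIL_RADIUS."""
    fr = np.fft.fftfreq(shape[0])
    fc = np.fft.fftfreq(shape[1])
    rad = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    return rad <= PUPIL_RADIUS


def _integrated_speckle_frame(
    rng: np.random.Generator,
    mask: np.ndarray,
    tau_c: float,
    exposure_time: float,
    n_steps: int = N_SUBSTEPS,
) -> np.ndarray:
    """One exposure-integrated speckle intensity frame with unit mean.

    A complex Gaussian field restricted to the pupil evolves as an AR(1)
    chain with step correlation exp(-dt/tau_c); the intensities of the
    n_steps sub-fields are averaged, emulating integration during the
    exposure.  The output expectation is exactly 1 per pixel.
    """
    shape = mask.shape
    n_mask = int(mask.sum())
    dt = exposure_time / n_steps
    rho = math.exp(-dt / tau_c)
    mix = math.sqrt(1.0 - rho * rho)

    def draw() -> np.ndarray:
        z = rng.standard_normal(n_mask) + 1j * rng.standard_normal(n_mask)
        return z

    coeffs = draw()
    spec = np.zeros(shape, dtype=complex)
    acc = np.zeros(shape, dtype=float)
    for step in range(n_steps):
        if step:
            coeffs = rho * coeffs + mix * draw()
        spec[mask] = coeffs
        field = np.fft.ifft2(spec)
        acc += field.real**2 + field.imag**2
    # E[|ifft2|^2] = 2 * n_mask / (M*N)^2 for unit-variance parts
    norm = 2.0 * n_mask / (shape[0] * shape[1]) ** 2
    return acc / (n_steps * norm)


def _tau_c_trajectory(t: np.ndarray, phys: PhysiologyParams) -> np.ndarray:
    """Correlation time per time point, with modulation and occlusion."""
    tau = np.full_like(t, phys.baseline_correlation_time)
    mod = phys.cardiac_modulation_depth * np.sin(
        2 * np.pi * phys.cardiac_frequency * t
    ) + phys.respiratory_modulation_depth * np.sin(
        2 * np.pi * phys.respiratory_frequency * t
    )
    tau = tau * np.clip(1.0 + mod, 0.05, None)
    if phys.occlusion_window is not None:
        t0, t1 = phys.occlusion_window
        tau = np.where((t >= t0) & (t < t1), tau * phys.occlusion_tau_factor, tau)
    return tau


def _chromophore_trajectory(
    t: np.ndarray, phys: PhysiologyParams
) -> np.ndarray:
    """(Delta HbO2, Delta Hb) in relative mM at each time point.

    Deltas are zero outside an occlusion.  During occlusion they approach
    mode-dependent asymptotes exponentially (time constant
    ``occlusion_time_constant``); after release they decay back.  Arterial
    occlusion starves the bed of oxygenated inflow (Delta HbO2 falls, Hb
    rises as it deoxygenates); arteriovenous occlusion also traps venous
    return, so HbO2 and total hemoglobin both rise (venous pooling).
    """
    d = np.zeros((len(t), 2))
    if phys.occlusion_window is None:
        return d
    t0, t1 = phys.occlusion_window
    mag = phys.occlusion_delta_magnitude
    tc = phys.occlusion_time_constant
    if phys.occlusion_mode == "arterial":
        asym = np.array([-mag, 0.5 * mag])
    else:  # arteriovenous
        asym = np.array([mag, 0.5 * mag])
    during = (t >= t0) & (t < t1)
    after = t >= t1
    rise = 1.0 - np.exp(-(t[during] - t0) / tc)
    d[during] = rise[:, None] * asym[None, :]
    level_at_release = (1.0 - math.exp(-(t1 - t0) / tc)) * asym
    decay = np.exp(-(t[after] - t1) / tc)
    d[after] = decay[:, None] * level_at_release[None, :]
    return d


def _beer_lambert_attenuation(
    wavelength: int, deltas: np.ndarray, extinction: Dict[int, Tuple[float, float]]
) -> np.ndarray:
    """Relative transmitted intensity exp(-eps . dC) per time point."""
    eps_hbo2, eps_hb = extinction[wavelength]
    od = eps_hbo2 * deltas[:, 0] + eps_hb * deltas[:, 1]
    return np.exp(-od)


def _timestamps(
    config: AcquisitionConfig, rng: np.random.Generator, offset: float
) -> np.ndarray:
    """Nominal frame times plus clipped Gaussian jitter, strictly increasing."""
    period = config.frame_period
    nominal = offset + np.arange(config.frame_count) * period
    jitter = rng.normal(0.0, config.jitter_sd, config.frame_count)
    np.clip(jitter, -0.4 * period, 0.4 * period, out=jitter)
    return nominal + jitter


def simulate_stack(
    config: AcquisitionConfig,
    physiology: PhysiologyParams,
    seed: int,
    extinction: Optional[Dict[int, Tuple[float, float]]] = None,
) -> Tuple[Dict[int, SpeckleStack], GroundTruth]:
    """Simulate one recording; returns one stack per wavelength + ground truth.

    Parameters
    ----------
    config : AcquisitionConfig
        Camera and illumination settings.
    physiology : PhysiologyParams
        Hidden physiology driving decorrelation and chromophores.
    seed : int
        Seeds all randomness; identical calls are bit-identical.
    extinction : dict, optional
        wavelength -> (eps_HbO2, eps_Hb) per (mM mm); defaults to the
        package's hemoglobin table.

    Returns
    -------
    stacks : dict mapping wavelength (nm) to SpeckleStack
    truth : GroundTruth
        Per-frame tau_c, chromophore deltas and timestamps of the first
        wavelength stream.
    """
    if extinction is None:
        from .oximetry import DEFAULT_EXTINCTION

        extinction = {
            wl: DEFAULT_EXTINCTION.coefficients(wl) for wl in config.wavelengths
        }
    duration = config.frame_count * config.frame_period
    if physiology.occlusion_window is not None:
        if physiology.occlusion_window[1] > duration + config.frame_period:
            raise ValueError(
                f"occlusion window {physiology.occlusion_window} extends beyond "
                f"the {duration:.2f} s recording"
            )

    rng = np.random.default_rng(seed)
    mask = _pupil_mask(config.frame_shape)
    mean_dn = config.mean_level_fraction * config.full_scale
    stacks: Dict[int, SpeckleStack] = {}
    truth: Optional[GroundTruth] = None

    for i_wl, wl in enumerate(config.wavelengths):
        offset = (
            i_wl * config.frame_period / len(config.wavelengths)
            if config.interleaved or len(config.wavelengths) > 1
            else 0.0
        )
        ts = _timestamps(config, rng, offset)
        tau = _tau_c_trajectory(ts, physiology)
        chrom = _chromophore_trajectory(ts, physiology)
        atten = _beer_lambert_attenuation(wl, chrom, extinction)

        frames = np.empty(
            (config.frame_count, *config.frame_shape), dtype=np.uint16
        )
        for i in range(config.frame_count):
            speckle = _integrated_speckle_frame(
                rng, mask, float(tau[i]), config.exposure_time
            )
            signal = speckle * (mean_dn * atten[i])
            if config.shot_noise:
                signal = rng.poisson(signal).astype(float)
            if config.read_noise_sd > 0:
                signal = signal + rng.normal(
                    0.0, config.read_noise_sd, signal.shape
                )
            np.clip(np.rint(signal), 0, config.full_scale, out=signal)
            frames[i] = signal.astype(np.uint16)

        stacks[wl] = SpeckleStack(
            frames=frames,
            timestamps=ts,
            wavelength=wl,
            exposure_time=config.exposure_time,
            bit_depth=config.bit_depth,
            metadata={"simulated": True, "seed": seed, "wavelength_nm": wl},
        )
        if truth is None:
            truth = GroundTruth(
                params=physiology,
                per_frame_tau_c=tau,
                per_frame_chromophores=chrom,
                timestamps=ts,
                seed=seed,
            )

    assert truth is not None
    return stacks, truth


def honeycomb_pattern(
    shape: Tuple[int, int], core_spacing: float, modulation_depth: float
) -> np.ndarray:
    """Static hexagonal fiber-bundle transmission pattern in [1 - depth, 1].

    Superposes three cosine gratings at 0/60/120 degrees, each with spatial
    frequency 1/core_spacing cycles per pixel, so the 2-D spectrum shows
    six-fold symmetric peaks at that radius.
    """
    if core_spacing < 3:
        raise ValueError("core_spacing must be >= 3 pixels")
    if not 0 < modulation_depth <= 1:
        raise ValueError("modulation_depth must lie in (0, 1]")
    r, c = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
    )
    f = 2 * np.pi / core_spacing
    angles = (0.0, np.pi / 3, 2 * np.pi / 3)
    h = sum(np.cos(f * (np.cos(a) * c + np.sin(a) * r)) for a in angles)
    h = (h + 3.0) / 6.0  # -> [0, 1]
    return 1.0 - modulation_depth * (1.0 - h)


def overlay_fiber_pattern(
    stack: SpeckleStack, core_spacing: float, modulation_depth: float
) -> SpeckleStack:
    """Multiply every frame by the same honeycomb transmission pattern.

    The pattern is frame-invariant (the bundle does not move), so its
    contribution has zero temporal variance per pixel.
    """
    pattern = honeycomb_pattern(stack.frame_shape, core_spacing, modulation_depth)
    frames = np.rint(stack.frames.astype(float) * pattern[None, :, :])
    frames = np.clip(frames, 0, 2**stack.bit_depth - 1).astype(stack.frames.dtype)
    meta = dict(stack.metadata)
    meta["fiber_core_spacing_px"] = core_spacing
    meta["fiber_modulation_depth"] = modulation_depth
    return SpeckleStack(
        frames=frames,
        timestamps=stack.timestamps.copy(),
        wavelength=stack.wavelength,
        exposure_time=stack.exposure_time,
        bit_depth=stack.bit_depth,
        metadata=meta,
    )
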