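import numpy as np
import pytest

from especkle.config import AcquisitionConfig, PhysiologyParams
from especkle.contrast import roi_contrast_series
from especkle.simulate import simulate_stack

ROI = (32, 96, 32, 96)


@pytest.fixture(scope="session")
def static_stack():
    """Noise-limited static speckle: exposure far below the correlation time."""
    acq = AcquisitionConfig(
        exposure_time=5e-4, nominal_frame_rate=20, wavelengths=(660,),
        frame_count=2, frame_shape=(128, 128),
    )
    phys = PhysiologyParams(
        cardiac_modulation_depth=0, respiratory_modulation_depth=0,
        baseline_correlation_time=1.0,
    )
    stacks, truth = simulate_stack(acq, phys, seed=11)
    return stacks[660], truth


@pytest.fixture(scope="session")
def occlusion_recording():
    """Dual-wavelength 25 s flow / 25 s occlusion / 15 s release protocol."""
    acq = AcquisitionConfig(
        exposure_time=2e-2, nominal_frame_rate=1.6, wavelengths=(660, 830),
        frame_count=int(1.6 * 65),
    )
    phys = PhysiologyParams(
        heart_rate=180, respiratory_rate=30,
        cardiac_modulation_depth=0.3, respiratory_modulation_depth=0.2,
        occlusion_window=(25.0, 50.0), occlusion_mode="arteriovenous",
    )
    stacks, truth = simulate_stack(acq, phys, seed=0)
    return stacks, truth


@pytest.fixture(scope="session")
def occlusion_series(occlusion_recording):
    stacks, truth = occlusion_recording
    return roi_contrast_series(stacks[660], ROI, 7)
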