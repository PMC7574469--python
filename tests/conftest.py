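import numpy as np
import pytest

from visiomod import isoi_fourier, stimulus, synthetic


@pytest.fixture(scope="session")
def isoi_protocol():
    """Still-fast grating at widefield timing, shortened to 4 cycles."""
    return stimulus.build_grating_protocol(0, 50, 6.0, 2.0, n_cycles=4, frame_rate_hz=30.0)


@pytest.fixture(scope="session")
def twop_protocol():
    """Slow-fast grating at two-photon timing: 50+50 frames, 21 cycles."""
    return stimulus.build_grating_protocol(
        10, 50, 50, 50, n_cycles=21, frame_period_s=0.26727, timing="frames"
    )


@pytest.fixture(scope="session")
def scene():
    return synthetic.make_cortex_scene()


@pytest.fixture(scope="session")
def noiseless_bar_maps(scene):
    """Fourier maps from noiseless elevation/azimuth bar sweeps (binned)."""
    maps = {}
    for axis in ("horizontal", "vertical"):
        stack = synthetic.simulate_bar_retinotopy(
            scene, axis, shot_sd=0, pink_amplitude=0, quantize=False, seed=0
        )
        f_bar = stack.frame_rate_hz / stack.meta["sweep_frames"]
        maps[axis] = isoi_fourier.fourier_maps(isoi_fourier.bin_stack(stack), f_bar)
    return maps


def circular_corr(a, b):
    """Circular correlation coefficient between two angle arrays."""
    a = np.asarray(a) - np.angle(np.exp(1j * np.asarray(a)).mean())
    b = np.asarray(b) - np.angle(np.exp(1j * np.asarray(b)).mean())
    num = np.sum(np.sin(a) * np.sin(b))
    den = np.sqrt(np.sum(np.sin(a) ** 2) * np.sum(np.sin(b) ** 2))
    return num / den
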