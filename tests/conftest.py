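import numpy as np
import pytest

import flapflow as ff


@pytest.fixture(scope="session")
def geometry():
    """Desk-scale elliptical flap geometry (128 x 256, midline at col 128)."""
    return ff.default_geometry()


@pytest.fixture(scope="session")
def zones(geometry):
    return ff.partition_zones(geometry)


@pytest.fixture(scope="session")
def noiseless(geometry):
    """Trimmed noiseless simulation + ground truth for each pattern preset."""
    out = {}
    for preset in (1, 2, 3):
        stack, truth = ff.simulate_flap_video(geometry, preset=preset, noise_sd=0.0, seed=0)
        out[preset] = (ff.trim_to_duration(stack), truth)
    return out


def random_curve(rng: np.random.Generator, n: int = 80, rate: float = 4.0) -> ff.PerfusionCurve:
    """A random bolus-like noisy curve that always has a well-defined rise."""
    times = np.arange(n) / rate
    b = rng.uniform(0, 30)
    a = rng.uniform(20, 150)
    t0 = rng.uniform(1.0, 4.0)
    tp = rng.uniform(2.0, 8.0)
    alpha = rng.uniform(1.0, 4.0)
    vals = ff.gamma_variate(times, b, a, t0, tp, alpha) + rng.normal(0, 1.0, n)
    return ff.PerfusionCurve(times=times, values=vals)
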