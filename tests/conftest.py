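import pytest

from her2calib.synthetic import SimConfig, generate_calibrator_image, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default simulated survey at seed 0: cores, labs, scores, ish."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def noisefree_study():
    """Survey with reader noise switched off (the deterministic mechanism)."""
    cfg = SimConfig(seed=0, reader_noise_manual=0.0, reader_noise_ia=0.0)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def calibrator_slide():
    """One noise-free calibrator image at true LOD 60,000 with ground truth."""
    img, truth = generate_calibrator_image(60e3, seed=5)
    return img, truth
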