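import numpy as np
import pytest

from cardioratio import synthetic_heart as sh
from cardioratio.ratio_imaging import RatioTrace


@pytest.fixture(scope="session")
def control_config():
    return sh.scenario_preset("control", seed=42)


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, background-free render of a beating control heart."""
    cfg = sh.scenario_preset(
        "control", shot_noise=False, background_level=0.0, seed=0
    )
    movie, gt = sh.render_dual_channel_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def noisy_movie():
    """Default camera model (Poisson + read noise), pixel shift (1, 4)."""
    cfg = sh.scenario_preset("control", channel_pixel_shift=(1, 4), seed=7)
    movie, gt = sh.render_dual_channel_movie(cfg)
    return cfg, movie, gt


def noisy_ratio_trace(gt, chamber, seed, noise_fraction=0.1):
    """Forward-model ratio trace plus Gaussian noise scaled to CaT amplitude."""
    clean = gt.true_ratio_trace[chamber]
    amp = float(clean.max() - clean.min())
    rng = np.random.default_rng(seed)
    return RatioTrace(
        values=clean + noise_fraction * amp * rng.standard_normal(clean.shape),
        time=gt.time,
        roi_label=chamber,
    )
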