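import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import yellott as y


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def aoslo_cfg():
    """Rendering config on the 8-bit-like 0-255 intensity scale."""
    return y.SynthConfig(
        scale_um_per_px=1.0, noise_sd=2.0, background=20.0, amplitude=150.0
    )


@pytest.fixture(scope="session")
def jittered_roi(aoslo_cfg):
    """A realistic 128x128 mosaic ROI: ICD 8 um, 5% jitter, mild noise."""
    truth = y.generate_hex_mosaic(8.0, 0.05, 128.0, seed=7)
    return y.render_mosaic_image(truth, aoslo_cfg), truth
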