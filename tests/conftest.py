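import numpy as np
import pytest

import facemetry as fm


@pytest.fixture(scope="session")
def template():
    """Shared low-resolution template: (mesh, landmarks, region labels)."""
    return fm.make_template(16, seed=1)


@pytest.fixture(scope="session")
def model(template):
    mesh, _, _ = template
    return fm.make_morphable_model(mesh, 8, seed=2)


@pytest.fixture(scope="session")
def clean_pair(model):
    """Scan/reconstruction pair with no deformation, noise or misalignment."""
    gt = fm.PairGroundTruth(
        region_amplitudes={}, noise_sd=0.0, seed=3, coeff_sigma=10.0
    )
    return fm.make_scan_pair(model, gt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
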