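import numpy as np
import pytest

import myomech as mm

# the two headline parameter sets of the identification campaign:
# (i) axial-only combined fit, (iii) all-six combined fit
PARAMS_AXIAL = mm.MaterialParameters(c1=0.24, c2=0.70, c3=1.56)
PARAMS_COMBINED = mm.MaterialParameters(c1=0.39, c2=0.53, c3=1.27)


def random_admissible_F(rng, scale=0.25, min_det=0.3):
    """A random deformation gradient with comfortably positive determinant."""
    while True:
        F = np.eye(3) + scale * rng.uniform(-1.0, 1.0, (3, 3))
        if np.linalg.det(F) > min_det:
            return F


def random_unit_vector(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


@pytest.fixture
def params_combined():
    return PARAMS_COMBINED


@pytest.fixture
def params_axial():
    return PARAMS_AXIAL


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def noiseless_campaign():
    """One noise-free replicate of each of the six protocols at the true set."""
    spec = mm.CampaignSpec(
        true_params=PARAMS_COMBINED,
        replicates={name: 1 for name in mm.DEFAULT_REPLICATES},
        noise_sd_frac=0.0,
        specimen_scale_sd=0.0,
        seed=0,
    )
    return mm.generate_campaign(spec)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_campaign):
    """Six-protocol identification on noise-free curves from p0 = (1, 1, 1)."""
    return mm.fit_parameters(noiseless_campaign, mm.FitConfig(p0=(1.0, 1.0, 1.0)))
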