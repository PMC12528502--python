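import numpy as np
import pytest

from orthosyn.losses import FeatureExtractorSpec
from orthosyn.network import ModelConfig
from orthosyn.phantom import PhantomSpec, make_cohort
from orthosyn.pipeline import PrepSettings, prepare_fraction


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale phantom grid: 32x32x16 voxels at 8 mm (256x256x128 mm FOV)."""
    return PhantomSpec(grid_shape=(32, 32, 16), spacing_mm=(8.0, 8.0, 8.0), n_fractions=2)


@pytest.fixture(scope="session")
def desk_cohort(desk_spec):
    return make_cohort(desk_spec, 4, (0.5, 0.25, 0.25), seed=7)


@pytest.fixture(scope="session")
def desk_model_cfg():
    return ModelConfig(variant="fusion_skip_res", in_shape_3d=(32, 32, 16),
                       in_raster_2d=(32, 32), base_channels=8)


@pytest.fixture(scope="session")
def feat_spec():
    return FeatureExtractorSpec()


@pytest.fixture(scope="session")
def desk_sample(desk_cohort):
    """One prepared (DRRs, pCT) -> CBCT training sample, no augmentation."""
    return prepare_fraction(desk_cohort.cases[0], 0, PrepSettings())


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of scalar f at array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
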