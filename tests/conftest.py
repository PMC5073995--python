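import numpy as np
import pytest

from voxelsvm import SubjectMatrix, SyntheticConfig, VolumeGeometry, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_geometry():
    return VolumeGeometry.default((4, 4, 4), 2.0)


def make_matrix(values, coords=None, labels=None, ids=None, geometry=None):
    """Build a SubjectMatrix with defaulted coords/labels/ids."""
    values = np.asarray(values, dtype=float)
    n_sub, n_vox = values.shape
    if coords is None:
        coords = np.column_stack(
            [np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)]
        )
    if labels is None:
        labels = np.array(
            ["positive"] * (n_sub // 2) + ["control"] * (n_sub - n_sub // 2)
        )
    if ids is None:
        ids = np.array([f"s{i}" for i in range(n_sub)])
    return SubjectMatrix(values, coords, labels, ids, geometry)


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with a strong planted effect, shared across tests."""
    cfg = SyntheticConfig(
        shape=(24, 24, 20),
        n_pos=10,
        n_ctrl=10,
        n_effect_clusters=2,
        cluster_radius_vox=2,
        effect_size=0.4,
        noise_sigma=40.0,
        smooth_fwhm_vox=3.0,
        seed=7,
    )
    return generate_cohort(cfg)
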