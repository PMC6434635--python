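import numpy as np
import pytest

import dticlass as dc


@pytest.fixture(scope="session")
def gtab():
    return dc.default_gradient_table()


@pytest.fixture(scope="session")
def straight_tube_phantom(gtab):
    """Noiseless straight-tube phantom along x with radially peaked FA."""
    spec = dc.PhantomSpec(
        shape=(30, 12, 12), voxel_size=(2.0, 2.0, 2.0),
        tubes=[dc.Tube(start=(0, 12, 12), direction=(1, 0, 0), length=60,
                       radius=5.0, anisotropy_falloff=0.6)],
        seed=11,
    )
    dwi, tensors, labels = dc.gen_dwi_phantom(spec, gtab)
    return spec, dwi, tensors, labels


@pytest.fixture(scope="session")
def straight_tube_fa(straight_tube_phantom):
    _, dwi, _, _ = straight_tube_phantom
    return dc.compute_fa(dc.fit_tensor(dwi))


@pytest.fixture(scope="session")
def curved_tube_phantom(gtab):
    """Quarter-arc tube in the z mid-plane."""
    spec = dc.PhantomSpec(
        shape=(26, 26, 9), voxel_size=(2.0, 2.0, 2.0),
        tubes=[dc.Tube(kind="curved", center=(4, 4, 9), u_axis=(1, 0, 0),
                       v_axis=(0, 1, 0), arc_radius=32,
                       angle_range=(0.0, np.pi / 2), radius=5.0)],
        seed=13,
    )
    dwi, tensors, labels = dc.gen_dwi_phantom(spec, gtab)
    return spec, dwi, tensors, labels


@pytest.fixture()
def uniform_field():
    """Synthetic FA/direction field: constant direction along x."""
    shape = (30, 9, 9)
    fa = np.full(shape, 0.8)
    dirs = np.zeros(shape + (3,))
    dirs[..., 0] = 1.0
    return dc.FAVolume(fa=fa, directions=dirs,
                       mask=np.ones(shape, bool), affine=np.eye(4))


@pytest.fixture(scope="session")
def null_cohort():
    return dc.gen_feature_cohort(dc.CohortSpec(effect=0.0, seed=100))


@pytest.fixture(scope="session")
def effect_cohort():
    return dc.gen_feature_cohort(dc.CohortSpec(effect=2.0, seed=0))
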