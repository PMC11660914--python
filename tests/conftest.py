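import numpy as np
import pytest

from glioloc.imaging import ImageGrid, LabelAtlas, LesionMask
from glioloc.synthetic import fixtures_spec, generate_cohort, generate_template


@pytest.fixture(scope="session")
def grid10():
    """Tiny 10^3 grid at 1 mm isotropic, centred on world x=0."""
    affine = np.eye(4)
    affine[:3, 3] = -4.5
    return ImageGrid(dims=(10, 10, 10), affine=affine)


@pytest.fixture(scope="session")
def grid2mm():
    """11^3 grid at 2 mm isotropic (odd width: exact mid-sagittal voxel plane)."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -10.0
    return ImageGrid(dims=(11, 11, 11), affine=affine)


def make_mask(grid, coords, compartment="core", subject_id="sub-x"):
    values = np.zeros(grid.dims, dtype=np.uint8)
    for c in coords:
        values[tuple(c)] = 1
    return LesionMask(grid=grid, values=values, compartment=compartment, subject_id=subject_id)


@pytest.fixture(scope="session")
def template24():
    return generate_template((24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def micro_cohort():
    """The 5-subject fixtures preset used across integration tests."""
    return generate_cohort(fixtures_spec(seed=7))


@pytest.fixture(scope="session")
def two_lobe_atlas(grid10):
    """Toy lobe atlas: label 1 fills x<5, label 2 fills x>=5."""
    labels = np.zeros(grid10.dims, dtype=np.int32)
    labels[:5] = 1
    labels[5:] = 2
    import pandas as pd

    table = pd.DataFrame(
        {
            "label_id": [1, 2],
            "region_name": ["alpha", "beta"],
            "tissue_class": ["lobe", "lobe"],
        }
    )
    return LabelAtlas(grid=grid10, labels=labels, table=table, name="toy_lobes")
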