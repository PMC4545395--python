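import numpy as np
import pytest

from cardiofuse.types import CohortSpec, GridGeometry, SubgroupTruth


@pytest.fixture
def tiny_spec() -> CohortSpec:
    """Small two-subgroup cohort on a reduced grid, fast enough for unit tests."""
    return CohortSpec(
        n_per_subgroup={"CTRL": 2, "HF-I": 2},
        subgroup_truth={
            "CTRL": SubgroupTruth(lvef_mean=0.62, lvef_concentration=90.0, edv_ml=110.0),
            "HF-I": SubgroupTruth(lvef_mean=0.28, lvef_concentration=45.0, edv_ml=150.0),
        },
        geometry=GridGeometry(grid_size=80, pixel_spacing_mm=1.25,
                              slice_thickness_mm=8.0, n_slices=6),
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
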