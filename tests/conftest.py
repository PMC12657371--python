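import numpy as np
import pytest

from glymphkit.dti_alps import fit_tensors
from glymphkit.synthetic import (
    CohortSpec,
    alps_phantom_spec,
    make_cohort,
    make_dwi_phantom,
    make_pvs_phantom,
    standard_pvs_phantom_spec,
)


@pytest.fixture(scope="session")
def fiber_phantom():
    """Noiseless ALPS fiber phantom: (spec, dwi, ground-truth field)."""
    spec = alps_phantom_spec(grid_shape=(16, 16, 16))
    dwi, gt = make_dwi_phantom(spec)
    return spec, dwi, gt


@pytest.fixture(scope="session")
def fitted_fiber_field(fiber_phantom):
    _, dwi, _ = fiber_phantom
    return fit_tensors(dwi)


@pytest.fixture(scope="session")
def noiseless_pvs_phantom():
    """Standard tube phantom without noise: (spec, t1w, t2w, atlas, gt mask)."""
    spec = standard_pvs_phantom_spec(noise_fraction=0.0)
    t1w, t2w, atlas, gt = make_pvs_phantom(spec)
    return spec, t1w, t2w, atlas, gt


@pytest.fixture(scope="session")
def default_cohort():
    df, truth = make_cohort(CohortSpec(seed=11))
    return df, truth
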