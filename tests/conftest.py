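import numpy as np
import pytest

from fociscreen.imaging import FociDetectionConfig
from fociscreen.synthgen import (
    CohortParams,
    generate_cohort,
    generate_image_truth,
    generate_zstack,
)


def small_cohort_params(**kwargs) -> CohortParams:
    """A fast cohort: fewer individuals and cells, no planted outliers."""
    defaults = dict(
        n_individuals={"HI": 10, "RC": 15},
        outlier_fraction={"HI": 0.0, "RC": 0.0},
        cells_per_individual=400,
        seed=42,
    )
    defaults.update(kwargs)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    params = small_cohort_params()
    records, truth = generate_cohort(params)
    return params, records, truth


@pytest.fixture(scope="session")
def default_config():
    return FociDetectionConfig()


@pytest.fixture(scope="session")
def small_field():
    """One rendered field with 20 nuclei, Poisson(2) planted foci."""
    truth = generate_image_truth(n_nuclei=20, mean_foci=2.0, seed=7)
    stack, table = generate_zstack(truth)
    return truth, stack, table


def make_disk_image(centers, radii, shape=(256, 256), intensity=3000.0,
                    background=200.0, noise_sd=5.0, seed=0):
    """Plain DAPI-like test image of hard-edged disks."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r in zip(centers, radii):
        img[np.hypot(yy - cy, xx - cx) <= r] = background + intensity
    img = img + rng.normal(0, noise_sd, shape)
    return np.clip(img, 0, 65535).astype(np.uint16)
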