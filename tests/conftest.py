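import numpy as np
import pytest

from radiotex.io_preprocess import RoiImage, normalize_roi
from radiotex.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_worked_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    """The tiny hand-checkable arrays shared across suites."""
    return generate_worked_fixtures()


def make_roi(seed: int = 0, size: int = 32, mask: str = "full") -> RoiImage:
    """A random normalized ROI for property tests."""
    rng = np.random.default_rng(seed)
    pixels = rng.uniform(0.0, 1.0, size=(size, size))
    if mask == "full":
        m = np.ones((size, size), dtype=bool)
    else:
        yy, xx = np.mgrid[:size, :size]
        m = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 < (size / 2.5) ** 2
    return RoiImage(pixels=pixels, mask=m, subject_id=f"rand{seed}")


@pytest.fixture
def random_roi():
    return make_roi


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 8+8 cohort with texture-separated arms."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from radiotex.features import extract_table

    return extract_table(normalize_roi(r) for r in small_cohort.rois())
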