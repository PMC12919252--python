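import math

import pytest

from podovat.stereology import SectionSpec
from podovat.synthetic import SyntheticCohortSpec, generate_slide_fixture, simulate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return SectionSpec()


@pytest.fixture(scope="session")
def sphere_spec():
    """Section spec matching the simulated spherical nuclei (k = pi/4)."""
    return SectionSpec(thickness_T=4.5, shape_k=math.pi / 4)


@pytest.fixture(scope="session")
def slide_fixture(tmp_path_factory):
    """Medium slide annotation fixture plus its ground truth."""
    path = tmp_path_factory.mktemp("slides") / "subject.geojson"
    truth = generate_slide_fixture(
        path,
        n_glomeruli=120,
        density_per_um3=210e-6,
        nucleus_D=7.0,
        thickness_T=4.5,
        sclerotic_fraction=0.05,
        pixel_size=0.5,
        seed=11,
    )
    return path, truth


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SyntheticCohortSpec(seed=7))
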