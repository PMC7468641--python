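import pytest

from painsgrid import SimConfig, build_default_atlas, score_series, simulate_cohort
from painsgrid.io import meta_to_frame, painmaps_from_frame, scales_from_frame
from painsgrid.synthetic import make_fixture


@pytest.fixture(scope="session")
def atlas():
    return build_default_atlas()


@pytest.fixture(scope="session")
def tiny_frames(atlas):
    return make_fixture("tiny", atlas)


@pytest.fixture(scope="session")
def tiny_painmaps(atlas, tiny_frames):
    return painmaps_from_frame(tiny_frames["painmaps"], atlas)


@pytest.fixture(scope="session")
def default_cohort(atlas):
    return simulate_cohort(SimConfig(seed=11), atlas)


@pytest.fixture(scope="session")
def default_series(atlas, default_cohort):
    return score_series(default_cohort.painmaps, default_cohort.scales,
                        atlas, "head_neck")
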