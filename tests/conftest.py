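import numpy as np
import pytest

from npcmorph.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study structure."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def reduced_spec(**overrides) -> CohortSpec:
    """A one-region, no-questionnaire spec for fast simulation loops."""
    defaults = dict(
        regions=("precuneus",),
        metric_baselines={
            ("precuneus", "thickness"): (2.5, 0.15),
            ("precuneus", "area"): (3600.0, 360.0),
        },
        region_effects={},
        global_volumes={"TotalGrayVol": (7e5, 5.5e4)},
        score_ranges={},
        severity_loadings={},
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
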