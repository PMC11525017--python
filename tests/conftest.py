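import pytest

from mmrquant import cohort, scoring


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized default-parameter cohort shared by statistical tests."""
    cfg = cohort.GeneratorConfig(n_cases=1500, seed=1)
    cells, truth = cohort.generate_cohort(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    _, cells, _ = default_cohort
    profiles, report = scoring.score_cohort(cells)
    return profiles, report
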