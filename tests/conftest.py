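import pytest

from promopanel.matrix import cpm, filter_inactive, qc_libraries
from promopanel.screen import run_screen
from promopanel.simulate import (
    CohortConfig,
    IHCSimConfig,
    simulate_cohort,
    simulate_ihc,
)

# One fixed cohort seed shared by all regression fixtures.
FIXTURE_SEED = 20160929

CONTRAST = ("non-lepidic AD", "PDSCC")


def _screen(m, samples):
    m2 = qc_libraries(m)
    retained = filter_inactive(cpm(m2), samples)
    return run_screen(m2.subset_regions(retained), samples, *CONTRAST)


@pytest.fixture(scope="session")
def discovery_cohort():
    """Default study-sized cohort: 97 samples, planted DE and separators."""
    return simulate_cohort(CohortConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def discovery_screen(discovery_cohort):
    m, samples, _ = discovery_cohort
    return _screen(m, samples)


@pytest.fixture(scope="session")
def separator_cohort():
    """Cohort with 10 planted separators and no other differential signal."""
    cfg = CohortConfig(
        n_regions=2000, n_de=0, n_separators=10, sep_log2_margin=2.0, seed=FIXTURE_SEED
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def separator_screen(separator_cohort):
    m, samples, _ = separator_cohort
    return _screen(m, samples)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted structure at all (false-discovery control)."""
    cfg = CohortConfig(n_regions=2000, n_de=0, n_separators=0, seed=FIXTURE_SEED)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_screen(null_cohort):
    m, samples, _ = null_cohort
    return _screen(m, samples)


@pytest.fixture(scope="session")
def ihc_scores(discovery_cohort):
    _, samples, _ = discovery_cohort
    cfg = IHCSimConfig(seed=FIXTURE_SEED + 1)
    return simulate_ihc(cfg, samples), cfg.markers, samples
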