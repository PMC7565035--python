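import pytest

from natscreen import cohort_sim


@pytest.fixture(scope="session")
def strong_cohort():
    """One cohort with every planted-signal class at strong defaults."""
    return cohort_sim.simulate_cohort(cohort_sim.strong_config(11))


@pytest.fixture(scope="session")
def null_cohort():
    """One cohort with no planted signals."""
    return cohort_sim.simulate_cohort(cohort_sim.null_config(7))


@pytest.fixture(scope="session")
def strong_cohort_dir(strong_cohort, tmp_path_factory):
    directory = tmp_path_factory.mktemp("strong_cohort")
    cohort_sim.write_cohort(strong_cohort, directory)
    return directory
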