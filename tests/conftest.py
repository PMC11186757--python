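import pytest

from pbudget import assemble_budgets, default_config, generate_measurements, truth


@pytest.fixture(scope="session")
def site_config():
    return default_config()


@pytest.fixture(scope="session")
def cv0_config(site_config):
    """The calibrated site with all between-plot and record noise removed."""
    return site_config.with_cv_scale(0.0)


@pytest.fixture(scope="session")
def cv0_tables(cv0_config):
    return generate_measurements(cv0_config, seed=11)


@pytest.fixture(scope="session")
def cv0_budgets(cv0_tables):
    return assemble_budgets(cv0_tables)


@pytest.fixture(scope="session")
def ambient_truth(site_config):
    return truth(site_config)


@pytest.fixture(scope="session")
def small_config(site_config):
    """Reduced design (fewer years and sub-replicates) for fast end-to-end
    runs where the full calendar adds nothing."""
    return site_config.model_copy(
        update={
            "years": [2013, 2014, 2015],
            "n_litter_traps": 2,
            "n_soil_subplots": 2,
        }
    )
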