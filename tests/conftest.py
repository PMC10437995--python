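import pandas as pd
import pytest

import nutricea as nc


@pytest.fixture(scope="session")
def printed_effect() -> nc.EffectEstimate:
    """The published incremental effect: 16.11 (95% CI 11.72 to 20.50)."""
    return nc.EffectEstimate.from_interval(16.11, 11.72, 20.50)


@pytest.fixture(scope="session")
def base_costs() -> nc.CostSummary:
    """Packaged ledger aggregated over 227 retained intervention children."""
    return nc.load_and_summarize(n_children=227)


@pytest.fixture(scope="session")
def small_config() -> nc.SyntheticConfig:
    """A reduced trial for fast mixed-model tests."""
    return nc.SyntheticConfig(
        n_intervention=60,
        n_control=60,
        n_villages=10,
        retained_intervention=50,
        retained_control=50,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_trial(small_config) -> pd.DataFrame:
    return nc.simulate_trial(small_config)


@pytest.fixture(scope="session")
def default_trial() -> pd.DataFrame:
    """One default-sized synthetic trial, after attrition."""
    return nc.simulate_trial(nc.SyntheticConfig(seed=7))


def noise_free_config(**overrides) -> nc.SyntheticConfig:
    base = dict(
        sd_village=0.0,
        sd_individual=0.0,
        sd_residual=0.0,
        seed=0,
        n_intervention=40,
        n_control=40,
        n_villages=8,
        retained_intervention=40,
        retained_control=40,
    )
    base.update(overrides)
    return nc.SyntheticConfig(**base)
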