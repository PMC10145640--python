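import dataclasses

import pytest

from hedgetick import fixtures, simulate as sim


def scaled_config(seed, scale=1.0, **overrides):
    """Study-like cohort with abundance scaled down for fast tests."""
    cfg = sim.study_config(seed=seed, **overrides)
    if scale != 1.0:
        cfg = dataclasses.replace(
            cfg, abundance_mean={k: v * scale for k, v in cfg.abundance_mean.items()})
    return cfg


@pytest.fixture(scope="session")
def daybin_counts():
    return fixtures.dropoff_daybins()


@pytest.fixture(scope="session")
def abundance_counts():
    return fixtures.allocate_cell_totals(fixtures.abundance_cells(), seed=None)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort at ~quarter scale, shared across tests."""
    ticks, hosts = sim.simulate_cohort(scaled_config(seed=1405, scale=0.25))
    return ticks, hosts
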