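import pytest

from asthmacea import default_parameters, make_life_table, run_cohort, run_psa


@pytest.fixture(scope="session")
def bundle():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def base_results(bundle, life_table):
    """Deterministic lifetime results for both arms at base-case values."""
    return {
        arm: run_cohort(bundle, arm, life_table) for arm in ("triple", "dual")
    }


@pytest.fixture(scope="session")
def psa_1000(bundle, life_table):
    """The full 1000-replicate probabilistic sensitivity analysis."""
    return run_psa(bundle, n_reps=1000, seed=2021, life_table=life_table)


@pytest.fixture(scope="session")
def psa_small(bundle, life_table):
    return run_psa(bundle, n_reps=40, seed=7, life_table=life_table)


@pytest.fixture()
def zero_mortality_life_table():
    """A life table with q = 0 at every age (isolates disease dynamics)."""
    from asthmacea.lifetable import LifeTable
    import numpy as np

    ages = np.arange(0, 101)
    return LifeTable(ages, np.zeros_like(ages, dtype=float))
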