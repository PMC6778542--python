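"""Shared fixtures.

Expensive simulated cohorts and fits are session-scoped so the full suite
stays well inside its time budget.
"""

import numpy as np
import pytest

from raclmap import (HierarchicalFactorModel, build_anatomical_spec,
                     build_one_factor_spec, default_population,
                     simulate_bp_table)


@pytest.fixture(scope="session")
def anatomical_cohort():
    """n=176 anatomical cohort at the default population parameters."""
    return simulate_bp_table(default_population("anatomical", seed=101))


@pytest.fixture(scope="session")
def functional_cohort():
    return simulate_bp_table(default_population("functional", seed=202))


@pytest.fixture(scope="session")
def anatomical_wide(anatomical_cohort):
    return anatomical_cohort.wide()


@pytest.fixture(scope="session")
def anatomical_fit(anatomical_wide):
    spec = build_anatomical_spec(mean_structure=True)
    model = HierarchicalFactorModel(spec, data=anatomical_wide)
    return model.fit(n_restarts=1, rng=5)


@pytest.fixture(scope="session")
def one_factor_fit(anatomical_wide):
    spec = build_one_factor_spec(build_anatomical_spec(mean_structure=True))
    model = HierarchicalFactorModel(spec, data=anatomical_wide)
    return model.fit(n_restarts=1, compute_se=False, rng=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
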