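import numpy as np
import pandas as pd
import pytest

import triowa
from triowa import SimulationConfig, OutcomeTruth
from triowa.impute import ImputedStack


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=2000, n_variants=24, block_size=4, ld_rho=0.5,
        seed=11,
        outcome_specs=[
            OutcomeTruth(name="y_cont", true_effect_exposure=0.2, theme="a"),
            OutcomeTruth(name="y_rare", family_truth="binary", base_rate=0.06,
                         true_effect_exposure=0.3, theme="a"),
            OutcomeTruth(name="y_common", family_truth="binary", base_rate=0.3,
                         link="log", true_effect_exposure=0.15, theme="b"),
            OutcomeTruth(name="y_cat", family_truth="categorical", k=3,
                         true_effect_exposure=0.3, theme="b"),
            OutcomeTruth(name="y_null", theme="b"),
        ],
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return triowa.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    return triowa.simulate_cohort(small_config, small_panel)


@pytest.fixture(scope="session")
def small_catalog():
    return pd.DataFrame({
        "name": ["y_cont", "y_rare", "y_common", "y_cat", "y_null"],
        "type": ["continuous", "binary", "binary", "categorical", "continuous"],
        "theme": ["a", "a", "b", "b", "b"],
    })


@pytest.fixture(scope="session")
def complete_stack(small_cohort):
    """Single-dataset stack from complete data (no missingness)."""
    return ImputedStack(datasets=[small_cohort.data], trace=pd.DataFrame())


def brute_force_bh(pvals, alpha=0.05):
    """Independent step-up implementation used as the FDR oracle."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha
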