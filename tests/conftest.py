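import numpy as np
import pytest

from episelect import synthetic_trials as syn


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def f3_params():
    """Small two-location plot trial: 27 epi lines (3 per category), 5 WT."""
    return syn.SimParams(
        wt_mean_by_env={"normalN": 5999.0, "lowN": 2335.0},
        line_var=150.0**2,
        block_var=80.0**2,
        resid_var=300.0**2,
        n_epi_lines=27,
        n_wt_lines=5,
        plants_or_plots_per_line_per_rep=1,
        n_reps_by_env={"normalN": 3, "lowN": 2},
        seed=42,
    )


@pytest.fixture
def f3_plots(f3_params):
    return syn.simulate_epiF3_multienv_trial(f3_params)


@pytest.fixture
def f3_categories(f3_params):
    return syn.default_category_assignment(f3_params)


@pytest.fixture
def f2_params():
    return syn.SimParams(
        wt_mean_by_env={"F2": 70.0},
        line_var=9.0,
        block_var=4.0,
        resid_var=100.0,
        epi_mixture=syn.EpiMixture(0.15, 0.05, 0.80, 12.0, 10.0),
        tiller_effect_logfc=0.15,
        n_epi_lines=30,
        plants_or_plots_per_line_per_rep=10,
        n_reps_by_env={"F2": 3},
        seed=7,
    )


@pytest.fixture
def f2_plants(f2_params):
    return syn.simulate_epiF2_trial(f2_params)
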