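"""Shared fixtures: calibrated parameters and cached scenario runs."""

import numpy as np
import pytest

from metaflex import (
    Meal,
    apply_insulin_resistance,
    healthy_parameters,
    scenario_tissues,
    simulate_scenario,
    steady_state,
    summarise,
)

CORE_SCENARIOS = ("healthy", "adipose", "liver", "muscle", "all")


@pytest.fixture(scope="session")
def params():
    """Registry defaults calibrated so unity is the fasting equilibrium."""
    return healthy_parameters()


@pytest.fixture(scope="session")
def meal():
    """The reference mixed meal: 550 kcal carbohydrate + 150 kcal fat."""
    return Meal(carb_kcal=550.0, fat_kcal=150.0)


@pytest.fixture(scope="session")
def scenario_runs(params, meal):
    """12 h postprandial trajectories and summaries for the core scenarios.

    Each run starts from the scenario's own fasting steady state, which is
    also the fasting reference for peaks and recovery.
    """
    runs = {}
    for name in CORE_SCENARIOS:
        traj = simulate_scenario(name, params, meal, t_end=12.0)
        runs[name] = (traj, summarise(traj, window=12.0))
    return runs


@pytest.fixture(scope="session")
def fasting_states(params):
    return {
        name: steady_state(params, apply_insulin_resistance(scenario_tissues(name)))
        for name in CORE_SCENARIOS
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
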