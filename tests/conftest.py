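import numpy as np
import pytest

from mmchoice import (
    AttributeSpec,
    EstimationSettings,
    TrueModel,
    add_validity_tasks,
    default_catalog,
    default_true_model,
    generate_design,
    simulate_choices,
    simulate_profiles,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def design36(catalog):
    """Optimized 36-task, 3-block design with validity tasks (seed 1)."""
    d = generate_design(catalog, n_tasks=36, n_blocks=3, seed=1, n_sweeps=6)
    return add_validity_tasks(d, repeat_position=3)


@pytest.fixture(scope="session")
def small_catalog():
    """Reduced 3-attribute catalog for estimation-heavy experiments."""
    return [
        AttributeSpec(
            "orr", "Response rate", "benefit", ("25%", "55%", "85%"),
            reference_index=0, numeric_values=(25.0, 55.0, 85.0),
        ),
        AttributeSpec(
            "os", "Survival", "benefit", ("6 months", "2 years"),
            reference_index=0, numeric_values=(6.0, 24.0),
        ),
        AttributeSpec(
            "crs", "CRS", "risk", ("high_risk", "no_risk"),
            reference_index=1, numeric_values=(85.0, 0.0),
        ),
    ]


@pytest.fixture(scope="session")
def small_design(small_catalog):
    return generate_design(small_catalog, n_tasks=8, n_blocks=1, seed=3, n_sweeps=10)


@pytest.fixture(scope="session")
def small_truth():
    """Known data-generating parameters on the reduced catalog."""
    return TrueModel(
        part_worths={"orr": {1: 0.5, 2: 1.0}, "os": {1: 0.7}, "crs": {0: -0.6}},
        sigma=0.5,
    )


@pytest.fixture(scope="session")
def sim_dataset(design36, catalog):
    """One moderate simulated dataset on the full catalog (296 respondents)."""
    truth = default_true_model(sigma=0.8, optout_rate=0.05)
    profiles = simulate_profiles(296, seed=2)
    return simulate_choices(design36, profiles, truth, seed=3), truth


@pytest.fixture(scope="session")
def fast_settings():
    return EstimationSettings(n_draws=100, seed=11)


def simulate_small(small_design, truth, n_respondents, seed):
    profiles = simulate_profiles(n_respondents, seed=seed)
    return simulate_choices(small_design, profiles, truth, seed=seed + 10_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
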