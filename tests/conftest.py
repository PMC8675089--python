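import numpy as np
import pytest

import guiltgame as gg


@pytest.fixture(scope="session")
def canonical_design():
    """One canonical 45-trial design (rejection sampling, fixed seed)."""
    return gg.generate_design(seed=11)


@pytest.fixture(scope="session")
def example_trial():
    """The worked-example trial: payoffs 780/650 (Cooperate), 220/910
    (Defect), outside option 500/300, belief 0.8."""
    return gg.TrialSpec(x_A=780, x_B=650, y_A=220, y_B=910,
                        z_A=500, z_B=300, tau=0.8)


@pytest.fixture(scope="session")
def small_cohort(canonical_design):
    """12 simulated participants with default study conditions."""
    cfg = gg.CohortConfig(n_per_sex=6, seed=3)
    records = gg.simulate_cohort(canonical_design, cfg)
    choices, covariates = gg.cohort_frames(records)
    return records, choices, covariates


def random_valid_trial(rng: np.random.Generator, tau: float = 0.8) -> gg.TrialSpec:
    """Draw one payoff-ordering-valid trial on the 10-yen grid."""
    grid = np.arange(100, 1001, 10)
    y_A, z_A, x_A = np.sort(rng.choice(grid, 3, replace=False))
    z_B, x_B, y_B = np.sort(rng.choice(grid, 3, replace=False))
    return gg.TrialSpec(int(x_A), int(x_B), int(y_A), int(y_B),
                        int(z_A), int(z_B), tau)
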