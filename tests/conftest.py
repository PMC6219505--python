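import numpy as np
import pytest

from oligoprog import survnet, synthetic


@pytest.fixture(scope="session")
def planted_cohort():
    """n=400 cohort, 5 strong planted effects among 50 binary features."""
    return synthetic.generate_cohort(synthetic.benchmark_cohort_config(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 well-conditioned cohort with 10 features, for optimisation
    and linear-equivalence checks."""
    cfg = synthetic.SimulationConfig(
        n_samples=300, alteration_freqs=np.full(10, 0.3),
        planted_effects=np.array([0.8, -0.6, 0.5, 0, 0, 0, 0, 0, 0.4, -0.3]),
        seed=1)
    return synthetic.generate_cohort(cfg)


@pytest.fixture
def mixed_outcomes():
    """Small hand-checkable censored outcome set."""
    return survnet.SurvivalOutcome(
        time=np.array([2.0, 5.0, 5.0, 8.0, 11.0, 12.0]),
        event=np.array([1, 1, 0, 1, 0, 1]))
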