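import numpy as np
import pytest

from ehrmtl.models import HyperParams, TrainConfig
from ehrmtl.rules import Clause, PhenotypeRule
from ehrmtl.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10,000 patients, 50 codes, 2 latent factors; factor 0 emits codes 0-9."""
    config = CohortConfig(
        n_patients=10_000,
        n_codes=50,
        latent_prevalences=(0.05, 0.1),
        emissions=(
            tuple((c, 0.6) for c in range(10)),
            tuple((c, 0.5) for c in range(10, 20)),
        ),
        background_rate=0.01,
        hidden_flag_rate=0.5,
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture
def pair_rule():
    """Cases carry codes 0 and 1 (no hidden-flag requirement, no noise)."""
    return PhenotypeRule(
        rule_id="pair",
        oracle_codes=(0, 1, 2),
        clauses=(Clause(frozenset({0, 1})),),
    )


@pytest.fixture
def toy_separable():
    """200 points, 10 features; label = x0 > 0 so a perfect classifier exists."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 10))
    y = (X[:, 0] > 0).astype(np.int8)
    X[:, 0] += 3 * y  # widen the margin
    return X[:160], y[:160], X[160:], y[160:]


@pytest.fixture
def toy_hp():
    return HyperParams(n_hidden_layers=1, hidden_size=16, learning_rate=1e-2)


@pytest.fixture
def toy_tc():
    return TrainConfig(max_epochs=30, batch_size=32, seed=0)
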