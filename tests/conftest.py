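import numpy as np
import pytest

from retest import FeatureTable, SyntheticSpec, generate_feature_table


@pytest.fixture
def small_table() -> FeatureTable:
    """3 subjects x 2 sessions x 2 features, hand-enumerable."""
    values = np.array(
        [
            [[1.0, 10.0], [1.1, 10.5]],
            [[2.0, 20.0], [2.1, 19.5]],
            [[3.0, 30.0], [2.9, 30.5]],
        ]
    )
    return FeatureTable(["s1", "s2", "s3"], ["fA", "fB"], values)


@pytest.fixture
def identical_sessions_table() -> FeatureTable:
    """Retest is an exact copy of the test session."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(8, 5))
    values = np.stack([x, x], axis=1)
    return FeatureTable(
        [f"s{i}" for i in range(8)], [f"f{r}" for r in range(5)], values
    )


def make_table(
    n_subjects=30,
    n_features=10,
    sigma_b=1.0,
    sigma_w=0.5,
    session_shift=0.0,
    seed=0,
    **kw,
):
    spec = SyntheticSpec(
        n_subjects=n_subjects,
        n_features=n_features,
        sigma_b=sigma_b,
        sigma_w=sigma_w,
        session_shift=session_shift,
        seed=seed,
        **kw,
    )
    table, truth = generate_feature_table(spec)
    return table, truth


@pytest.fixture
def table_factory():
    return make_table
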