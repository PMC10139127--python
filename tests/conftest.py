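import numpy as np
import pandas as pd
import pytest

from stavarsel import (
    StandardNestedCV,
    build_ratios,
    generate_worked_fixture,
)

# reduced inner-CV settings used throughout the suite so full pipeline
# runs stay fast; the protocol structure is unchanged
FAST_CV = dict(inner_folds=5, inner_repeats=2, n_lambda=25)


@pytest.fixture(scope="session")
def worked_cohort():
    expr, meta, truth = generate_worked_fixture()
    return expr, meta, truth


@pytest.fixture(scope="session")
def worked_ratios(worked_cohort):
    expr, meta, truth = worked_cohort
    ratios = build_ratios(expr)
    y = (meta["group"] == "B").astype(int).to_numpy()
    return ratios, y, truth


@pytest.fixture(scope="session")
def fitted_standard_cv(worked_ratios):
    ratios, y, _ = worked_ratios
    return StandardNestedCV(random_state=1, **FAST_CV).fit(ratios, y)


@pytest.fixture
def tiny_expr():
    """4 samples x 3 strictly positive features with known values."""
    return pd.DataFrame(
        [[10.0, 5.0, 2.0], [8.0, 4.0, 2.0], [6.0, 3.0, 1.5], [12.0, 6.0, 3.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
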