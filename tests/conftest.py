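import numpy as np
import pandas as pd
import pytest

from obesipath import cohort, elicitation, pipeline


@pytest.fixture(scope="session")
def design():
    return elicitation.default_design()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = cohort.CohortConfig(n_subjects=120, seed=3)
    subjects, truth = cohort.generate_cohort(cfg)
    return subjects, truth


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    subjects, _ = small_cohort
    scored, n_excluded = pipeline.score_subjects(subjects)
    assert n_excluded == 0
    return scored


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def linear_frame(rng):
    """Two independent predictors with known linear effects on y."""
    n = 400
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = 0.5 * x1 - 0.3 * x2 + rng.standard_normal(n)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})
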