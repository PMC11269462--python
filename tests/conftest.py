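import numpy as np
import pytest

from cuemeta import RegressionInput, StudyRecord, fixture_regression_input


@pytest.fixture(scope="session")
def heavy_input() -> RegressionInput:
    """The nine-medication cue-craving vs heavy-drinking dataset."""
    return fixture_regression_input("heavy_drinking")


@pytest.fixture(scope="session")
def abstinence_input() -> RegressionInput:
    return fixture_regression_input("abstinence")


@pytest.fixture()
def parallel_record() -> StudyRecord:
    return StudyRecord(
        study_id="s1", medication="drugA", paradigm="cue_reactivity",
        outcome="cue_craving", design="parallel",
        n_med=20, mean_med=8.0, sd_med=2.0,
        n_ctrl=20, mean_ctrl=10.0, sd_ctrl=2.0,
    )


def random_regression_instance(rng: np.random.Generator, n: int) -> RegressionInput:
    """A small random errors-in-both-variables instance for oracle checks."""
    x = rng.uniform(-1.0, 1.0, n)
    slope = rng.uniform(-2.0, 2.0)
    y = slope * x + rng.normal(0, 0.3, n)
    sx = rng.uniform(0.05, 0.4, n)
    sy = rng.uniform(0.05, 0.4, n)
    return RegressionInput(x=x, y=y, sx=sx, sy=sy)
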