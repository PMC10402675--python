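import numpy as np
import pytest

from mlczones import (
    DEFAULT_PARAMETERS,
    BeamModelParameters,
    ControlPoint,
    MLCGeometry,
    make_validation_plan,
)


@pytest.fixture(scope="session")
def params() -> BeamModelParameters:
    """The default clinical beam-model parameter set."""
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def geometry() -> MLCGeometry:
    return MLCGeometry.millennium120()


@pytest.fixture(scope="session")
def validation_plan():
    return make_validation_plan()


@pytest.fixture
def closed_cp(geometry) -> ControlPoint:
    """All 60 pairs closed at x = 0, 30 x 30 cm^2 jaws."""
    n = geometry.n_pairs
    return ControlPoint(
        index=0,
        bank_a=np.zeros(n),
        bank_b=np.zeros(n),
        jaw_x_low=-15.0,
        jaw_x_high=15.0,
        jaw_y_low=-15.0,
        jaw_y_high=15.0,
        cumulative_weight=0.0,
    )


def cohort_table(n=10, seed=0):
    """Random but plausible per-plan GPF design (rows on the simplex)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.array([20, 1, 4, 40, 10, 0.5, 0.5]), size=n)
    cols = ["open", "calibration", "tip", "body", "paired", "exposed", "neglected"]
    df = pd.DataFrame(f, columns=cols)
    df.insert(0, "plan_id", [f"plan{i}" for i in range(n)])
    return df


def make_cp(
    geometry,
    bank_a,
    bank_b,
    jaws=(-15.0, 15.0, -15.0, 15.0),
    index=0,
    weight=0.0,
) -> ControlPoint:
    cp = ControlPoint(
        index=index,
        bank_a=np.asarray(bank_a, dtype=float),
        bank_b=np.asarray(bank_b, dtype=float),
        jaw_x_low=jaws[0],
        jaw_x_high=jaws[1],
        jaw_y_low=jaws[2],
        jaw_y_high=jaws[3],
        cumulative_weight=weight,
    )
    cp.validate()
    return cp
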