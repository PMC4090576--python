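import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssastream.models import MassAction, Model, Reaction, SystemState

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schlogl():
    from ssastream.models import builtin_model

    return builtin_model("schlogl")


@pytest.fixture(scope="session")
def neurospora_dark():
    from ssastream.models import builtin_model

    return builtin_model("neurospora", condition="dark")


@pytest.fixture()
def decay_model():
    """Single first-order decay A -> 0 with c = 3.5."""
    return Model(
        name="decay",
        species=("A",),
        reactions=(Reaction((("A", 1),), (), MassAction(3.5)),),
        initial_state=SystemState({"A": 5}),
    )


@pytest.fixture()
def inert_model():
    """No reactions: every trajectory is constant."""
    return Model(
        name="inert",
        species=("X",),
        reactions=(),
        initial_state=SystemState({"X": 7}),
    )


def savgol_lstsq_oracle(window: int, order: int, deriv: int) -> np.ndarray:
    """Independent SG coefficients by explicit least squares.

    Fit a degree-``order`` polynomial to the stencil positions
    ``-h..h`` and read off the value (or first derivative) at 0; the
    coefficient of sample ``j`` is obtained by fitting the unit vector.
    """
    h = window // 2
    x = np.arange(-h, h + 1, dtype=float)
    V = np.vander(x, order + 1, increasing=True)  # columns 1, x, x^2, ...
    coeffs = np.zeros(window)
    for j in range(window):
        e = np.zeros(window)
        e[j] = 1.0
        beta, *_ = np.linalg.lstsq(V, e, rcond=None)
        coeffs[j] = beta[deriv] * (1.0 if deriv == 0 else 1.0)
    if deriv == 1:
        pass  # beta[1] is already d/dx at 0
    return coeffs
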