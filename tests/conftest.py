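import numpy as np
import pytest

from tcellopt import default_factors, generate_ccd, Factor


@pytest.fixture(scope="session")
def factors6():
    return default_factors()


@pytest.fixture(scope="session")
def ccd6(factors6):
    return generate_ccd(factors6, n_center=8, alpha_mode="orthogonal")


@pytest.fixture
def simple_factor():
    return Factor("IL3", low=0.0, center=10.0, high=20.0)


def quad_vertex(model):
    """Analytic argmax of a strictly concave full-quadratic sqrt-scale model."""
    beta0, b, Q = model.quad_form()
    assert np.linalg.eigvalsh(Q).max() < 0, "vertex only defined for concave surfaces"
    return -0.5 * np.linalg.solve(Q, b)
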