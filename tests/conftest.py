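import numpy as np
import pytest

from classed.fixtures import ToySpec, make_recovery_case, make_toy_network
from classed.model import ParameterSet


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def cascade5():
    return make_toy_network(ToySpec("cascade", 5, seed=1))


@pytest.fixture(scope="session")
def demo():
    return make_toy_network(ToySpec("crosstalk_demo"))


@pytest.fixture(scope="session")
def recovery_case():
    """(pruned model, noise-free records, withheld AND edge) — shared because
    record labelling runs a batch of ODE simulations."""
    return make_recovery_case(seed=0)


def fixed_point_steady_state(model, params, perturbations=(), iters=400, damp=0.5):
    """Damped fixed-point iteration y <- Ymax * F(y): the ODE-free oracle."""
    from classed.lde_engine import build_rhs

    sys_ = build_rhs(model, params, perturbations)
    y = sys_.y_init.copy()
    for _ in range(iters):
        y_new = sys_.ymax * sys_.production(y)
        y_new[sys_.clamped] = sys_.y_init[sys_.clamped]
        y = damp * y + (1.0 - damp) * y_new
    return y
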