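import numpy as np
import pytest

from cvc_cea.parameters import ProbabilityParam, StrategyParams, default_parameters


@pytest.fixture()
def defaults():
    return default_parameters()


@pytest.fixture()
def ug(defaults):
    return defaults[0]


@pytest.fixture()
def lm(defaults):
    return defaults[1]


@pytest.fixture()
def budget_ctx(defaults):
    return defaults[2]


def point(name: str, value: float) -> ProbabilityParam:
    """Degenerate probability parameter at a single value."""
    return ProbabilityParam(name, value, value, value)


def make_params(
    f1: float, f2: float, c1: float, c2: float, c3: float,
    arterial: float | None = None, strategy: str = "X",
) -> StrategyParams:
    """Strategy parameter set with point probabilities and default costs."""
    if arterial is None:
        arterial = min(c1, 0.99)
    cost_map = default_parameters()[0].cost_map
    return StrategyParams(
        strategy=strategy,
        f1=point("f1", f1),
        f2=point("f2", f2),
        c1=point("c1", c1),
        c2=point("c2", c2),
        c3=point("c3", c3),
        arterial=point("arterial", arterial),
        cost_map=cost_map,
    )


def random_params(rng: np.random.Generator, strategy: str = "X") -> StrategyParams:
    """A random valid parameter set for property tests."""
    f1, f2 = rng.uniform(0.01, 0.95, 2)
    c1, c2, c3 = rng.uniform(0.005, 0.6, 3)
    arterial = rng.uniform(0.0, c1)
    return make_params(f1, f2, c1, c2, c3, arterial, strategy)
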