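"""Shared fixtures: small fields and session-scoped Turing simulations."""

import numpy as np
import pytest

from symscan.fields import IntensityField
from symscan.turing import RDParams, simulate

STRIPE_SEEDS = (101, 102, 103)
ADVECTION_RATES = (0.0, 3.0, 6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_field(rng):
    """A rough strictly positive field for algebraic identities."""
    return IntensityField(rng.uniform(1.0, 5.0, (16, 12)))


@pytest.fixture()
def smooth_field(rng):
    """A smooth positive field where interpolation error is small."""
    x = np.linspace(-1, 1, 65)
    X, Y = np.meshgrid(x, x)
    return IntensityField(2.0 + np.sin(3 * X) * np.cos(2 * Y) + 0.3 * np.cos(5 * X * Y))


@pytest.fixture(scope="session")
def stripe_states():
    """c=0 stripe-regime simulations to t=100 for three seeds."""
    return {s: simulate(RDParams(T=100.0, c=0.0, seed=s)) for s in STRIPE_SEEDS}


@pytest.fixture(scope="session")
def advection_states(stripe_states):
    """States at increasing advection rate, common seed."""
    out = {0.0: stripe_states[STRIPE_SEEDS[0]]}
    for c in ADVECTION_RATES[1:]:
        out[c] = simulate(RDParams(T=100.0, c=c, seed=STRIPE_SEEDS[0]))
    return out
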