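import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import moodkit as mk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return mk.CircuitParameters()


@pytest.fixture(scope="session")
def midpoint():
    return mk.DecisionVector.midpoint()


@pytest.fixture(scope="session")
def midpoint_trajectory(midpoint):
    """One default stimulus-response simulation, shared across tests."""
    return mk.simulate(midpoint)


def make_tiny_pareto(n=8, seed=0):
    """Small synthetic Pareto approximation with in-bounds circuit thetas.

    Objective values lie on a convex trade-off; thetas are random points in
    the wet-lab box. Useful wherever an archive's *structure* matters but
    its optimality does not (persistence, clustering plumbing, CLI).
    """
    from moodkit.model import LOWER, UPPER
    from moodkit.optimize import Individual, ParetoApproximation

    rng = np.random.default_rng(seed)
    j1 = np.sort(1.0 + 99.0 * rng.random(n))
    j2 = 20.0 / j1  # strictly decreasing => mutually non-dominated
    thetas = LOWER + rng.random((n, 10)) * (UPPER - LOWER)
    inds = [
        Individual(theta=thetas[i], J=(float(j1[i]), float(j2[i])),
                   P=50.0, violation=0.0, pertinent=True, feasible=True)
        for i in range(n)
    ]
    return ParetoApproximation(individuals=inds, seed=seed, evaluations=n)


@pytest.fixture()
def tiny_pareto():
    return make_tiny_pareto()
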