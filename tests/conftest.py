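"""Shared fixtures: tiny symbolic models and scripted objectives.

The scripted objectives implement the same evaluate() contract as the
NLL objective but are analytic (decomposable quadratics), which makes
optimizer behaviour checkable against closed forms and lets failure
scenarios be injected deterministically.
"""

from __future__ import annotations

import numpy as np
import pytest

import batchode as b
from batchode.objective import ObjectiveValue


@pytest.fixture(scope="session")
def decay_model():
    """One-state linear decay: dx/dt = -k x, x(0)=1, y=x."""
    return b.ODEModel.from_symbolic(
        states={"x": "1"}, parameters=["k"], inputs=[],
        rates={"x": "-k*x"}, observables={"y": "x"})


@pytest.fixture(scope="session")
def cascade_2layer():
    return b.build_cascade_model(b.CascadeSpec(n_layers=2))


@pytest.fixture(scope="session")
def small_problem():
    """12-condition reduced-scale time-course problem with ground truth."""
    return b.generate_dataset(b.get_preset("fujita_like", n_conditions=12), seed=42)


@pytest.fixture(scope="session")
def small_objective(small_problem):
    return b.NLLObjective(small_problem)


@pytest.fixture(scope="session")
def viability_problem():
    """Small steady-state dose-response problem with responder labels."""
    return b.generate_viability_dataset(n_cell_lines=5, n_drugs=2, n_doses=4, seed=3)


class QuadraticObjective:
    """Decomposable quadratic J(theta) = sum_e 1/2 ||theta - c_e||^2.

    Analytic stand-in for the ODE objective: same evaluate() contract,
    closed-form value and gradient, which lets optimizer trajectories be
    verified exactly.
    """

    def __init__(self, centers: dict[str, np.ndarray]):
        self.centers = {k: np.asarray(v, dtype=float) for k, v in centers.items()}

    @property
    def condition_ids(self):
        return sorted(self.centers)

    def n_records(self, subset=None):
        ids = self.condition_ids if subset is None else list(subset)
        return len(ids)

    def evaluate(self, theta, subset=None, with_gradient=False):
        theta = np.asarray(theta, dtype=float)
        ids = self.condition_ids if subset is None else sorted(subset)
        J = 0.0
        per = {}
        grad = np.zeros_like(theta) if with_gradient else None
        for cid in ids:
            d = theta - self.centers[cid]
            per[cid] = 0.5 * float(d @ d)
            J += per[cid]
            if with_gradient:
                grad += d
        return ObjectiveValue(J, J, per, grad, "ok", len(ids))


class ScriptedFailureObjective(QuadraticObjective):
    """Quadratic objective whose evaluations fail on scripted call indices.

    ``fail_calls`` enumerates 1-based indices of *gradient* evaluations that
    return evaluation_failure (the call counter only counts gradient
    evaluations, mirroring where the optimizer loop detects failures).
    """

    def __init__(self, centers, fail_calls=()):
        super().__init__(centers)
        self.fail_calls = set(fail_calls)
        self.calls = 0

    def evaluate(self, theta, subset=None, with_gradient=False):
        if with_gradient:
            self.calls += 1
            if self.calls in self.fail_calls:
                return ObjectiveValue(np.nan, np.nan, {}, None, "evaluation_failure",
                                      len(subset or self.centers))
        return super().evaluate(theta, subset, with_gradient)


@pytest.fixture
def quadratic_objective():
    rng = np.random.default_rng(7)
    centers = {f"e{i}": rng.normal(0.0, 1.0, size=3) for i in range(6)}
    return QuadraticObjective(centers)


@pytest.fixture
def quadratic_bounds():
    return b.ParameterSpace(["p0", "p1", "p2"], lower=np.full(3, -5.0), upper=np.full(3, 3.0))
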