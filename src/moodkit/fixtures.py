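"""Seed-deterministic synthetic fixtures for testing the pipeline pieces.

Three generators, each exercising one stage with known ground truth:

* ``benchmark`` — the convex analytic bi-objective problem
  f1 = theta^2, f2 = (theta - 2)^2 on theta in [-5, 10], whose exact
  Pareto front is f2 = (sqrt(f1) - 2)^2 for theta in [0, 2]. Oracle for
  the optimizer's convergence.
* ``planted`` — a synthetic clustered Pareto front/set: two objective
  blobs, a chosen number of parameters shifted between the blobs by a
  controllable effect size, the rest iid noise. Oracle for cluster-count
  selection and guideline classification.
* ``pulse`` — an analytic adaptation pulse trajectory with closed-form
  objective values (J1 = input step / peak height for a full-return
  triangular pulse; J2 = residual offset / input step). Oracle for the
  objective functionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .model import Trajectory
from .optimize import EvalOutcome

__all__ = ["FixtureSpec", "BenchmarkProblem", "PlantedParetoData", "make_fixture",
           "make_pulse_trajectory"]


@dataclass(frozen=True)
class FixtureSpec:
    """What fixture to generate; generation is deterministic given ``seed``."""

    kind: str                 # benchmark | planted | pulse
    size: int = 40            # solutions (planted) / unused elsewhere
    effect: float = 1.0       # planted between-cluster shift in [0, 1]
    seed: int = 0
    options: dict = field(default_factory=dict)


class BenchmarkProblem:
    """Convex bi-objective benchmark with a closed-form Pareto front."""

    def __init__(self) -> None:
        self.lower = np.array([-5.0])
        self.upper = np.array([10.0])
        self.n_evals = 0

    def __call__(self, theta) -> EvalOutcome:
        self.n_evals += 1
        t = float(np.asarray(theta).ravel()[0])
        return EvalOutcome(J=(t * t, (t - 2.0) ** 2))

    @staticmethod
    def true_front(f1: float) -> float:
        """Analytic front: f2 as a function of f1 in [0, 4]."""
        return (np.sqrt(f1) - 2.0) ** 2


@dataclass
class PlantedParetoData:
    """Synthetic clustered front/set with known structure."""

    front: np.ndarray          # (n, 2) objective blobs
    theta: np.ndarray          # (n, d) parameter values in [0, 1] bounds
    labels: np.ndarray         # true cluster per solution (1 or 2)
    shifted: tuple[int, ...]   # indices of cluster-dependent parameters
    bounds: dict[str, tuple[float, float]]
    names: tuple[str, ...]


def _make_planted(spec: FixtureSpec) -> PlantedParetoData:
    n = spec.size
    if n < 4:
        raise ConfigError("planted fixture needs size >= 4")
    d = int(spec.options.get("n_params", 10))
    n_shift = int(spec.options.get("n_shift", 3))
    if not 0 <= n_shift <= d:
        raise ConfigError("n_shift must be between 0 and n_params")
    shift = float(spec.effect)
    rng = np.random.default_rng(spec.seed)
    labels = np.ones(n, dtype=int)
    labels[n // 2:] = 2
    # two well-separated blobs on the unit trade-off diagonal
    centers = {1: (0.2, 0.8), 2: (0.8, 0.2)}
    front = np.array([centers[c] for c in labels]) + rng.normal(0, 0.04, (n, 2))
    theta = rng.random((n, d))  # iid noise parameters
    for j in range(n_shift):
        base = rng.random(n) * 0.3
        theta[:, j] = base + (labels - 1) * shift * 0.7
    names = tuple(f"p{j}" for j in range(d))
    return PlantedParetoData(
        front=front,
        theta=theta,
        labels=labels,
        shifted=tuple(range(n_shift)),
        bounds={name: (0.0, 1.0) for name in names},
        names=names,
    )


def make_pulse_trajectory(
    step: float = 100.0,
    peak: float = 50.0,
    residual: float = 0.0,
    p_value: float = 10.0,
    tf: float = 100.0,
    n_points: int = 201,
) -> Trajectory:
    """Analytic triangular output pulse with known objective values.

    The input x9 steps from 0 to ``step`` at t0 = 0 and holds; the output
    x8 ramps 0 -> ``peak`` -> ``residual`` (total variation
    peak + |peak - residual|); the repressor x6 ramps monotonically so its
    total variation is exactly ``p_value``. With full return
    (residual = 0): J1 = 2*step/(2*peak) = step/peak and J2 = 0.
    """
    if peak <= 0 or step <= 0:
        raise ConfigError("peak and step must be positive")
    t = np.linspace(0.0, tf, n_points)
    t_peak = tf / 2.0
    up = t <= t_peak
    x8 = np.where(
        up,
        peak * t / t_peak,
        peak + (residual - peak) * (t - t_peak) / (tf - t_peak),
    )
    x6 = p_value * t / tf
    states = np.zeros((9, n_points))
    states[7] = x8
    states[5] = x6
    states[8] = step
    return Trajectory(
        t=t,
        states=states,
        M=np.zeros(n_points),
        tv8=peak + abs(peak - residual),
        tv6=p_value,
        x9_prestep=0.0,
        x8_pre=0.0,
        t0=0.0,
        tf=tf,
        Ie_step=step,
        diagnostics={"synthetic": True},
    )


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; see the module docstring."""
    if spec.kind == "benchmark":
        return BenchmarkProblem()
    if spec.kind == "planted":
        return _make_planted(spec)
    if spec.kind == "pulse":
        return make_pulse_trajectory(**spec.options)
    raise ConfigError(f"unknown fixture kind {spec.kind!r}")
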