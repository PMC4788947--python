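"""The I1-FFL tuning problem as a bounded bi-objective evaluator.

Glues the circuit simulation and the adaptation objectives into the
interface the optimization engine consumes. Supports reduced problems in
which only a subset of the ten tunable parameters is free (the rest pinned
at fixed values), used for brute-force oracle comparisons in low dimension.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, MoodkitError
from .model import (
    BOUNDS,
    DECISION_NAMES,
    CircuitParameters,
    DecisionVector,
    LoadParameters,
    StimulusProtocol,
    simulate,
)
from .objectives import PertinencyBox, evaluate
from .optimize import EvalOutcome

__all__ = ["CircuitProblem"]

#: Violation assigned when the simulation itself fails.
FAILURE_VIOLATION = 1e6


def _range_violation(v: float, lo: float, hi: float) -> float:
    """Normalized distance outside an open interval (0 inside)."""
    if not np.isfinite(v):
        return FAILURE_VIOLATION
    if v <= lo:
        return (lo - v) / max(abs(lo), 1.0) + 1e-12
    if v >= hi:
        return (v - hi) / max(abs(hi), 1.0) + 1e-12
    return 0.0


class CircuitProblem:
    """Evaluate a decision vector of the adaptation circuit.

    Parameters
    ----------
    protocol, box, base, load, tie_kmA
        Experiment definition, pertinency/constraint box, fixed-constant
        overrides, optional downstream load, and whether kmA_CgA follows
        kmC_CgC (same plasmid).
    free
        Names of the tunable parameters exposed to the optimizer; the
        remaining ones are pinned to ``pinned`` (default: mid-bounds).
    bounds
        Optional per-parameter search ranges; each must lie within the
        wet-lab ranges of :data:`moodkit.model.BOUNDS`.
    rtol, atol
        Solver tolerances used for every evaluation.
    """

    def __init__(
        self,
        protocol: Optional[StimulusProtocol] = None,
        box: Optional[PertinencyBox] = None,
        base: Optional[CircuitParameters] = None,
        load: Optional[LoadParameters] = None,
        tie_kmA: bool = True,
        free: Optional[Sequence[str]] = None,
        pinned: Optional[dict[str, float]] = None,
        bounds: Optional[dict[str, tuple[float, float]]] = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> None:
        self.protocol = protocol or StimulusProtocol()
        self.box = box or PertinencyBox()
        self.base = base
        self.load = load
        self.tie_kmA = tie_kmA
        self.rtol = rtol
        self.atol = atol
        self.free = tuple(free) if free is not None else DECISION_NAMES
        unknown = set(self.free) - set(DECISION_NAMES)
        if unknown:
            raise ConfigError(f"unknown decision variables: {sorted(unknown)}")
        mid = {n: 0.5 * (BOUNDS[n][0] + BOUNDS[n][1]) for n in DECISION_NAMES}
        if pinned:
            unknown = set(pinned) - set(DECISION_NAMES)
            if unknown:
                raise ConfigError(f"unknown pinned parameters: {sorted(unknown)}")
            mid.update(pinned)
        self._pinned = mid
        ranges = dict(BOUNDS)
        if bounds:
            for name, (lo, hi) in bounds.items():
                if name not in BOUNDS:
                    raise ConfigError(f"unknown bounded parameter {name!r}")
                wlo, whi = BOUNDS[name]
                if not (wlo <= lo < hi <= whi):
                    raise ConfigError(
                        f"bounds for {name} must satisfy "
                        f"{wlo} <= lo < hi <= {whi}, got ({lo}, {hi})"
                    )
                ranges[name] = (float(lo), float(hi))
        self.bounds = ranges
        self.lower = np.array([ranges[n][0] for n in self.free])
        self.upper = np.array([ranges[n][1] for n in self.free])
        self.n_evals = 0
        self.n_failures = 0

    def full_theta(self, theta: Sequence[float]) -> DecisionVector:
        """Embed a reduced decision vector into the full 10-vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.free),):
            raise ConfigError(
                f"expected {len(self.free)} free parameters, got {theta.shape}"
            )
        values = dict(self._pinned)
        values.update(zip(self.free, theta.tolist()))
        return DecisionVector(**values)

    def __call__(self, theta: Sequence[float]) -> EvalOutcome:
        self.n_evals += 1
        dv = self.full_theta(theta)
        try:
            traj = simulate(
                dv,
                self.protocol,
                self.load,
                base=self.base,
                tie_kmA=self.tie_kmA,
                rtol=self.rtol,
                atol=self.atol,
                n_points=0,
            )
            res = evaluate(traj, self.box)
        except MoodkitError:
            self.n_failures += 1
            return EvalOutcome(
                J=(np.inf, np.inf), P=np.nan,
                violation=FAILURE_VIOLATION, pertinent=False, feasible=False,
            )
        violation = (
            _range_violation(res.J1, *self.box.j1)
            + _range_violation(res.J2, *self.box.j2)
            + _range_violation(res.P, *self.box.p)
        )
        return EvalOutcome(
            J=(res.J1, res.J2), P=res.P, violation=violation,
            pertinent=res.pertinent, feasible=res.feasible,
        )
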