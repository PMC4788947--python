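"""Application scenarios: wet-lab knob sweeps and downstream-load robustness.

Scenario I — tuning-knob sweep: starting from a chosen Pareto solution,
vary a single tunable parameter over a grid with everything else fixed.
If the guidelines are robust, the swept designs stay close to the Pareto
front (a one-parameter wet-lab edit moves the circuit *along* the
trade-off rather than off it), whereas sweeping a critical parameter such
as dC destroys pertinency altogether.

Scenario II — load analysis: re-simulate every Pareto solution with a
downstream binding load (total load species LT, binding K1, unbinding K2)
and compare loaded against unloaded objectives. Only the |front| solutions
are re-simulated — no re-optimization — which is what makes a-posteriori
retroactivity screening cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
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
from .objectives import ObjectiveResult, PertinencyBox, evaluate, is_admissible
from .optimize import ParetoApproximation

__all__ = ["SweepResult", "LoadComparison", "knob_sweep", "load_analysis",
           "log_grid", "front_margin_violations"]


def front_margin_violations(
    points: np.ndarray, front: np.ndarray, margin: float = 0.05
) -> np.ndarray:
    """Which points are dominated by the front beyond a normalized margin.

    Objectives are normalized to the front's ideal/nadir box; a point
    violates if some front member beats it by more than ``margin`` in
    *every* normalized objective. Swept designs that stay within the
    margin are "on top of the front" for practical purposes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    front = np.atleast_2d(np.asarray(front, dtype=float))
    lo = front.min(axis=0)
    span = front.max(axis=0) - lo
    span[span <= 0] = 1.0
    pn = (points - lo) / span
    fn = (front - lo) / span
    out = np.zeros(points.shape[0], dtype=bool)
    for i, p in enumerate(pn):
        out[i] = bool(np.any(np.all(fn <= p - margin, axis=1)))
    return out


def log_grid(start: float, stop: float, num: int = 20) -> np.ndarray:
    """Logarithmically spaced sweep grid from ``start`` to ``stop``."""
    if start <= 0 or stop <= 0:
        raise ConfigError("log grid endpoints must be positive")
    return np.geomspace(start, stop, num)


@dataclass
class SweepResult:
    """Objective trace of a single-parameter sweep."""

    base_theta: DecisionVector
    parameter: str
    values: np.ndarray
    results: list[Optional[ObjectiveResult]]   # None where simulation failed
    in_bounds: np.ndarray                      # grid value within the wet-lab range
    base_result: ObjectiveResult
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for v, res, ok in zip(self.values, self.results, self.in_bounds):
            row = {"value": float(v), "in_bounds": bool(ok)}
            if res is None:
                row.update(J1=np.nan, J2=np.nan, P=np.nan,
                           pertinent=False, feasible=False, failed=True)
            else:
                row.update(J1=res.J1, J2=res.J2, P=res.P,
                           pertinent=res.pertinent, feasible=res.feasible,
                           failed=False)
            rows.append(row)
        return pd.DataFrame(rows)


def knob_sweep(
    theta0: DecisionVector | Sequence[float],
    name: str,
    grid: Sequence[float],
    protocol: Optional[StimulusProtocol] = None,
    box: Optional[PertinencyBox] = None,
    base: Optional[CircuitParameters] = None,
    load: Optional[LoadParameters] = None,
    tie_kmA: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepResult:
    """Sweep one tunable parameter of a base design over ``grid``.

    Grid values may deliberately leave the optimization bounds (a wet-lab
    part outside the characterized range); they are flagged rather than
    rejected. A failed simulation flags its row and the sweep continues.
    """
    if name not in DECISION_NAMES:
        raise ConfigError(
            f"unknown tunable parameter {name!r}; expected one of {DECISION_NAMES}"
        )
    if not isinstance(theta0, DecisionVector):
        theta0 = DecisionVector.from_array(np.asarray(theta0, dtype=float))
    protocol = protocol or StimulusProtocol()
    box = box or PertinencyBox()
    grid = np.asarray(grid, dtype=float)
    lo, hi = BOUNDS[name]
    in_bounds = (grid >= lo) & (grid <= hi)

    base_traj = simulate(theta0, protocol, load, base=base, tie_kmA=tie_kmA,
                         rtol=rtol, atol=atol, n_points=0)
    base_result = evaluate(base_traj, box)

    results: list[Optional[ObjectiveResult]] = []
    for v in grid:
        params = theta0.expand(base, tie_kmA=tie_kmA)
        from dataclasses import replace

        params = replace(params, **{name: float(v)})
        if tie_kmA and name == "kmC_CgC":
            params = replace(params, kmA_CgA=float(v))
        try:
            traj = simulate(params, protocol, load, rtol=rtol, atol=atol,
                            n_points=0)
            results.append(evaluate(traj, box))
        except MoodkitError:
            results.append(None)
    return SweepResult(
        base_theta=theta0,
        parameter=name,
        values=grid,
        results=results,
        in_bounds=in_bounds,
        base_result=base_result,
        meta={"load": load is not None},
    )


@dataclass
class LoadComparison:
    """Per-Pareto-solution objectives with and without the downstream load."""

    unloaded: np.ndarray            # (n, 2) J1, J2 without load
    loaded: np.ndarray              # (n, 2) J1, J2 with load
    retained: np.ndarray            # bool: still pertinent+feasible under load
    load: LoadParameters
    simulations: int
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "J1_unloaded": self.unloaded[:, 0],
                "J2_unloaded": self.unloaded[:, 1],
                "J1_loaded": self.loaded[:, 0],
                "J2_loaded": self.loaded[:, 1],
                "adaptation_retained": self.retained,
            }
        )


def load_analysis(
    pareto: ParetoApproximation,
    load: Optional[LoadParameters] = None,
    protocol: Optional[StimulusProtocol] = None,
    box: Optional[PertinencyBox] = None,
    base: Optional[CircuitParameters] = None,
    tie_kmA: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> LoadComparison:
    """Re-evaluate every Pareto solution under a downstream binding load.

    The loaded system is pre-equilibrated jointly with the load present
    (so x10 + x11 = LT splits at its pre-stimulus steady state), stepped
    and re-integrated; exactly ``len(pareto)`` simulations are run.
    Unloaded objectives are taken from the stored front.
    """
    if len(pareto) == 0:
        raise ConfigError("Pareto approximation is empty")
    load = load or LoadParameters()
    protocol = protocol or StimulusProtocol()
    box = box or PertinencyBox()
    unloaded = pareto.front()
    loaded = np.full_like(unloaded, np.nan)
    retained = np.zeros(len(pareto), dtype=bool)
    sims = 0
    for i, ind in enumerate(pareto.individuals):
        try:
            traj = simulate(
                ind.theta, protocol, load, base=base, tie_kmA=tie_kmA,
                rtol=rtol, atol=atol, n_points=0,
            )
            sims += 1
            res = evaluate(traj, box)
        except MoodkitError:
            sims += 1
            continue
        loaded[i] = res.J1, res.J2
        pert, feas = is_admissible(res, box)
        retained[i] = pert and feas
    return LoadComparison(
        unloaded=unloaded,
        loaded=loaded,
        retained=retained,
        load=load,
        simulations=sims,
        meta={"K1": load.K1, "K2": load.K2, "LT": load.LT},
    )
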