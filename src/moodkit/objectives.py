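"""Adaptation objectives for the stimulus-response experiment.

Two indexes, both minimized:

* ``J1`` — inverse sensitivity: the input variation divided by the total
  variation of the output. The total absolute variation of the output is
  half the accumulated |dx8/dt|, so ``J1 = 2 (x9(tf) - x9(t0)) / ∫|dx8/dt| dt``.
  A large output pulse for a given input step gives a small J1.
* ``J2`` — inverse precision: the residual output change relative to the
  input change, ``J2 = (x8(tf) - x8(t0)) / (x9(tf) - x9(t0))``. Perfect
  adaptation (output back at its pre-stimulus value) gives J2 = 0.

``x9(t0)`` is the pre-step inducer value, so the input change is the
applied step net of inducer decay over the experiment.

A third functional, ``P = ∫|dx6/dt| dt``, bounds the excursion of the
repressor protein B: without it the optimizer buys precision with
unrealistically high repressor levels. Solutions must also sit inside a
*pertinency box* on (J1, J2) — outside it the response no longer counts as
adaptive at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError, InvalidParameterError
from .model import Trajectory

__all__ = [
    "PertinencyBox",
    "ObjectiveResult",
    "total_variation",
    "evaluate",
    "is_admissible",
]

#: Floor below which a denominator is treated as zero (nM).
DENOM_FLOOR = 1e-9


@dataclass(frozen=True)
class PertinencyBox:
    """Objective-space box delimiting designer-relevant (adaptive) behavior.

    The default J ranges are the standard pertinency limits for adaptive behavior; the default P
    range keeps the repressor-B excursion above the noise floor and below
    an unrealistic ceiling (the constraint is stated with a 1e4 ceiling
    where it is introduced and 1e5 in the compact problem statement; the
    former is the default here, configurable).
    """

    j1: tuple[float, float] = (1e-3, 200.0)
    j2: tuple[float, float] = (1e-4, 20.0)
    p: tuple[float, float] = (1.0, 1e4)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("j1", self.j1), ("j2", self.j2), ("p", self.p)):
            if not lo < hi:
                raise InvalidParameterError(f"{name} range must have lower < upper")


@dataclass(frozen=True)
class ObjectiveResult:
    """Objectives, constraint value and screening flags for one simulation."""

    J1: float
    J2: float
    P: float
    pertinent: bool
    feasible: bool
    diagnostics: dict = field(default_factory=dict, compare=False)


def total_variation(traj: Trajectory, species: int) -> float:
    """Accumulated |dx/dt| over the experiment for ``species`` (1-based).

    For the output protein C (x8) and repressor B (x6) this is read from
    the quadrature states integrated alongside the model; other species are
    not accumulated during integration, so their variation is estimated
    from the sampled series by trapezoidal integration of |dx/dt|.
    """
    if species == 8:
        return traj.tv8
    if species == 6:
        return traj.tv6
    if 1 <= species <= traj.n_states:
        if traj.t.size < 3:
            raise EvaluationError(
                f"x{species} has no quadrature accumulator and the trajectory "
                "is too sparse for a finite-difference estimate"
            )
        deriv = np.gradient(traj.x(species), traj.t)
        return float(np.trapezoid(np.abs(deriv), traj.t))
    raise EvaluationError(f"species x{species} not present in trajectory")


def evaluate(
    traj: Trajectory, box: PertinencyBox | None = None
) -> ObjectiveResult:
    """Compute (J1, J2, P) and screening flags from a simulated trajectory."""
    box = box or PertinencyBox()
    dx9 = traj.final(9) - traj.x9_prestep
    if abs(dx9) < DENOM_FLOOR:
        raise EvaluationError(
            f"input change {dx9:.3e} nM below floor — no stimulus applied?"
        )
    tv8 = traj.tv8
    dx8 = traj.final(8) - traj.x8_pre
    if tv8 < DENOM_FLOOR:
        j1 = math.inf  # flat output: zero variation, sensitivity undefined
    else:
        j1 = 2.0 * dx9 / tv8
    j2 = dx8 / dx9
    p_val = traj.tv6
    pertinent, feasible = _flags(j1, j2, p_val, box)
    return ObjectiveResult(
        J1=j1,
        J2=j2,
        P=p_val,
        pertinent=pertinent,
        feasible=feasible,
        diagnostics={"tv8": tv8, "dx9": dx9, "dx8": dx8},
    )


def _flags(j1: float, j2: float, p_val: float, box: PertinencyBox) -> tuple[bool, bool]:
    pertinent = (
        math.isfinite(j1)
        and math.isfinite(j2)
        and box.j1[0] < j1 < box.j1[1]
        and box.j2[0] < j2 < box.j2[1]
    )
    feasible = pertinent and box.p[0] < p_val < box.p[1]
    return pertinent, feasible


def is_admissible(
    result: ObjectiveResult, box: PertinencyBox | None = None
) -> tuple[bool, bool]:
    """(pertinent, feasible) of a result against a (possibly new) box.

    Pertinent: both objectives inside the box. Feasible: additionally the
    repressor-excursion constraint P holds. Non-finite sentinels map to
    ``(False, False)``.
    """
    box = box or PertinencyBox()
    return _flags(result.J1, result.J2, result.P, box)
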