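"""Level-Diagram data for Pareto front/set visualization.

A Level Diagram plots every Pareto solution in a panel per objective and a
panel per decision variable. The X-axis is the raw objective or parameter
value; the Y-axis is the same quantity in every panel: the p-norm of the
solution's min-max-normalized objective vector, i.e. its distance to the
ideal corner. A solution therefore sits at one height everywhere, which
lets the eye link its position across panels. Cluster membership is
carried as a column so plots can color solutions by tuning strategy.

The canonical artifact is the data table; rendering is optional so the
module stays testable headlessly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, InvalidParameterError

__all__ = ["normalize_front", "scores", "export_ld", "plot_ld"]


def normalize_front(front: np.ndarray) -> np.ndarray:
    """Min-max normalize each objective to [0, 1].

    A degenerate dimension (min == max, e.g. a single-solution front) maps
    to 0 so the ideal corner stays at the origin.
    """
    J = np.atleast_2d(np.asarray(front, dtype=float))
    if J.shape[0] < 1:
        raise ConfigError("front must contain at least one solution")
    lo = J.min(axis=0)
    span = J.max(axis=0) - lo
    out = np.zeros_like(J)
    ok = span > 0
    out[:, ok] = (J[:, ok] - lo[ok]) / span[ok]
    return out


def scores(normalized: np.ndarray, p: float = 2.0) -> np.ndarray:
    """p-norm of each normalized objective row (``p=inf`` gives the max)."""
    X = np.atleast_2d(np.asarray(normalized, dtype=float))
    if not (p >= 1):
        raise InvalidParameterError(f"norm order must satisfy p >= 1, got {p!r}")
    if np.isinf(p):
        return X.max(axis=1)
    return np.linalg.norm(X, ord=p, axis=1)


def export_ld(
    front: np.ndarray,
    thetas: np.ndarray,
    labels: Optional[Sequence[int]] = None,
    p: float = 2.0,
    names: Optional[Sequence[str]] = None,
):
    """One-row-per-solution Level-Diagram table.

    Columns: cluster label, score ||J_hat||_p, raw and normalized
    objectives, and the decision-variable values. Round-trips losslessly
    through CSV (plain floats and integers only).
    """
    import pandas as pd

    J = np.atleast_2d(np.asarray(front, dtype=float))
    T = np.atleast_2d(np.asarray(thetas, dtype=float))
    n = J.shape[0]
    if T.shape[0] != n:
        raise ConfigError(
            f"front has {n} rows but set has {T.shape[0]}"
        )
    if labels is None:
        labels = np.ones(n, dtype=int)
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ConfigError("labels length must match the front")
    Jn = normalize_front(J)
    y = scores(Jn, p=p)
    if names is None:
        names = [f"theta{j}" for j in range(T.shape[1])]
    data = {"cluster": labels.astype(int), "score": y}
    for q in range(J.shape[1]):
        data[f"J{q + 1}"] = J[:, q]
        data[f"J{q + 1}_norm"] = Jn[:, q]
    for j, name in enumerate(names):
        data[str(name)] = T[:, j]
    return pd.DataFrame(data)


def plot_ld(table, out_prefix: str, trajectories=None) -> list[str]:
    """Render the Level-Diagram panels to PNG files; returns written paths.

    One panel per objective and per decision variable (score on Y, value
    on X, color by cluster), plus an optional time-course panel when
    ``trajectories`` (an iterable of (Trajectory, cluster) pairs) is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[str] = []
    clusters = table["cluster"].to_numpy()
    cmap = plt.get_cmap("tab10")
    colors = [cmap((c - 1) % 10) for c in clusters]
    skip = {"cluster", "score"} | {
        c for c in table.columns if str(c).endswith("_norm")
    }
    for col in table.columns:
        if col in skip:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(table[col], table["score"], c=colors, s=18)
        ax.set_xlabel(str(col))
        ax.set_ylabel("||J_hat||_p")
        fig.tight_layout()
        path = f"{out_prefix}_{col}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    if trajectories:
        fig, ax = plt.subplots(figsize=(5, 3))
        for traj, cluster in trajectories:
            ax.plot(traj.t, traj.x(8), color=cmap((cluster - 1) % 10), lw=0.8)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("protein C (nM)")
        fig.tight_layout()
        path = f"{out_prefix}_timecourses.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
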