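"""Tuning-guideline extraction from the Pareto-optimal solutions.

The Pareto front is clustered hierarchically (Euclidean distance on
min-max-normalized objectives, weighted-centroid/WPGMC linkage). The
cluster count is chosen by cutting the tree at every k from ten down to
two and, at each cut, testing every tunable parameter with a
Kruskal-Wallis test (the rank-based analogue of one-way ANOVA) across
clusters; the k that maximizes the number of significantly
cluster-dependent parameters wins (ties break toward fewer clusters).

Parameters then classify into three wet-lab guideline categories:

* *cluster-specific* tuning knobs — significantly different across
  clusters; their per-cluster ranges encode the trade-off strategies,
* *general* guidelines — not cluster-dependent, but the optimizer
  compressed their range well inside the initial search interval, so the
  compressed range is required for adaptation regardless of strategy,
* *unconstrained* — neither cluster-dependent nor compressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kruskal as _scipy_kruskal

from .errors import ConfigError, InvalidParameterError
from .leveldiagrams import normalize_front

__all__ = [
    "ClusteringResult",
    "GuidelineEntry",
    "GuidelineReport",
    "cluster_tree",
    "kruskal_wallis",
    "select_k",
    "extract_guidelines",
]


def cluster_tree(front: np.ndarray, features: Optional[np.ndarray] = None) -> np.ndarray:
    """Agglomerative linkage tree over the (normalized) objective vectors.

    Objectives are min-max normalized per dimension before computing
    Euclidean distances (raw J1 spans two orders of magnitude more than J2
    and would otherwise dominate the metric). ``features``, if given, is
    appended to the normalized objectives (e.g. normalized parameters, for
    the variant that clusters in the joint space).

    Returns a scipy linkage matrix (weighted-centroid / median linkage).
    """
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    if front.shape[0] < 2:
        raise ConfigError("clustering needs at least 2 solutions")
    X = normalize_front(front)
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.shape[0] != X.shape[0]:
            raise ConfigError("features row count must match the front")
        X = np.hstack([X, features])
    return linkage(X, method="median", metric="euclidean")


def kruskal_wallis(
    values: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value for ``values`` grouped by ``labels``.

    Rank-based with tie correction; p from the chi-square approximation
    with k-1 degrees of freedom. The degenerate all-identical case (zero
    rank variance) returns (0.0, 1.0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InvalidParameterError("values and labels must align")
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise InvalidParameterError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = _scipy_kruskal(*groups)
    return float(h), float(p)


def _threshold(alpha: float, d: int, correction: str) -> float:
    if correction == "bonferroni":
        return alpha / max(d, 1)
    if correction == "none":
        return alpha
    raise ConfigError(f"unknown correction {correction!r}")


@dataclass
class ClusteringResult:
    """Selected cut of the linkage tree plus the per-k significance table."""

    k: int
    labels: np.ndarray          # cluster id (1..k) per solution
    tree: np.ndarray            # scipy linkage matrix
    table: object               # DataFrame: k, parameter, H, p
    alpha: float

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        if not (2 <= uniq.size):
            raise ConfigError("selected clustering must have at least 2 clusters")


def select_k(
    tree: np.ndarray,
    theta: np.ndarray,
    alpha: float = 0.05,
    names: Optional[Sequence[str]] = None,
    k_max: int = 10,
    k_min: int = 2,
    correction: str = "bonferroni",
) -> ClusteringResult:
    """Choose the cluster count maximizing significantly split parameters.

    Cuts the tree at k = ``k_max`` down to ``k_min`` (capped at n-1),
    Kruskal-Wallis-tests every parameter column of ``theta`` against the
    cluster labels, counts the significant ones, and keeps the k with the
    highest count (ties toward the smallest k).

    ``alpha`` is treated as a family-wise level: each cut tests all d
    parameters at once and the max-count selection scans many cuts, so by
    default each individual test is held to the Bonferroni-corrected
    threshold alpha/d. Without the correction, per-test false positives
    (expected ~0.05 d per cut) routinely tip the count toward spurious
    large k. ``correction="none"`` restores the raw per-test threshold.
    """
    import pandas as pd

    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n, d = theta.shape
    if names is None:
        names = [f"theta{j}" for j in range(d)]
    threshold = _threshold(alpha, d, correction)
    rows = []
    best_k, best_count = None, -1
    candidates = range(min(k_max, n - 1), max(k_min, 2) - 1, -1)
    labels_by_k: dict[int, np.ndarray] = {}
    for k in candidates:
        labels = fcluster(tree, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        labels_by_k[k] = labels
        count = 0
        for j in range(d):
            h, p = kruskal_wallis(theta[:, j], labels)
            rows.append({"k": k, "parameter": names[j], "H": h, "p": p,
                         "significant": p < threshold})
            if p < threshold:
                count += 1
        # iterate high k -> low k; '>=' prefers the later (smaller) k on ties
        if count >= best_count:
            best_k, best_count = k, count
    if best_k is None:
        raise ConfigError("no valid tree cut produced >= 2 clusters")
    return ClusteringResult(
        k=best_k,
        labels=labels_by_k[best_k],
        tree=tree,
        table=pd.DataFrame(rows),
        alpha=alpha,
    )


@dataclass(frozen=True)
class GuidelineEntry:
    """Guideline for one tunable parameter."""

    name: str
    category: str                       # cluster-specific | general | unconstrained
    initial: tuple[float, float]
    overall: tuple[float, float]
    per_cluster: dict[int, tuple[float, float]]
    p_value: float
    H: float


@dataclass
class GuidelineReport:
    """Per-parameter tuning guidelines extracted from a clustered Pareto set."""

    entries: list[GuidelineEntry]
    k: int
    alpha: float
    shrink_threshold: float
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> GuidelineEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self):
        """Tabular layout: parameter, initial range, guideline per category."""
        import pandas as pd

        rows = []
        for e in self.entries:
            row = {
                "parameter": e.name,
                "initial_lo": e.initial[0],
                "initial_hi": e.initial[1],
                "category": e.category,
                "overall_lo": e.overall[0],
                "overall_hi": e.overall[1],
                "H": e.H,
                "p": e.p_value,
            }
            for c, (lo, hi) in sorted(e.per_cluster.items()):
                row[f"cluster{c}_lo"] = lo
                row[f"cluster{c}_hi"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def extract_guidelines(
    clustering: ClusteringResult,
    theta: np.ndarray,
    bounds: dict[str, tuple[float, float]],
    alpha: Optional[float] = None,
    shrink_threshold: float = 0.6,
    correction: str = "bonferroni",
) -> GuidelineReport:
    """Classify each parameter and report its optimized ranges.

    Kruskal-Wallis-significant parameters (at the same family-wise
    ``alpha``/correction convention as :func:`select_k`) become
    cluster-specific knobs with per-cluster [min, max]. Others whose
    overall optimized width is at most ``shrink_threshold`` times the
    initial width become general guidelines; the rest are unconstrained.
    """
    alpha = clustering.alpha if alpha is None else alpha
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    names = list(bounds)
    if theta.shape[1] != len(names):
        raise ConfigError("theta column count must match bounds")
    if theta.shape[0] != clustering.labels.size:
        raise ConfigError("theta row count must match clustering labels")
    threshold = _threshold(alpha, len(names), correction)
    entries = []
    for j, name in enumerate(names):
        col = theta[:, j]
        h, p = kruskal_wallis(col, clustering.labels)
        lo0, hi0 = bounds[name]
        overall = (float(col.min()), float(col.max()))
        per_cluster = {
            int(c): (float(col[clustering.labels == c].min()),
                     float(col[clustering.labels == c].max()))
            for c in np.unique(clustering.labels)
        }
        if p < threshold:
            category = "cluster-specific"
        elif overall[1] - overall[0] <= shrink_threshold * (hi0 - lo0):
            category = "general"
        else:
            category = "unconstrained"
        entries.append(
            GuidelineEntry(
                name=name, category=category, initial=(lo0, hi0),
                overall=overall, per_cluster=per_cluster, p_value=p, H=h,
            )
        )
    return GuidelineReport(
        entries=entries,
        k=clustering.k,
        alpha=alpha,
        shrink_threshold=shrink_threshold,
    )
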