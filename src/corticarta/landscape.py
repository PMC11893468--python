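"""Subregion landscape metrics: flattening, smoothness and waviness.

A subregion's scalar topography (typically the cytoarchitectural axis E1) is
described after flattening the subregion to two dimensions with a
geodesic-distance-preserving embedding.  Smoothness is the adjusted R^2 of a
low-order bivariate polynomial fit of the field on the two spatial axes;
waviness is the fraction of mesh edges whose endpoint values straddle the
mean plane — a surface-roughness notion borrowed from materials engineering.
Subregions are compared with a one-way ANOVA in which each subregion
contributes one observation per hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components, dijkstra

from .mesh import CorticalSheet, edge_graph

__all__ = [
    "Landscape",
    "flatten_subregion",
    "smoothness",
    "waviness",
    "compare_subregions",
]


@dataclass
class Landscape:
    """2D point cloud with a scalar field and an adjacency edge list."""

    coords2d: np.ndarray  # (P, 2)
    values: np.ndarray  # (P,)
    edges: np.ndarray  # (E, 2) indices of adjacent points

    def __post_init__(self) -> None:
        self.coords2d = np.asarray(self.coords2d, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if not np.all(np.isfinite(self.coords2d)):
            raise ValueError("coordinates must be finite")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.coords2d.shape[0]
        ):
            raise ValueError("edges reference invalid points")


def flatten_subregion(mesh: CorticalSheet, subregion: np.ndarray) -> np.ndarray:
    """Two-dimensional geodesic-preserving flattening of a connected patch.

    Runs Isomap on the subregion's mesh-graph geodesics: classical
    multidimensional scaling of the geodesic distance matrix, keeping the two
    leading components.  Output is mean-centred.
    """
    subregion = np.asarray(subregion)
    if subregion.dtype == bool:
        subregion = np.flatnonzero(subregion)
    g = mesh.graph()[np.ix_(subregion, subregion)]
    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise ValueError(f"subregion is disconnected ({n_comp} components)")
    d = dijkstra(g, directed=False)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return coords - coords.mean(axis=0)


def _polynomial_design(coords2d: np.ndarray, order: int) -> np.ndarray:
    x, y = coords2d[:, 0], coords2d[:, 1]
    cols = [x**a * y**b for a in range(order + 1) for b in range(order + 1 - a)]
    return np.column_stack(cols)


def smoothness(landscape: Landscape, order: int = 2, adjusted: bool = True) -> float:
    """(Adjusted) R^2 of a bivariate polynomial fit of the field on (x, y).

    All monomials ``x^a y^b`` with ``a + b <= order`` enter the design;
    ``adjusted=False`` returns the raw coefficient of determination (which
    is non-decreasing in the order, the designs being nested).
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3 or 4")
    design = _polynomial_design(landscape.coords2d, order)
    n, p_full = design.shape
    if n <= p_full:
        raise ValueError("need more points than polynomial terms")
    if np.linalg.matrix_rank(design) < p_full:
        raise ValueError("rank-deficient polynomial design")
    y = landscape.values
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    r2 = 1.0 - ss_res / ss_tot
    if not adjusted:
        return float(r2)
    p = p_full - 1  # predictors excluding the intercept
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def waviness(landscape: Landscape) -> float:
    """Fraction of edges whose endpoint values strictly straddle the mean.

    The field is mean-centred first; an edge counts as a zero-plane crossing
    only when its endpoints have strictly opposite signs (exact zeros do not
    cross).  Division by the total edge count keeps the score in [0, 1] and
    comparable across subregion sizes and mesh resolutions.
    """
    if landscape.edges.shape[0] < 1:
        raise ValueError("need at least one edge")
    centred = landscape.values - landscape.values.mean()
    a = centred[landscape.edges[:, 0]]
    b = centred[landscape.edges[:, 1]]
    crossings = np.sum(a * b < 0)
    return float(crossings) / landscape.edges.shape[0]


def compare_subregions(
    metrics: pd.DataFrame, n_permutations: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """One-way ANOVA across subregions, hemispheres as replicates.

    ``metrics`` must have columns ``subregion`` and ``hemisphere`` plus one
    column per metric (e.g. ``r2_order2..4``, ``waviness``).  Every
    subregion must contribute both hemispheres.  Returns a table of F and p
    per metric; when the within-group variance is exactly zero but groups
    differ, F is reported as ``inf`` with p 0 and flagged degenerate.
    ``n_permutations`` adds a label-permutation p-value per metric
    (``p_perm``) — a useful alternative given only two replicates per group.
    """
    required = {"subregion", "hemisphere"}
    if not required.issubset(metrics.columns):
        raise ValueError("metrics needs 'subregion' and 'hemisphere' columns")
    counts = metrics.groupby("subregion")["hemisphere"].nunique()
    if (counts < 2).any():
        missing = counts[counts < 2].index.tolist()
        raise ValueError(f"missing hemisphere observation for subregions: {missing}")
    metric_cols = [c for c in metrics.columns if c not in required]

    def f_stat_of(values, labels):
        groups = [values[labels == s] for s in np.unique(labels)]
        grand = values.mean()
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        if ss_within == 0:
            return (np.inf if ss_between > 0 else 0.0), ss_between, ss_within
        k, n = len(groups), values.size
        return (ss_between / (k - 1)) / (ss_within / (n - k)), ss_between, ss_within

    labels = metrics["subregion"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for col in metric_cols:
        values = metrics[col].to_numpy(dtype=float)
        f_stat, ss_b, ss_w = f_stat_of(values, labels)
        degenerate = ss_w == 0 and ss_b > 0
        if degenerate:
            p = 0.0
        elif ss_b == 0 and ss_w == 0:
            f_stat, p = 0.0, 1.0
        else:
            groups = [values[labels == s] for s in np.unique(labels)]
            f_stat, p = sps.f_oneway(*groups)
        row = {"metric": col, "F": float(f_stat), "p": float(p), "degenerate": degenerate}
        if n_permutations:
            null = np.array(
                [
                    f_stat_of(values, rng.permutation(labels))[0]
                    for _ in range(n_permutations)
                ]
            )
            row["p_perm"] = float((np.sum(null >= f_stat) + 1) / (n_permutations + 1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def landscape_metrics(
    landscapes: dict[tuple[str, str], Landscape], orders: tuple[int, ...] = (2, 3, 4)
) -> pd.DataFrame:
    """Smoothness (per order) and waviness for (subregion, hemisphere) pairs."""
    rows = []
    for (sub, hemi), ls in landscapes.items():
        row = {"subregion": sub, "hemisphere": hemi}
        for k in orders:
            row[f"r2_order{k}"] = smoothness(ls, order=k)
        row["waviness"] = waviness(ls)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_metric_differences(metrics: pd.DataFrame, column: str) -> pd.DataFrame:
    """Absolute subregion-mean differences for one metric (descriptive aid)."""
    means = metrics.groupby("subregion")[column].mean()
    rows = [
        {"a": a, "b": b, "difference": abs(means[a] - means[b])}
        for a, b in combinations(means.index, 2)
    ]
    return pd.DataFrame(rows)
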