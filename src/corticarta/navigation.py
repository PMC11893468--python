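"""Greedy spatial navigation on structural connectomes.

Navigation (greedy routing) models decentralised communication on a spatially
embedded network: from the current node, the next hop is the structurally
connected neighbour closest (in Euclidean space) to the target.  The path
length is the summed distance of the selected hops and navigation efficiency
``E_nav`` is its inverse; navigation fails — efficiency zero — when a node
repeats or a dead end is reached.  Routing is computed within each hemisphere
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Connectome",
    "NavigationResult",
    "weight_to_length",
    "navigate_path",
    "navigation_efficiency_matrix",
    "summarize_rows",
]


@dataclass
class Connectome:
    """Symmetric weighted connectome with node coordinates and metadata."""

    W: np.ndarray  # (P, P) non-negative streamline weights, zero diagonal
    coords: np.ndarray  # (P, 3) node coordinates, mm
    hemisphere: np.ndarray  # (P,) "L"/"R"
    network: np.ndarray | None = None  # (P,) functional network labels
    cortical_type: np.ndarray | None = None  # (P,) type codes
    e1: np.ndarray | None = None  # (P,) cytoarchitectural axis values

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def lengths(self) -> np.ndarray:
        """Log-transformed edge lengths L (infinite where no edge)."""
        return weight_to_length(self.W)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between node coordinates."""
        return np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=2)


@dataclass
class NavigationResult:
    """Navigation efficiency matrix with success bookkeeping."""

    E_nav: np.ndarray  # (P, P), 1/mm; 0 where navigation failed; NaN where masked
    success: np.ndarray  # (P, P) bool

    def masked(self) -> np.ndarray:
        return ~np.isfinite(self.E_nav)


def weight_to_length(W: np.ndarray) -> np.ndarray:
    """Remap weights to lengths: ``L = -log10(W / (max(W) + min(W > 0)))``.

    The denominator exceeds the maximum weight, so every edge maps to a
    strictly positive length and the transform is strictly decreasing in W.
    Entries with ``W == 0`` are absent edges and map to ``inf``.
    """
    W = np.asarray(W, dtype=float)
    pos = W[W > 0]
    if pos.size == 0:
        raise ValueError("W has no positive entries")
    denom = W.max() + pos.min()
    with np.errstate(divide="ignore"):
        L = -np.log10(W / denom)
    L[W == 0] = np.inf
    return L


def navigate_path(
    connectome: Connectome, source: int, target: int, metric: str = "euclidean"
) -> tuple[list[int], float, bool]:
    """Greedy navigation from ``source`` to ``target`` (same hemisphere).

    At each step, hop to the connected neighbour with minimal Euclidean
    distance to the target (ties broken by lowest node id).  Returns the node
    path, its length, and whether the target was reached.  ``metric`` selects
    the reported length: summed Euclidean hop distances (default) or summed
    log-transformed edge lengths (``"weighted"``).
    """
    if source == target:
        raise ValueError("source and target must differ")
    if connectome.hemisphere[source] != connectome.hemisphere[target]:
        raise ValueError("navigation is computed within each hemisphere separately")
    if metric not in ("euclidean", "weighted"):
        raise ValueError(f"unknown metric: {metric!r}")
    coords = connectome.coords
    W = connectome.W
    L = connectome.lengths() if metric == "weighted" else None
    d_target = np.linalg.norm(coords - coords[target], axis=1)

    path = [source]
    visited = {source}
    length = 0.0
    current = source
    while current != target:
        neigh = np.flatnonzero(W[current] > 0)
        if neigh.size == 0:
            return path, length, False
        nxt = int(neigh[np.argmin(d_target[neigh])])  # argmin takes lowest id on ties
        hop = (
            np.linalg.norm(coords[nxt] - coords[current])
            if metric == "euclidean"
            else L[current, nxt]
        )
        length += float(hop)
        if nxt in visited:
            path.append(nxt)
            return path, length, False
        path.append(nxt)
        visited.add(nxt)
        current = nxt
    return path, length, True


def navigation_efficiency_matrix(
    connectome: Connectome, metric: str = "euclidean"
) -> NavigationResult:
    """Navigate all ordered intra-hemisphere pairs; ``E_nav = 1/length``.

    Failed navigations score 0 (informative inefficiency, keeping averages
    defined); the diagonal and cross-hemisphere entries are masked with NaN.
    Each hemisphere's subgraph must be connected.
    """
    p = connectome.n_nodes
    W = connectome.W
    coords = connectome.coords
    L = connectome.lengths() if metric == "weighted" else None
    e_nav = np.full((p, p), np.nan)
    success = np.zeros((p, p), dtype=bool)
    neighbours = [np.flatnonzero(W[i] > 0) for i in range(p)]
    hop_dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    for label in np.unique(connectome.hemisphere):
        nodes = np.flatnonzero(connectome.hemisphere == label)
        n_comp, _ = connected_components(
            sparse.csr_matrix(W[np.ix_(nodes, nodes)] > 0), directed=False
        )
        if n_comp != 1:
            raise ValueError(f"hemisphere {label!r} subgraph is disconnected")
        for t in nodes:
            # greedy successor toward t is a fixed function of the current node
            succ = np.full(p, -1, dtype=int)
            for u in nodes:
                if u == t or neighbours[u].size == 0:
                    continue
                nb = neighbours[u]
                succ[u] = int(nb[np.argmin(hop_dist[nb, t])])
            for s in nodes:
                if s == t:
                    continue
                length = 0.0
                current = s
                visited = {s}
                ok = False
                while True:
                    nxt = succ[current]
                    if nxt < 0:
                        break
                    length += hop_dist[current, nxt] if metric == "euclidean" else L[current, nxt]
                    if nxt == t:
                        ok = True
                        break
                    if nxt in visited:
                        break
                    visited.add(nxt)
                    current = nxt
                e_nav[s, t] = 1.0 / length if ok else 0.0
                success[s, t] = ok
    return NavigationResult(E_nav=e_nav, success=success)


def summarize_rows(
    matrix: np.ndarray,
    row_mask: np.ndarray,
    column_types: np.ndarray | None = None,
) -> dict:
    """Per-row means over out-of-mask columns, overall and per cortical type.

    ``row_mask`` is a boolean mask (e.g. DMN membership): rows inside the
    mask are summarised over columns *outside* it.  NaN entries (masked
    connectivity) are excluded from means; a type group with no finite entry
    for a row yields NaN for that row, never zero.

    Returns a dict with key ``"all"`` -> ``(n_rows,)`` vector and, if
    ``column_types`` is given, one key per type code present among the
    out-of-mask columns.
    """
    matrix = np.asarray(matrix, dtype=float)
    row_mask = np.asarray(row_mask, dtype=bool)
    rows = np.flatnonzero(row_mask)
    cols = np.flatnonzero(~row_mask)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("row mask and its complement must both be non-empty")
    block = matrix[np.ix_(rows, cols)]

    def nanmean_rows(b):
        valid = np.isfinite(b)
        out = np.full(b.shape[0], np.nan)
        any_valid = valid.any(axis=1)
        if np.any(any_valid):
            s = np.where(valid, b, 0.0).sum(axis=1)
            out[any_valid] = s[any_valid] / valid.sum(axis=1)[any_valid]
        return out

    result = {"all": nanmean_rows(block)}
    if column_types is not None:
        column_types = np.asarray(column_types)
        for t in np.unique(column_types[cols]):
            sub = block[:, column_types[cols] == t]
            result[t] = nanmean_rows(sub)
    return result
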