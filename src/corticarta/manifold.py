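"""Data-driven cytoarchitectural axis from profile affinity.

The masked region's vertex profiles are reduced to patches by mesh
decimation, a partial-correlation affinity is built between patch-average
profiles (controlling for the region-mean profile, negatives zeroed), and a
diffusion map embedding of the affinity yields the cytoarchitectural axis E1
plus higher components.  Density normalisation uses ``alpha = 0.5`` by
default; first components are expected to be near-identical across alpha
values and across embedding methods (diffusion maps, PCA, Laplacian
eigenmaps), which :func:`crossmethod_check` quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.decomposition import PCA

from .mesh import CorticalSheet, farthest_point_sample
from .profiles import ProfileMatrix

__all__ = [
    "PatchAssignment",
    "AffinityMatrix",
    "Embedding",
    "decimate_and_patch",
    "build_affinity",
    "diffusion_embed",
    "crossmethod_check",
    "profile_flatness",
]


@dataclass
class PatchAssignment:
    """Retained vertices and the patch each masked-in vertex belongs to."""

    retained: np.ndarray  # (P,) vertex ids of retained patch centres
    vertex_to_patch: np.ndarray  # (N,) patch index, -1 outside the mask
    mask: np.ndarray  # (N,) bool

    @property
    def n_patches(self) -> int:
        return self.retained.size


@dataclass
class AffinityMatrix:
    """Symmetric non-negative patch affinity with entries in [0, 1]."""

    values: np.ndarray  # (P, P)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("affinity must be symmetric")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("affinity entries must lie in [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("affinity must be finite")


@dataclass
class Embedding:
    """Diffusion-map components of the affinity; E1 is the first column."""

    components: np.ndarray  # (P, K)
    eigenvalues: np.ndarray  # (K,) sorted descending
    variance_fractions: np.ndarray  # (K,)
    sign_anchor: str = "none"

    @property
    def e1(self) -> np.ndarray:
        return self.components[:, 0]


def decimate_and_patch(
    mesh: CorticalSheet, mask: np.ndarray, factor: int = 6
) -> PatchAssignment:
    """Decimate the masked mesh and assign every vertex to a retained patch.

    ``ceil(|mask| / factor)`` vertices are retained by farthest-point
    sampling of the mesh-graph geodesics; each masked-in vertex is assigned
    to the retained vertex with the fewest hops on the mesh graph, ties
    broken by smallest Euclidean distance, remaining ties by lowest vertex
    id.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        m = np.zeros(mesh.n_vertices, dtype=bool)
        m[mask] = True
        mask = m
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    if factor < 1:
        raise ValueError("factor must be at least 1")
    if factor > idx.size:
        raise ValueError("decimation factor exceeds mask size")
    n_keep = int(np.ceil(idx.size / factor))
    g = mesh.graph()[np.ix_(idx, idx)]
    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise ValueError("mask is disconnected on the mesh")
    local_keep = farthest_point_sample(g, np.arange(idx.size), n_keep)
    retained = idx[local_keep]
    if factor == 1:
        order = np.argsort(retained)
        retained = retained[order]
        v2p = np.full(mesh.n_vertices, -1, dtype=int)
        v2p[retained] = np.arange(retained.size)
        return PatchAssignment(retained=retained, vertex_to_patch=v2p, mask=mask)

    g_unweighted = g.copy()
    g_unweighted.data[:] = 1.0
    hops = dijkstra(g_unweighted, indices=local_keep, directed=False)  # (P, |mask|)
    euc = np.linalg.norm(
        mesh.outer_vertices[idx][None, :, :] - mesh.outer_vertices[retained][:, None, :], axis=2
    )
    # lexicographic argmin over (hops, euclidean distance, retained vertex id)
    best = np.zeros(idx.size, dtype=int)
    key_hops = hops.T  # (|mask|, P)
    key_euc = euc.T
    for v in range(idx.size):
        cand = np.lexsort((retained, key_euc[v], key_hops[v]))
        best[v] = cand[0]
    v2p = np.full(mesh.n_vertices, -1, dtype=int)
    v2p[idx] = best
    return PatchAssignment(retained=retained, vertex_to_patch=v2p, mask=mask)


def patch_profiles(profiles: ProfileMatrix, patches: PatchAssignment) -> np.ndarray:
    """Profiles averaged within patches, shape (n_depths, P)."""
    out = np.zeros((profiles.n_depths, patches.n_patches))
    v2p = patches.vertex_to_patch
    for p in range(patches.n_patches):
        out[:, p] = profiles.intensities[:, v2p == p].mean(axis=1)
    return out


def profile_flatness(profile_matrix: np.ndarray) -> np.ndarray:
    """Negative depth-wise kurtosis per column: high = flat profile."""
    return -sps.kurtosis(profile_matrix, axis=0, fisher=True, bias=True)


def build_affinity(profiles: ProfileMatrix, patches: PatchAssignment) -> AffinityMatrix:
    """Partial-correlation affinity between patch-average profiles.

    Every pair of patch profiles is correlated (product–moment) after
    regressing out the mask-mean profile from each; negative partial
    correlations are zeroed to emphasise non-shared similarities, and the
    diagonal is set to 1.
    """
    if profiles.n_depths < 3:
        raise ValueError("need at least 3 depths")
    if patches.n_patches < 3:
        raise ValueError("need at least 3 patches")
    pp = patch_profiles(profiles, patches)  # (D, P)
    mean_profile = profiles.intensities[:, patches.mask].mean(axis=1)
    design = np.column_stack([np.ones_like(mean_profile), mean_profile])
    beta, *_ = np.linalg.lstsq(design, pp, rcond=None)
    resid = pp - design @ beta
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"patch {int(dead[0])} has zero residual variance after removing the mean profile"
        )
    z = (resid - resid.mean(axis=0)) / sd
    corr = (z.T @ z) / z.shape[0]
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    aff = np.where(corr < 0, 0.0, corr)
    aff = 0.5 * (aff + aff.T)
    return AffinityMatrix(values=aff)


def diffusion_embed(
    affinity: AffinityMatrix,
    alpha: float = 0.5,
    n_components: int = 10,
    sign_anchor: np.ndarray | None = None,
) -> Embedding:
    """Diffusion map embedding of a symmetric non-negative affinity.

    The affinity is density-normalised (``W' = D^-alpha W D^-alpha``),
    row-normalised to a Markov transition matrix, and eigendecomposed; the
    trivial constant eigenvector is dropped and the remaining components are
    scaled by ``lambda / (1 - lambda)`` (diffusion-time aggregated).
    Variance fractions are each eigenvalue's share of the retained spectrum.
    If ``sign_anchor`` is given (e.g. per-patch profile flatness), E1's sign
    is fixed so that it correlates positively with the anchor.
    """
    w = affinity.values.copy()
    deg = w.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("affinity has zero-degree rows")
    n_comp, labels = connected_components((w > 0).astype(float), directed=False)
    if n_comp != 1:
        sizes = np.bincount(labels)
        raise ValueError(f"affinity graph is disconnected (component sizes {sizes.tolist()})")
    d_alpha = deg**-alpha
    w_norm = w * d_alpha[:, None] * d_alpha[None, :]
    d2 = w_norm.sum(axis=1)
    # symmetric conjugate of the row-normalised transition matrix
    s = w_norm * (d2**-0.5)[:, None] * (d2**-0.5)[None, :]
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = (d2**-0.5)[:, None] * evecs
    psi = psi / psi[:, [0]]  # normalise against the trivial constant eigenvector
    k = min(n_components, evals.size - 1)
    lam = evals[1 : k + 1]
    comps = psi[:, 1 : k + 1] * (lam / (1.0 - lam))[None, :]
    var_frac = lam / lam.sum()
    anchor_mode = "none"
    if sign_anchor is not None:
        r = np.corrcoef(comps[:, 0], np.asarray(sign_anchor, dtype=float))[0, 1]
        if r < 0:
            comps[:, 0] = -comps[:, 0]
        anchor_mode = "profile-flatness"
    else:
        if comps[np.argmax(np.abs(comps[:, 0])), 0] < 0:
            comps[:, 0] = -comps[:, 0]
        anchor_mode = "largest-loading-positive"
    return Embedding(
        components=comps,
        eigenvalues=lam,
        variance_fractions=var_frac,
        sign_anchor=anchor_mode,
    )


def _laplacian_eigenmap_first(w: np.ndarray) -> np.ndarray:
    deg = w.sum(axis=1)
    d_half = deg**-0.5
    s = w * d_half[:, None] * d_half[None, :]
    evals, evecs = np.linalg.eigh(0.5 * (s + s.T))
    order = np.argsort(evals)[::-1]
    psi = d_half[:, None] * evecs[:, order]
    return psi[:, 1]


def crossmethod_check(affinity: AffinityMatrix) -> pd.DataFrame:
    """First-component agreement across diffusion maps, PCA and Laplacian
    eigenmaps, as a symmetric table of absolute pairwise correlations."""
    emb = diffusion_embed(affinity, alpha=0.5, n_components=2)
    first = {
        "diffusion": emb.e1,
        "pca": PCA(n_components=1).fit_transform(affinity.values).ravel(),
        "laplacian": _laplacian_eigenmap_first(affinity.values),
    }
    names = list(first)
    table = np.eye(len(names))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                r = abs(np.corrcoef(first[a], first[b])[0, 1])
                table[i, j] = table[j, i] = r
    return pd.DataFrame(table, index=names, columns=names)
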