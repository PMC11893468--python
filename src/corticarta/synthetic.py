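"""Synthetic cortical sheets, atlases, profiles, connectomes and BOLD dynamics.

Every generator in this module is a pure function of its arguments, including
the seed: calling it twice with identical inputs produces bitwise-identical
output.  The generators provide all inputs that the analysis pipeline
consumes — folded two-hemisphere cortical sheets with matched inner/outer
surfaces, contiguous parcellations with six cortical types and seven
functional networks, depth-wise staining-intensity profiles ranging from
peaked (mid–deep density maximum) to flat, distance-decaying weighted
connectomes, and stable linear dynamics observed through a haemodynamic
response — together with the ground truth needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.cluster import KMeans

from .effective import TimeseriesMatrix, canonical_hrf
from .landscape import Landscape
from .mesh import CorticalSheet, edge_graph, farthest_point_sample
from .navigation import Connectome
from .profiles import ProfileMatrix

__all__ = [
    "CORTICAL_TYPES",
    "NETWORK_NAMES",
    "DMN_LABEL",
    "Parcellation",
    "TypeAtlas",
    "NetworkAtlas",
    "GroundTruth",
    "generate_sheet",
    "generate_atlases",
    "generate_profiles",
    "generate_landscape",
    "generate_connectome",
    "generate_dcm_timeseries",
    "smooth_vertex_field",
    "peakedness_field",
    "hemisphere_submesh",
]

#: Six levels of laminar differentiation, ordered from most to least granular.
CORTICAL_TYPES = (
    "koniocortical",
    "eulaminate-III",
    "eulaminate-II",
    "eulaminate-I",
    "dysgranular",
    "agranular",
)

#: Seven-network scheme; the default mode network label comes last.
DMN_LABEL = "default"
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    DMN_LABEL,
)

_ICO_COUNTS = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562, 5: 10242}


@dataclass
class Parcellation:
    """Assignment of vertices to spatially contiguous parcels."""

    vertex_to_parcel: np.ndarray  # (N,) parcel id, -1 = masked
    parcel_centroids: np.ndarray  # (P, 3) mm
    parcel_hemisphere: np.ndarray  # (P,) "L"/"R"

    @property
    def n_parcels(self) -> int:
        return self.parcel_centroids.shape[0]


@dataclass
class TypeAtlas:
    """Cortical-type labels (laminar differentiation) per vertex and parcel."""

    vertex_types: np.ndarray  # (N,) int code into CORTICAL_TYPES, -1 = masked
    parcel_types: np.ndarray  # (P,) int code

    def vertex_names(self) -> np.ndarray:
        out = np.full(self.vertex_types.shape, "masked", dtype=object)
        ok = self.vertex_types >= 0
        out[ok] = np.asarray(CORTICAL_TYPES, dtype=object)[self.vertex_types[ok]]
        return out


@dataclass
class NetworkAtlas:
    """Functional-network labels; exactly one label is the DMN."""

    vertex_networks: np.ndarray  # (N,) str
    parcel_networks: np.ndarray  # (P,) str
    dmn_label: str = DMN_LABEL
    dmn_subregion: np.ndarray | None = None  # (P,) int, -1 outside the DMN

    def dmn_parcels(self) -> np.ndarray:
        return np.flatnonzero(self.parcel_networks == self.dmn_label)

    def dmn_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.vertex_networks == self.dmn_label)


@dataclass
class GroundTruth:
    """Generative parameters recorded alongside each synthetic dataset."""

    peakedness: np.ndarray | None = None
    A_true: np.ndarray | None = None
    decay_length: float | None = None
    seeds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(x):
            return None if x is None else np.asarray(x).tolist()

        return json.dumps(
            {
                "peakedness": enc(self.peakedness),
                "A_true": enc(self.A_true),
                "decay_length": self.decay_length,
                "seeds": self.seeds,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)

        def dec(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            peakedness=dec(d["peakedness"]),
            A_true=dec(d["A_true"]),
            decay_length=d["decay_length"],
            seeds=dict(d["seeds"]),
        )


def _smooth_sphere_field(unit: np.ndarray, rng: np.random.Generator, n_waves: int = 4) -> np.ndarray:
    """Smooth zero-mean field on unit-sphere points from random plane waves."""
    out = np.zeros(unit.shape[0])
    for _ in range(n_waves):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        k = rng.uniform(2.0, 5.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += rng.uniform(0.5, 1.0) * np.sin(k * unit @ direction + phase)
    return out


def smooth_vertex_field(sheet: CorticalSheet, seed: int, n_waves: int = 4) -> np.ndarray:
    """Smooth per-vertex field in [0, 1], e.g. a peakedness map.

    The field is homotopically mirror-symmetric: the right hemisphere is
    evaluated on left-equivalent coordinates, so homotopic vertices share
    values, as large-scale microstructural gradients do.
    """
    rng = np.random.default_rng(seed)
    coords = sheet.sphere_coordinates.copy()
    coords[sheet.hemisphere == "R", 0] *= -1.0  # map onto the left sphere
    f = _smooth_sphere_field(coords, rng, n_waves=n_waves)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full_like(f, 0.5)


def generate_sheet(
    n_vertices: int = 162,
    folding_amplitude: float = 2.0,
    thickness_range: tuple[float, float] = (1.5, 3.5),
    seed: int = 0,
    radius: float = 60.0,
) -> CorticalSheet:
    """Two-hemisphere folded cortical sheet on subdivided icosahedral spheres.

    ``n_vertices`` is the minimum vertex count per hemisphere; the smallest
    icosphere subdivision meeting it is used (12, 42, 162, 642, ...).  The
    outer surface folds radially with smooth sinusoidal displacement of peak
    amplitude ``folding_amplitude`` (mm); the inner surface is displaced
    inward by a spatially smooth thickness field constrained to
    ``thickness_range`` (mm).  The right hemisphere mirrors the left.
    """
    tmin, tmax = thickness_range
    if tmin <= 0 or tmax < tmin:
        raise ValueError("thickness_range must be positive with min <= max")
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices per hemisphere")
    if folding_amplitude < 0:
        raise ValueError("folding_amplitude must be non-negative")
    subdiv = min(s for s, c in _ICO_COUNTS.items() if c >= n_vertices)
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=int)
    nh = unit.shape[0]

    rng = np.random.default_rng(seed)
    fold = _smooth_sphere_field(unit, rng)
    peak = np.abs(fold).max()
    if peak > 0:
        fold = fold / peak
    thick_raw = _smooth_sphere_field(unit, rng)
    lo, hi = thick_raw.min(), thick_raw.max()
    tnorm = (thick_raw - lo) / (hi - lo) if hi > lo else np.full(nh, 0.5)
    thickness = tmin + (tmax - tmin) * tnorm

    centers = {"L": np.array([-(radius + 2.0), 0.0, 0.0]), "R": np.array([radius + 2.0, 0.0, 0.0])}
    mirror = np.array([-1.0, 1.0, 1.0])

    outer, inner, sphere, hemi, all_faces = [], [], [], [], []
    for i, label in enumerate(("L", "R")):
        u = unit if label == "L" else unit * mirror
        r_out = radius + folding_amplitude * fold
        outer.append(centers[label] + r_out[:, None] * u)
        inner.append(centers[label] + (r_out - thickness)[:, None] * u)
        sphere.append(u)
        hemi.append(np.full(nh, label))
        f = faces if label == "L" else faces[:, ::-1]
        all_faces.append(f + i * nh)

    return CorticalSheet(
        outer_vertices=np.vstack(outer),
        inner_vertices=np.vstack(inner),
        faces=np.vstack(all_faces),
        sphere_coordinates=np.vstack(sphere),
        hemisphere=np.concatenate(hemi),
        hemisphere_centers=centers,
    )


def hemisphere_submesh(sheet: CorticalSheet, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Vertex indices and re-indexed faces of one hemisphere."""
    idx = np.flatnonzero(sheet.hemisphere == label)
    pos = np.full(sheet.n_vertices, -1, dtype=int)
    pos[idx] = np.arange(idx.size)
    in_hemi = np.all(np.isin(sheet.faces, idx), axis=1)
    return idx, pos[sheet.faces[in_hemi]]


def _repair_parcel_connectivity(
    assignment: np.ndarray, graph: sparse.csr_matrix, max_iter: int = 30
) -> np.ndarray:
    """Reassign minority components so every parcel is mesh-connected."""
    assignment = assignment.copy()
    coo = graph.tocoo()
    for _ in range(max_iter):
        changed = False
        for pid in np.unique(assignment):
            members = np.flatnonzero(assignment == pid)
            sub = graph[np.ix_(members, members)]
            n_comp, comp = connected_components(sub, directed=False)
            if n_comp == 1:
                continue
            sizes = np.bincount(comp)
            keep = np.argmax(sizes)
            for c in range(n_comp):
                if c == keep:
                    continue
                stray = members[comp == c]
                # adopt the neighbouring parcel with the most contacts
                mask = np.isin(coo.row, stray) & ~np.isin(coo.col, stray)
                neigh = assignment[coo.col[mask]]
                if neigh.size:
                    vals, counts = np.unique(neigh, return_counts=True)
                    assignment[stray] = vals[np.argmax(counts)]
                    changed = True
        if not changed:
            return assignment
    return assignment


def generate_atlases(
    sheet: CorticalSheet,
    n_parcels: int = 40,
    dmn_fraction: float = 0.3,
    seed: int = 0,
    type_noise_sd: float = 0.05,
    n_dmn_subregions: int = 4,
) -> tuple[Parcellation, TypeAtlas, NetworkAtlas]:
    """Contiguous parcels, cortical types and a 7-network atlas with a DMN.

    Parcels come from farthest-point sampling plus geodesic nearest-seed
    assignment per hemisphere.  Types follow a smooth geodesic gradient from a
    "sensory pole" (koniocortical) to its antipode (agranular), with additive
    smooth noise of amplitude ``type_noise_sd``.  The DMN is grown from
    ``n_dmn_subregions`` anchor parcels per hemisphere placed at spread-out
    positions along the type gradient, so that under default settings it is
    distributed and overlaps at least five of the six cortical types.
    """
    if not (0.0 < dmn_fraction < 1.0):
        raise ValueError("dmn_fraction must lie in (0, 1)")
    if n_parcels < 14:
        raise ValueError("need at least 14 parcels (7 per hemisphere)")

    rng = np.random.default_rng(seed)
    n = sheet.n_vertices
    vertex_to_parcel = np.full(n, -1, dtype=int)
    vertex_types = np.full(n, -1, dtype=int)
    gradient = np.zeros(n)
    parcel_centroids, parcel_hemi = [], []
    next_pid = 0
    per_hemi = {"L": n_parcels // 2, "R": n_parcels - n_parcels // 2}

    for label in ("L", "R"):
        idx, faces = hemisphere_submesh(sheet, label)
        verts = sheet.outer_vertices[idx]
        g = edge_graph(verts, faces)
        # sensory pole: topmost vertex on the hemisphere sphere
        pole = int(np.argmax(sheet.sphere_coordinates[idx, 2]))
        geo = dijkstra(g, indices=pole, directed=False)
        gn = geo / geo.max()
        noise = _smooth_sphere_field(sheet.sphere_coordinates[idx], rng) * type_noise_sd
        gn = np.clip(gn + noise, 0.0, 1.0)
        gradient[idx] = gn
        vertex_types[idx] = np.minimum((gn * 6).astype(int), 5)

        k = per_hemi[label]
        seeds = farthest_point_sample(g, np.arange(idx.size), k, start=pole)
        dist = dijkstra(g, indices=seeds, directed=False)
        local = np.argmin(dist, axis=0)
        local = _repair_parcel_connectivity(local, g)
        # compact parcel ids in seed order
        uniq = np.unique(local)
        remap = {u: next_pid + j for j, u in enumerate(uniq)}
        vertex_to_parcel[idx] = np.vectorize(remap.get)(local)
        for u in uniq:
            parcel_centroids.append(verts[local == u].mean(axis=0))
            parcel_hemi.append(label)
        next_pid += uniq.size

    parcellation = Parcellation(
        vertex_to_parcel=vertex_to_parcel,
        parcel_centroids=np.asarray(parcel_centroids),
        parcel_hemisphere=np.asarray(parcel_hemi),
    )
    p_total = parcellation.n_parcels

    # modal type per parcel (lowest code wins ties)
    parcel_types = np.zeros(p_total, dtype=int)
    parcel_gradient = np.zeros(p_total)
    for pid in range(p_total):
        members = vertex_to_parcel == pid
        counts = np.bincount(vertex_types[members], minlength=6)
        parcel_types[pid] = int(np.argmax(counts))
        parcel_gradient[pid] = gradient[members].mean()

    # parcel adjacency from mesh edges
    g_full = sheet.graph()
    coo = g_full.tocoo()
    pa, pb = vertex_to_parcel[coo.row], vertex_to_parcel[coo.col]
    cross = pa != pb
    adj = sparse.coo_matrix(
        (np.ones(cross.sum()), (pa[cross], pb[cross])), shape=(p_total, p_total)
    ).tocsr()
    adj.data[:] = 1.0

    parcel_networks = np.full(p_total, "", dtype=object)
    dmn_subregion = np.full(p_total, -1, dtype=int)
    sub_id = 0
    for label in ("L", "R"):
        hemi_pids = np.flatnonzero(parcellation.parcel_hemisphere == label)
        order = np.argsort(parcel_gradient[hemi_pids])
        targets = np.linspace(0.1, 0.9, n_dmn_subregions)
        anchors = []
        for t in targets:
            # closest-by-gradient parcel, preferring non-adjacency to anchors
            cand = hemi_pids[order]
            scores = np.abs(parcel_gradient[cand] - t)
            ranked = [c for c in cand[np.argsort(scores)] if dmn_subregion[c] < 0]
            pick = next(
                (c for c in ranked if all(adj[c, a] == 0 for a in anchors)),
                ranked[0] if ranked else None,
            )
            if pick is not None:
                anchors.append(int(pick))
        for a in anchors:
            dmn_subregion[a] = sub_id
            parcel_networks[a] = DMN_LABEL
            sub_id += 1
        # grow subregions round-robin, keeping them disjoint
        target_size = max(len(anchors), int(round(dmn_fraction * hemi_pids.size)))
        n_assigned = len(anchors)
        growing = True
        while n_assigned < target_size and growing:
            growing = False
            for a_sub in range(sub_id - len(anchors), sub_id):
                members = np.flatnonzero(dmn_subregion == a_sub)
                neigh = np.unique(adj[members].tocoo().col)
                other_dmn = np.flatnonzero((dmn_subregion >= 0) & (dmn_subregion != a_sub))
                ok = [
                    c
                    for c in neigh
                    if parcel_networks[c] == ""
                    and parcellation.parcel_hemisphere[c] == label
                    and not adj[c, other_dmn].nnz
                ]
                if ok:
                    c = min(ok)
                    dmn_subregion[c] = a_sub
                    parcel_networks[c] = DMN_LABEL
                    n_assigned += 1
                    growing = True
                if n_assigned >= target_size:
                    break

    # remaining parcels -> six non-DMN networks, mirror-symmetric clustering
    rest = np.flatnonzero(parcel_networks == "")
    sym = parcellation.parcel_centroids[rest].copy()
    sym[:, 0] = np.abs(sym[:, 0])
    km = KMeans(n_clusters=6, n_init=4, random_state=int(seed) % (2**31)).fit(sym)
    for j, pid in enumerate(rest):
        parcel_networks[pid] = NETWORK_NAMES[km.labels_[j]]

    vertex_networks = parcel_networks[vertex_to_parcel]
    atlas_t = TypeAtlas(vertex_types=vertex_types, parcel_types=parcel_types)
    atlas_n = NetworkAtlas(
        vertex_networks=np.asarray(vertex_networks, dtype=object),
        parcel_networks=parcel_networks,
        dmn_label=DMN_LABEL,
        dmn_subregion=dmn_subregion,
    )
    return parcellation, atlas_t, atlas_n


def peakedness_field(sheet: CorticalSheet, seed: int, contrast: float = 6.0) -> np.ndarray:
    """Smooth, bimodally distributed per-vertex peakedness field in [0, 1].

    A smooth random field is rank-uniformised and passed through a logistic
    of gain ``contrast``, concentrating values near 0 and 1 with a thin
    transition zone — emulating the strongly bimodal distribution of laminar
    differentiation across the cortex (well-laminated granular territories
    versus agranular ones, separated by narrow dysgranular strips).
    """
    from scipy.stats import rankdata

    f = smooth_vertex_field(sheet, seed)
    u = rankdata(f) / (f.size + 1)
    p = 1.0 / (1.0 + np.exp(-contrast * (u - 0.5)))
    return (p - p.min()) / (p.max() - p.min())


def generate_profiles(
    sheet: CorticalSheet,
    peakedness: np.ndarray,
    n_depths: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ProfileMatrix, GroundTruth]:
    """Depth-wise intensity profiles from a per-vertex peakedness field.

    Each profile is a unit baseline plus a Gaussian density bump in the
    mid–deep cortical band: centre ``0.55 + 0.2 p`` (depth fraction from the
    pial surface), width ``0.12 - 0.04 p``, amplitude ``min(1, p / 0.2)``.
    Peakedness therefore controls the *shape* of the profile — the bump
    sharpens and moves deeper as laminar differentiation grows — while the
    staining dynamic range saturates quickly, as in contrast-normalised
    staining data; ``p = 0`` gives an exactly flat profile.  Depth index 0
    is pial, the last index the white-matter boundary.
    """
    peakedness = np.asarray(peakedness, dtype=float)
    if peakedness.shape != (sheet.n_vertices,):
        raise ValueError("peakedness must be one value per vertex")
    if np.any((peakedness < 0) | (peakedness > 1)):
        raise ValueError("peakedness must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_depths < 3:
        raise ValueError("need at least 3 depths")
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, 1.0, n_depths)[:, None]
    amplitude = np.minimum(1.0, peakedness[None, :] / 0.2)
    mu = 0.55 + 0.2 * peakedness[None, :]
    sigma = 0.12 - 0.04 * peakedness[None, :]
    bump = np.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
    intensities = 1.0 + amplitude * bump
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=intensities.shape)
    gt = GroundTruth(peakedness=peakedness.copy(), seeds={"profiles": int(seed)})
    return ProfileMatrix(intensities=intensities), gt


def generate_landscape(
    grid_size: int = 32,
    kind: str = "gradient",
    frequency: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Landscape:
    """Scalar field on a 2D grid: planar ramp, interdigitated sinusoid or noise.

    The interdigitated field is ``cos(2*pi*frequency*x)`` sampled at cell
    centres, giving exactly ``2*frequency`` strict sign changes along every
    grid row.  Edges connect 4-neighbours.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be at least 8")
    if kind not in ("gradient", "interdigitated", "noise"):
        raise ValueError(f"unknown landscape kind: {kind!r}")
    rng = np.random.default_rng(seed)
    x = (np.arange(grid_size) + 0.5) / grid_size
    xx, yy = np.meshgrid(x, x, indexing="xy")
    if kind == "gradient":
        f = xx.copy()
    elif kind == "interdigitated":
        f = np.cos(2.0 * np.pi * frequency * xx)
    else:
        f = rng.normal(size=xx.shape)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)

    coords = np.column_stack([xx.ravel(), yy.ravel()])
    idx = np.arange(grid_size * grid_size).reshape(grid_size, grid_size)
    right = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    down = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    edges = np.vstack([right, down])
    return Landscape(coords2d=coords, values=f.ravel(), edges=edges)


def generate_connectome(
    parcellation: Parcellation,
    decay_length: float = 30.0,
    density: float = 0.35,
    seed: int = 0,
    type_atlas: TypeAtlas | None = None,
    network_atlas: NetworkAtlas | None = None,
    e1: np.ndarray | None = None,
    weight_noise_sd: float = 0.5,
) -> tuple[Connectome, GroundTruth]:
    """Symmetric distance-decaying weighted connectome on parcel centroids.

    Edge probability and weight both decay as ``exp(-d/decay_length)``;
    weights carry multiplicative lognormal noise.  Edges are resampled (with
    derived seeds) until each hemisphere's subgraph is connected.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    coords = parcellation.parcel_centroids
    hemi = parcellation.parcel_hemisphere
    p = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    decay = np.exp(-d / decay_length)
    off = ~np.eye(p, dtype=bool)
    scale = density / decay[off].mean()
    prob = np.clip(scale * decay, 0.0, 1.0)

    iu = np.triu_indices(p, k=1)
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        exist = rng.random(iu[0].size) < prob[iu]
        noise = rng.lognormal(0.0, weight_noise_sd, size=iu[0].size)
        w_up = np.where(exist, decay[iu] * noise, 0.0)
        W = np.zeros((p, p))
        W[iu] = w_up
        W = W + W.T
        ok = True
        for label in ("L", "R"):
            sub = np.flatnonzero(hemi == label)
            n_comp, _ = connected_components(sparse.csr_matrix(W[np.ix_(sub, sub)] > 0), directed=False)
            if n_comp != 1:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not generate a connectome with connected hemispheres")

    conn = Connectome(
        W=W,
        coords=coords,
        hemisphere=hemi,
        network=None if network_atlas is None else network_atlas.parcel_networks,
        cortical_type=None if type_atlas is None else type_atlas.parcel_types,
        e1=e1,
    )
    gt = GroundTruth(decay_length=float(decay_length), seeds={"connectome": int(seed)})
    return conn, gt


def generate_dcm_timeseries(
    A_true: np.ndarray,
    duration: float = 600.0,
    TR: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    process_noise_sd: float = 1.0,
    x0: np.ndarray | None = None,
) -> tuple[TimeseriesMatrix, GroundTruth]:
    """BOLD-like timeseries from stable linear dynamics through an HRF.

    Integrates ``dx/dt = A x + w`` (white process noise, no external driver)
    with fixed-step Euler at ``dt = TR/16``, convolves with the canonical
    double-gamma haemodynamic response, samples at ``TR`` and adds Gaussian
    observation noise of standard deviation ``noise_sd``.
    """
    A = np.asarray(A_true, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A_true must be square")
    if TR <= 0:
        raise ValueError("TR must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise ValueError(
            "A_true is unstable: all eigenvalues must have negative real part "
            f"(max real part {eig.real.max():.4f})"
        )
    r = A.shape[0]
    sub = 16
    dt = TR / sub
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros(r) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = np.empty((n_steps, r))
    sqdt = np.sqrt(dt)
    for t in range(n_steps):
        w = rng.normal(0.0, process_noise_sd, size=r) if process_noise_sd > 0 else 0.0
        x = x + dt * (A @ x) + sqdt * w
        states[t] = x
    hrf = canonical_hrf(dt)
    bold = np.empty_like(states)
    for j in range(r):
        bold[:, j] = np.convolve(states[:, j], hrf)[:n_steps]
    y = bold[sub - 1 :: sub]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    gt = GroundTruth(A_true=A.copy(), seeds={"dcm": int(seed)})
    return TimeseriesMatrix(values=y, TR=float(TR)), gt
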