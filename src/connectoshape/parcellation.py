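"""Spherical parcellation geometry.

A parcellation places N cortical parcels (N/2 per hemisphere) on the unit
sphere, assigns each a functional-system label and a laminar-differentiation
label, and records which parcels share a border (the spatial-adjacency
relation used by the spin test and by the "excluded" confound variant).

Generated parcellations use a Fibonacci lattice per hemisphere: deterministic,
quasi-uniform coverage of each half-sphere, with the left hemisphere the
x-mirror of the right.  Spatial adjacency comes from a per-hemisphere Delaunay
triangulation of the centroids, a computational proxy for shared parcel
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass
class Parcellation:
    """Node geometry and labels for one parcellation resolution.

    Attributes
    ----------
    centroids : (N, 3) float array
        Unit-norm parcel centroids; left hemisphere has x < 0.
    hemisphere : (N,) array of "L"/"R"
    system : (N,) int array, labels 1..K (functional communities)
    laminar : (N,) int array, labels 1..4 (laminar differentiation classes)
    spatial_adjacency : (N, N) bool array, symmetric, zero diagonal
    """

    centroids: np.ndarray
    hemisphere: np.ndarray
    system: np.ndarray
    laminar: np.ndarray
    spatial_adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.centroids.shape[0]

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must be unit-norm")
        adj = self.spatial_adjacency
        if not (adj == adj.T).all() or adj.diagonal().any():
            raise ValueError("spatial_adjacency must be symmetric with zero diagonal")
        if (adj.sum(axis=1) == 0).any():
            raise ValueError("every node needs at least one spatial neighbor")

    def spatial_neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.spatial_adjacency[i])


def _fibonacci_half_sphere(n: int, phase: float) -> np.ndarray:
    """Quasi-uniform points on the hemisphere x > 0.

    ``x`` plays the role of the area-uniform coordinate; the azimuth follows
    the golden-angle spiral, rotated by ``phase`` so distinct seeds give
    distinct (but equally uniform) lattices.
    """
    i = np.arange(n)
    x = (i + 0.5) / n
    theta = 2.0 * np.pi * (i / GOLDEN_RATIO + phase)
    r = np.sqrt(1.0 - x**2)
    return np.column_stack([x, r * np.cos(theta), r * np.sin(theta)])


def _hemisphere_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay adjacency of half-sphere points via their (y, z) projection.

    The hemisphere x > 0 is a graph over the unit disk in (y, z), so a planar
    Delaunay triangulation of the projection is well defined.
    """
    tri = Delaunay(points[:, 1:3])
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def _farthest_point_seeds(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    start = int(rng.integers(points.shape[0]))
    seeds = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(seeds)


def _nearest_seed_labels(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - points[seeds][None, :, :], axis=2)
    return np.argmin(d, axis=1) + 1


def _repair_label_connectivity(labels: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Reassign minority components so every label is adjacency-connected.

    Nearest-seed partitions are almost always connected already; when a label
    splinters, nodes of every non-largest component move to the most common
    neighboring label, iterating until stable.
    """
    labels = labels.copy()
    n = labels.size
    for _ in range(n):
        moved = False
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            comps = _components(members, adjacency)
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for comp in comps[1:]:
                for node in comp:
                    neigh_labels = labels[np.flatnonzero(adjacency[node])]
                    neigh_labels = neigh_labels[neigh_labels != lab]
                    if neigh_labels.size:
                        vals, counts = np.unique(neigh_labels, return_counts=True)
                        labels[node] = vals[np.argmax(counts)]
                        moved = True
        if not moved:
            return labels
    return labels


def _components(members: np.ndarray, adjacency: np.ndarray) -> list[list[int]]:
    member_set = set(int(m) for m in members)
    seen: set[int] = set()
    comps = []
    for m in members:
        m = int(m)
        if m in seen:
            continue
        stack, comp = [m], []
        seen.add(m)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adjacency[u]):
                v = int(v)
                if v in member_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def gen_parcellation(n_nodes: int, n_systems: int = 7, seed: int = 0) -> Parcellation:
    """Generate a bilateral spherical parcellation.

    Parameters
    ----------
    n_nodes : even integer >= 20; split equally between hemispheres.
    n_systems : number of functional-system labels (contiguous patches).
    seed : RNG seed controlling the lattice phase and label seeds.
    """
    if n_nodes % 2 != 0 or n_nodes < 20:
        raise ValueError("n_nodes must be an even integer >= 20")
    if n_systems < 2:
        raise ValueError("n_systems must be >= 2")
    if n_systems > n_nodes // 2:
        raise ValueError("n_systems may not exceed nodes per hemisphere")

    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    right = _fibonacci_half_sphere(half, phase=float(rng.uniform()))
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half)

    adjacency = np.zeros((n_nodes, n_nodes), dtype=bool)
    for offset, pts in ((0, left), (half, right)):
        for i, j in _hemisphere_delaunay_edges(pts):
            adjacency[offset + i, offset + j] = True
            adjacency[offset + j, offset + i] = True

    # Bilaterally symmetric labels: partition the right hemisphere by nearest
    # farthest-point seed, mirror onto the left, then repair connectivity
    # per hemisphere.
    sys_seeds = _farthest_point_seeds(right, n_systems, rng)
    sys_right = _nearest_seed_labels(right, sys_seeds)
    lam_seeds = _farthest_point_seeds(right, 4, rng)
    lam_right = _nearest_seed_labels(right, lam_seeds)

    system = np.concatenate([sys_right, sys_right])
    laminar = np.concatenate([lam_right, lam_right])
    for lo, hi in ((0, half), (half, n_nodes)):
        sub = adjacency[lo:hi, lo:hi]
        system[lo:hi] = _repair_label_connectivity(system[lo:hi], sub)
        laminar[lo:hi] = _repair_label_connectivity(laminar[lo:hi], sub)

    return Parcellation(
        centroids=centroids,
        hemisphere=hemisphere,
        system=system.astype(int),
        laminar=laminar.astype(int),
        spatial_adjacency=adjacency,
    )


def euclidean_distance_matrix(parcellation: Parcellation) -> np.ndarray:
    """Pairwise Euclidean centroid distances (symmetric, zero diagonal)."""
    c = parcellation.centroids
    diff = c[:, None, :] - c[None, :, :]
    return np.linalg.norm(diff, axis=2)
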