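"""Surrogate null families: spherical spins, degree-preserving rewires,
gene resamples, and the shared empirical p-value helper.

The spin test preserves the spatial autocorrelation of a brain map by rigidly
rotating parcel centroids on the sphere and reassigning each parcel the value
of its nearest rotated neighbor (same hemisphere; the right hemisphere gets
the x-mirrored rotation so bilateral symmetry is respected).  The rewired
test preserves the degree sequence and the approximate edge-length
distribution of the network by double-edge swaps confined to equal-frequency
Euclidean-length bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import special_ortho_group

from .connectome import Connectome
from .parcellation import Parcellation

_X_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass
class SurrogateEnsemble:
    kind: str  # {"spin_maps", "rewired_networks", "gene_resamples"}
    items: list
    seed: int | None
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def empirical_p(
    observed: float,
    null_values: np.ndarray,
    side: str = "greater",
    literal_fraction: bool = False,
) -> float:
    """One-sided permutation p-value against an empirical null.

    Default is the guarded (k + 1) / (n + 1) convention, which never returns
    zero; ``literal_fraction`` gives the plain fraction of nulls at or beyond
    the observed value.
    """
    nulls = np.asarray(null_values, dtype=float)
    if side == "greater":
        k = int((nulls >= observed).sum())
    elif side == "less":
        k = int((nulls <= observed).sum())
    else:
        raise ValueError("side must be 'greater' or 'less'")
    n = nulls.size
    if literal_fraction:
        return k / n
    return (k + 1) / (n + 1)


def spin_map(
    values: np.ndarray, parcellation: Parcellation, rotation: np.ndarray
) -> np.ndarray:
    """Apply one rotation: each parcel takes the value of the nearest rotated
    parcel in its own hemisphere (duplicates permitted)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for hemi, rot in (("L", rotation), ("R", _X_MIRROR @ rotation @ _X_MIRROR)):
        idx = np.flatnonzero(parcellation.hemisphere == hemi)
        cents = parcellation.centroids[idx]
        rotated = cents @ rot.T
        d = np.linalg.norm(cents[:, None, :] - rotated[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        out[idx] = values[idx[nearest]]
    return out


def spin_surrogates(
    values: np.ndarray,
    parcellation: Parcellation,
    n: int = 1000,
    seed: int | None = None,
    rotations: list[np.ndarray] | None = None,
) -> SurrogateEnsemble:
    """Spin-test surrogate maps from n uniform random sphere rotations.

    ``rotations`` overrides the random draw (e.g. a forced identity rotation
    returns the original map), which also makes the scheme auditable.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != parcellation.n_nodes:
        raise ValueError("map length must equal the parcellation size")
    rng = np.random.default_rng(seed)
    if rotations is None:
        rotations = [special_ortho_group.rvs(3, random_state=rng) for _ in range(n)]
    items = [spin_map(values, parcellation, rot) for rot in rotations]
    return SurrogateEnsemble(
        kind="spin_maps",
        items=items,
        seed=seed,
        parameters={"n": len(items), "rotation_scheme": "mirrored-per-hemisphere"},
    )


def _length_bins(lengths: np.ndarray, n_bins: int) -> list[np.ndarray]:
    order = np.argsort(lengths, kind="stable")
    n_bins = min(n_bins, max(1, order.size))
    return [g for g in np.array_split(order, n_bins) if g.size]


def _rewire_once(
    connectome: Connectome, n_bins: int, n_swap_factor: float, rng: np.random.Generator
) -> np.ndarray:
    edges = connectome.edge_list()
    lengths = connectome.distances[edges[:, 0], edges[:, 1]]
    adj = connectome.adjacency.astype(bool).copy()
    for bin_idx in _length_bins(lengths, n_bins):
        if bin_idx.size < 2:
            warnings.warn("length bin with < 2 edges left unswapped", stacklevel=3)
            continue
        lo, hi = lengths[bin_idx].min(), lengths[bin_idx].max()
        bin_edges = edges[bin_idx].copy()
        n_attempts = int(n_swap_factor * bin_idx.size)
        picks = rng.integers(bin_idx.size, size=(n_attempts, 2))
        flips = rng.integers(2, size=n_attempts)
        for (e1, e2), flip in zip(picks, flips):
            if e1 == e2:
                continue
            a, b = bin_edges[e1]
            c, d = bin_edges[e2]
            if flip:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            l1 = connectome.distances[a, d]
            l2 = connectome.distances[c, b]
            if not (lo <= l1 <= hi and lo <= l2 <= hi):
                continue  # would leave the length bin
            adj[a, b] = adj[b, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b] = adj[b, c] = True
            bin_edges[e1] = (a, d)
            bin_edges[e2] = (c, b)
    return adj.astype(np.int8)


def rewired_surrogates(
    connectome: Connectome,
    n_bins: int = 10,
    n: int = 1000,
    n_swap_factor: float = 10.0,
    seed: int | None = None,
    ensure_connected: bool = False,
    max_retries: int = 50,
) -> SurrogateEnsemble:
    """Degree-preserving, length-bin-constrained rewired surrogate networks.

    Each surrogate keeps the exact degree sequence and exact per-bin edge
    counts of the source.  Connectivity is not enforced by default (set
    ``ensure_connected`` when surrogates feed the diffusion model; a
    disconnected draw is then redrawn and logged).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not connectome.is_connected():
        raise ValueError("rewiring requires a connected source network")
    rng = np.random.default_rng(seed)
    items = []
    for _ in range(n):
        adj = _rewire_once(connectome, n_bins, n_swap_factor, rng)
        if ensure_connected:
            tries = 0
            while not Connectome(adj, connectome.distances).is_connected():
                tries += 1
                if tries > max_retries:
                    raise RuntimeError("could not draw a connected rewired surrogate")
                adj = _rewire_once(connectome, n_bins, n_swap_factor, rng)
            if tries:
                warnings.warn(
                    f"redrew a disconnected rewired surrogate {tries} time(s)",
                    stacklevel=2,
                )
        items.append(
            Connectome(adj, connectome.distances, parcellation=connectome.parcellation)
        )
    return SurrogateEnsemble(
        kind="rewired_networks",
        items=items,
        seed=seed,
        parameters={
            "n": n,
            "n_bins": n_bins,
            "n_swap_factor": n_swap_factor,
            "ensure_connected": ensure_connected,
        },
    )


def gene_resamples(
    all_genes: list[str],
    target_set: list[str],
    n: int = 1000,
    seed: int | None = None,
) -> SurrogateEnsemble:
    """Same-size random gene sets drawn from the genes outside the target set."""
    remaining = [g for g in all_genes if g not in set(target_set)]
    k = len(target_set)
    if len(remaining) < k:
        raise ValueError("fewer remaining genes than the target set size")
    rng = np.random.default_rng(seed)
    items = [list(rng.choice(remaining, size=k, replace=False)) for _ in range(n)]
    return SurrogateEnsemble(
        kind="gene_resamples", items=items, seed=seed, parameters={"n": n, "set_size": k}
    )


def morans_i(values: np.ndarray, adjacency: np.ndarray) -> float:
    """Moran's I spatial autocorrelation over a boolean adjacency (used to
    check that spin surrogates preserve autocorrelation)."""
    x = np.asarray(values, float)
    w = adjacency.astype(float)
    z = x - x.mean()
    num = (w * np.outer(z, z)).sum()
    den = (z**2).sum()
    return (x.size / w.sum()) * num / den
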