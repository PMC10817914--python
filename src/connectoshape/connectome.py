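"""Binary white-matter connectomes and their graph quantities.

Houses the group consensus backbone (distance-binned, frequency-ranked
retention of edges seen across individual networks) and the nodal topology
metrics used alongside the diffusion model: unweighted shortest-path
quantities, nodal efficiency, mean first passage time of an unbiased random
walk, and the participation coefficient over system labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .parcellation import Parcellation, euclidean_distance_matrix


@dataclass
class Connectome:
    """Symmetric binary adjacency plus inter-node Euclidean distances."""

    adjacency: np.ndarray
    distances: np.ndarray
    parcellation: Parcellation | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = (a != 0).astype(np.int8)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != self.adjacency.shape:
            raise ValueError("distances must match adjacency shape")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def edge_list(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n_comp == 1


def _require_connected(connectome: Connectome, what: str) -> None:
    n_comp, labels = connected_components(
        csr_matrix(connectome.adjacency), directed=False
    )
    if n_comp > 1:
        sizes = np.bincount(labels)
        smallest = int(np.argmin(sizes))
        members = np.flatnonzero(labels == smallest)
        raise ValueError(
            f"{what} requires a connected graph; smallest component "
            f"has {sizes[smallest]} node(s): {members.tolist()}"
        )


def shortest_path_lengths(connectome: Connectome) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf when disconnected)."""
    return shortest_path(csr_matrix(connectome.adjacency), method="D", unweighted=True)


def graph_diameter(connectome: Connectome) -> int:
    """Maximum shortest-path length over node pairs (the network diameter)."""
    _require_connected(connectome, "graph_diameter")
    return int(shortest_path_lengths(connectome).max())


def nodal_efficiency(connectome: Connectome) -> np.ndarray:
    """Per node, the mean inverse shortest-path length to all other nodes."""
    sp = shortest_path_lengths(connectome)
    n = connectome.n_nodes
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(sp)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def mean_first_passage_time(connectome: Connectome) -> np.ndarray:
    """Nodal mean first passage time of the unbiased random walk.

    The pairwise hitting time from j to i comes from the fundamental matrix
    Z = (I - P + 1 pi^T)^-1 of the walk, m_ji = (z_ii - z_ji) / pi_i with
    pi the degree-weighted stationary distribution; the nodal value is the
    mean over sources j != i.
    """
    _require_connected(connectome, "mean_first_passage_time")
    a = connectome.adjacency.astype(float)
    deg = a.sum(axis=1)
    p = a / deg[:, None]
    n = connectome.n_nodes
    pi = deg / deg.sum()
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    m = (np.diag(z)[None, :] - z) / pi[None, :]  # m[j, i] = hitting time j -> i
    return m.sum(axis=0) / (n - 1)


def participation_coefficient(
    connectome: Connectome, system_labels: np.ndarray
) -> np.ndarray:
    """PC_i = 1 - sum_s (k_is / k_i)^2 over system labels; 0 for isolated nodes."""
    labels = np.asarray(system_labels)
    a = connectome.adjacency
    deg = a.sum(axis=1).astype(float)
    pc = np.zeros(connectome.n_nodes)
    nz = deg > 0
    for s in np.unique(labels):
        k_is = a[:, labels == s].sum(axis=1).astype(float)
        pc[nz] += (k_is[nz] / deg[nz]) ** 2
    pc[nz] = 1.0 - pc[nz]
    return pc


def _equal_frequency_bins(lengths: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split edge indices into n_bins groups of near-equal size by length."""
    order = np.argsort(lengths, kind="stable")
    n_bins = min(n_bins, max(1, order.size))
    return [g for g in np.array_split(order, n_bins) if g.size]


def consensus_backbone(
    individuals: list[np.ndarray],
    distances: np.ndarray,
    n_bins: int = 10,
    hemisphere: np.ndarray | None = None,
    separate_hemispheres: bool = True,
    parcellation: Parcellation | None = None,
) -> Connectome:
    """Distance-binned consensus backbone of individual binary networks.

    The backbone keeps the rounded mean individual edge count.  Candidate
    edges (present in at least one individual) are partitioned into
    equal-frequency Euclidean-length bins -- separately for intra- and
    inter-hemispheric pools when hemisphere labels are available -- and each
    bin retains its quota (the mean individual edge count falling in that
    bin) of the most frequently occurring edges, breaking ties by shorter
    length, then lexicographic (i, j).  Binning by length preserves the
    connection-length distribution of the individual networks instead of
    favoring short edges wholesale.
    """
    if len(individuals) < 2:
        raise ValueError("need at least two individual networks")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    shape = individuals[0].shape
    for a in individuals:
        if a.shape != shape:
            raise ValueError("all individual networks must share a shape")
        if (a != a.T).any() or a.diagonal().any():
            raise ValueError("individual networks must be symmetric, zero diagonal")
    if hemisphere is None and parcellation is not None:
        hemisphere = parcellation.hemisphere

    stack = np.stack([(a != 0) for a in individuals])
    freq = stack.sum(axis=0)
    iu, ju = np.nonzero(np.triu(freq, 1))
    if iu.size == 0:
        raise ValueError("no candidate edges: all individual networks are empty")
    lengths = distances[iu, ju]
    if not np.isfinite(lengths).all():
        raise ValueError("distances missing (non-finite) for a candidate edge")
    counts = freq[iu, ju].astype(float)
    n_subj = len(individuals)

    target_total = int(round(stack.sum(axis=(1, 2)).mean() / 2.0))

    if hemisphere is not None and separate_hemispheres:
        intra = np.asarray(hemisphere)[iu] == np.asarray(hemisphere)[ju]
        pools = [np.flatnonzero(intra), np.flatnonzero(~intra)]
        pools = [p for p in pools if p.size]
    else:
        pools = [np.arange(iu.size)]

    # Per-bin raw quota = mean individual edge count in the bin; largest-
    # remainder apportionment makes the integer quotas sum exactly to the
    # rounded mean total edge count.
    bins: list[np.ndarray] = []
    raw_quotas: list[float] = []
    for pool in pools:
        for local in _equal_frequency_bins(lengths[pool], n_bins):
            idx = pool[local]
            bins.append(idx)
            raw_quotas.append(counts[idx].sum() / n_subj)
    raw = np.asarray(raw_quotas)
    quotas = np.floor(raw).astype(int)
    shortfall = target_total - quotas.sum()
    if shortfall > 0:
        remainders = raw - np.floor(raw)
        capacity = np.array([b.size for b in bins]) - quotas
        order = np.argsort(-remainders, kind="stable")
        for b in order:
            if shortfall == 0:
                break
            if capacity[b] > 0:
                quotas[b] += 1
                shortfall -= 1
    elif shortfall < 0:
        order = np.argsort(raw - np.floor(raw), kind="stable")
        for b in order:
            if shortfall == 0:
                break
            if quotas[b] > 0:
                quotas[b] -= 1
                shortfall += 1

    backbone = np.zeros(shape, dtype=np.int8)
    for idx, quota in zip(bins, quotas):
        if quota >= idx.size:
            chosen = idx
        else:
            order = np.lexsort((ju[idx], iu[idx], lengths[idx], -counts[idx]))
            chosen = idx[order[:quota]]
        backbone[iu[chosen], ju[chosen]] = 1
        backbone[ju[chosen], iu[chosen]] = 1

    result = Connectome(backbone, distances, parcellation=parcellation)
    if result.n_edges != target_total:
        warnings.warn(
            f"backbone has {result.n_edges} edges, target {target_total} "
            "(bin capacity exhausted)",
            stacklevel=2,
        )
    return result
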