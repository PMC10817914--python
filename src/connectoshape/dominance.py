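"""Dominant-node identification.

A node is *dominant* when the spatial layout of its diffusion profile
resembles the whole-brain maturation map more than expected from spatial
autocorrelation alone.  The primary method scores each node at each
neighboring scale by the cosine similarity between its symmetrized diffusion
profile row and the maturation map, spin-tests the similarity per node and
scale, and summarizes robustness as a conjunction map (fraction of scales at
which the node is dominant).  A rank-based alternative, which averages the
ascending ranks of a node's own maturation and its neighbors' mean
maturation, serves as a cross-method check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .connectome import Connectome
from .constraint import neighbor_mean_estimate
from .diffusion import DiffusionProfiles
from .nulls import SurrogateEnsemble, spin_surrogates
from .parcellation import Parcellation


@dataclass
class DominanceResult:
    likelihood: np.ndarray  # scales x nodes (1 x nodes for rank method)
    method: str  # {"diffusion_cosine", "rank_based"}
    p_spin: np.ndarray | None = None
    dominant_mask: np.ndarray | None = None
    conjunction: np.ndarray | None = None
    scales: list[int] = field(default_factory=list)


def _cosine_rows(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    if (norms == 0).any():
        raise AssertionError("zero-norm diffusion profile row on a connected graph")
    vnorm = np.linalg.norm(vector)
    if vnorm == 0:
        raise ValueError("maturation map must not be all zero")
    return (matrix @ vector) / (norms * vnorm)


def dominance_likelihood(
    profiles: DiffusionProfiles,
    map_values: np.ndarray,
    symmetrized: bool = True,
    centered: bool = False,
) -> np.ndarray:
    """Scales x nodes cosine similarity between profile rows and the map.

    Raw (uncentered) cosine by default; ``centered`` subtracts means first,
    giving the Pearson-correlation variant.
    """
    y = np.asarray(map_values, float)
    out = np.empty((profiles.M, y.size))
    for k, m in enumerate(profiles.scales):
        rows = profiles.profile(m, symmetrized=symmetrized)
        if centered:
            rows = rows - rows.mean(axis=1, keepdims=True)
            out[k] = _cosine_rows(rows, y - y.mean())
        else:
            out[k] = _cosine_rows(rows, y)
    return out


def dominant_nodes(
    profiles: DiffusionProfiles,
    map_values: np.ndarray,
    parcellation: Parcellation,
    spin_n: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    spin_ensemble: SurrogateEnsemble | None = None,
    symmetrized: bool = True,
) -> DominanceResult:
    """Spin-tested dominance: per node and scale, p = empirical one-sided
    p-value of the observed similarity against similarities to spun maps."""
    y = np.asarray(map_values, float)
    likelihood = dominance_likelihood(profiles, y, symmetrized=symmetrized)
    if spin_ensemble is None:
        spin_ensemble = spin_surrogates(y, parcellation, n=spin_n, seed=seed)
    n_spins = len(spin_ensemble)
    exceed = np.zeros_like(likelihood, dtype=int)
    spun = np.column_stack([np.asarray(s, float) for s in spin_ensemble])
    for k, m in enumerate(profiles.scales):
        rows = profiles.profile(m, symmetrized=symmetrized)
        norms = np.linalg.norm(rows, axis=1)
        null = (rows @ spun) / (norms[:, None] * np.linalg.norm(spun, axis=0)[None, :])
        exceed[k] = (null >= likelihood[k][:, None]).sum(axis=1)
    p_spin = (exceed + 1) / (n_spins + 1)
    mask = p_spin < alpha
    return DominanceResult(
        likelihood=likelihood,
        method="diffusion_cosine",
        p_spin=p_spin,
        dominant_mask=mask,
        conjunction=conjunction_map(mask),
        scales=profiles.scales,
    )


def conjunction_map(masks: np.ndarray) -> np.ndarray:
    """Per node, the fraction of scales at which the node is dominant."""
    masks = np.asarray(masks, bool)
    return masks.mean(axis=0)


def rank_based_dominance(
    map_values: np.ndarray,
    connectome: Connectome,
    parcellation: Parcellation,
    spin_n: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    spin_ensemble: SurrogateEnsemble | None = None,
) -> DominanceResult:
    """Rank-based dominance: mean of the ascending ranks of a node's own
    maturation and of its neighbors' mean maturation (ties get average
    ranks), spin-tested by recomputing mean ranks on spun maps."""
    y = np.asarray(map_values, float)

    def mean_rank(values: np.ndarray) -> np.ndarray:
        est = neighbor_mean_estimate(values, connectome)
        est = np.where(np.isnan(est), -np.inf, est)
        return (rankdata(values, method="average") + rankdata(est, method="average")) / 2.0

    likelihood = mean_rank(y)
    if spin_ensemble is None:
        spin_ensemble = spin_surrogates(y, parcellation, n=spin_n, seed=seed)
    null = np.stack([mean_rank(np.asarray(s, float)) for s in spin_ensemble])
    p_spin = ((null >= likelihood[None, :]).sum(axis=0) + 1) / (len(spin_ensemble) + 1)
    mask = p_spin < alpha
    return DominanceResult(
        likelihood=likelihood[None, :],
        method="rank_based",
        p_spin=p_spin[None, :],
        dominant_mask=mask[None, :],
        conjunction=mask[None, :].astype(float).mean(axis=0),
        scales=[1],
    )
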