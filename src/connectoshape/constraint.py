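"""Neighbor-constraint statistics.

A node's maturation is compared with the mean maturation of its directly
connected white-matter neighbors (the neighbor-mean estimate T-hat).  The
Pearson correlation between the observed map and T-hat quantifies how
strongly connectome wiring constrains maturation; two confound variants
control for spatial proximity:

* ``excluded`` -- T-hat recomputed over graph neighbors that are *not*
  spatial (border-sharing) neighbors;
* ``regressed`` -- T-hat residualized on each node's mean Euclidean distance
  to its graph neighbors before correlating.

Significance comes from spin-map and rewired-network surrogate ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import Connectome
from .nulls import SurrogateEnsemble, empirical_p, rewired_surrogates, spin_surrogates
from .parcellation import Parcellation

VARIANTS = ("plain", "excluded", "regressed")


@dataclass
class ConstraintResult:
    r: float
    variant: str
    estimated_map: np.ndarray  # NaN for nodes without usable neighbors
    used: np.ndarray  # boolean mask of nodes entering the correlation
    p_spin: float | None = None
    p_rewired: float | None = None
    n_dropped: int = 0
    extras: dict = field(default_factory=dict)


def neighbor_mean_estimate(
    map_values: np.ndarray, connectome: Connectome, adjacency: np.ndarray | None = None
) -> np.ndarray:
    """T-hat_i: mean map value over i's graph neighbors (NaN when degree 0)."""
    values = np.asarray(map_values, float)
    a = connectome.adjacency if adjacency is None else adjacency
    if values.shape[0] != a.shape[0]:
        raise ValueError("map and connectome must share node order")
    deg = a.sum(axis=1).astype(float)
    if (deg == 0).all():
        raise ValueError("all nodes have degree 0")
    with np.errstate(invalid="ignore"):
        est = (a @ values) / deg
    est[deg == 0] = np.nan
    return est


def _residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(covariate), covariate])
    coef, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ coef


def _estimate_for_variant(
    map_values: np.ndarray,
    connectome: Connectome,
    variant: str,
    parcellation: Parcellation | None,
    adjacency: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (estimate, usable-node mask) under one confound variant."""
    a = (connectome.adjacency if adjacency is None else adjacency).astype(int)
    if variant == "excluded":
        if parcellation is None:
            raise ValueError("variant='excluded' needs a parcellation")
        a = a * (~parcellation.spatial_adjacency).astype(int)
    est = neighbor_mean_estimate(map_values, connectome, adjacency=a)
    used = ~np.isnan(est)
    if variant == "regressed":
        deg = a.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            mean_dist = (a * connectome.distances).sum(axis=1) / deg
        est = est.copy()
        est[used] = _residualize(est[used], mean_dist[used])
    return est, used


def constraint_correlation(
    map_values: np.ndarray,
    connectome: Connectome,
    variant: str = "plain",
    parcellation: Parcellation | None = None,
    spin_ensemble: SurrogateEnsemble | None = None,
    rewired_ensemble: SurrogateEnsemble | None = None,
    n_nulls: int = 0,
    seed: int | None = None,
    min_usable: int = 10,
) -> ConstraintResult:
    """Correlate a maturation map with its neighbor-mean estimate.

    Pass pre-built surrogate ensembles, or set ``n_nulls`` to draw both
    families internally.  Null correlations recompute the full variant
    pipeline: spun maps re-estimate T-hat from the spun values; rewired
    networks re-estimate T-hat (and the distance covariate) from the
    surrogate wiring.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if parcellation is None:
        parcellation = connectome.parcellation
    values = np.asarray(map_values, float)

    est, used = _estimate_for_variant(values, connectome, variant, parcellation)
    if used.sum() < min_usable:
        raise ValueError(f"only {int(used.sum())} usable nodes under variant {variant!r}")
    r = float(stats.pearsonr(values[used], est[used]).statistic)

    rng = np.random.default_rng(seed)
    if n_nulls and spin_ensemble is None and parcellation is not None:
        spin_ensemble = spin_surrogates(
            values, parcellation, n=n_nulls, seed=int(rng.integers(2**31))
        )
    if n_nulls and rewired_ensemble is None:
        rewired_ensemble = rewired_surrogates(
            connectome, n=n_nulls, seed=int(rng.integers(2**31))
        )

    p_spin = p_rewired = None
    if spin_ensemble is not None:
        null_r = []
        for surrogate in spin_ensemble:
            s = np.asarray(surrogate, float)
            e, u = _estimate_for_variant(s, connectome, variant, parcellation)
            null_r.append(stats.pearsonr(s[u], e[u]).statistic)
        p_spin = empirical_p(r, np.asarray(null_r), side="greater")
    if rewired_ensemble is not None:
        null_r = []
        for surrogate in rewired_ensemble:
            e, u = _estimate_for_variant(
                values, surrogate, variant, parcellation
            )
            null_r.append(stats.pearsonr(values[u], e[u]).statistic)
        p_rewired = empirical_p(r, np.asarray(null_r), side="greater")

    return ConstraintResult(
        r=r,
        variant=variant,
        estimated_map=est,
        used=used,
        p_spin=p_spin,
        p_rewired=p_rewired,
        n_dropped=int((~used).sum()),
    )
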