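"""Synthetic study generator.

Emulates the statistical structure the analysis assumes, so every downstream
stage is testable without any imaging or transcriptome download:

* distance-dependent binary connectomes with community structure on the
  spherical parcel geometry (``gen_connectome``);
* longitudinal per-node cortical thickness with a planted group effect,
  sex covariate, subject random intercepts and i.i.d. noise, on a visit
  roster matching a mixed single/double/triple-scan design
  (``gen_longitudinal_ct``);
* effect maps planted as mixtures of diffusion profiles of chosen
  "dominant" nodes plus spatially autocorrelated noise (``gen_effect_map``);
* gene panels whose target sets follow age-dependent, category-divergent
  set-level trajectories (``gen_gene_panel``).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .connectome import Connectome
from .diffusion import DiffusionProfiles
from .parcellation import Parcellation, euclidean_distance_matrix, gen_parcellation

__all__ = [
    "ScanTable",
    "EffectMap",
    "GenePanel",
    "gen_parcellation",
    "gen_connectome",
    "gen_effect_map",
    "gen_longitudinal_ct",
    "gen_gene_panel",
    "gen_individual_networks",
]

AGE_CUT_YEARS = 10.0  # WHO-based child / adolescent boundary


@dataclass
class ScanTable:
    """Longitudinal scan roster: per-scan metadata plus a scans x nodes CT matrix.

    ``meta`` columns: subject, scan_index, age (years), sex (0/1), group
    ({child, adolescent}, from the age cut), optional site.  ``ct`` is in mm,
    row order bound to ``meta``.
    """

    meta: pd.DataFrame
    ct: np.ndarray

    def __post_init__(self) -> None:
        if len(self.meta) != self.ct.shape[0]:
            raise ValueError("meta rows and ct rows must match")
        if not np.isfinite(self.ct).all() or (self.ct <= 0).any():
            raise ValueError("ct values must be finite and positive")
        for _, grp in self.meta.groupby("subject"):
            ages = grp.sort_values("scan_index")["age"].to_numpy()
            if (np.diff(ages) <= 0).any():
                raise ValueError("scan ages must be strictly increasing per subject")

    @property
    def n_nodes(self) -> int:
        return self.ct.shape[1]

    @property
    def n_scans(self) -> int:
        return self.ct.shape[0]


@dataclass
class EffectMap:
    """Per-node group effect (mm) with provenance and planted ground truth."""

    beta: np.ndarray
    provenance: str  # {"planted_from_diffusion", "autocorrelated_null"}
    dominant_truth: set[int] = field(default_factory=set)
    planted_scale: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ValueError("effect map must be finite")


@dataclass
class GenePanel:
    """Samples x genes expression with region/category/age sample metadata."""

    expression: pd.DataFrame  # index: sample id, columns: gene names
    samples: pd.DataFrame  # columns: region, category, age
    gene_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.expression):
            raise ValueError("sample metadata and expression rows must match")
        genes = set(self.expression.columns)
        for name, members in self.gene_sets.items():
            if not set(members) <= genes:
                raise ValueError(f"gene set {name!r} contains unknown genes")


def gen_connectome(
    parcellation: Parcellation,
    target_density: float = 0.12,
    length_scale: float = 1.0,
    within_system_bonus: float = 8.0,
    seed: int | None = None,
) -> Connectome:
    """Distance-dependent binary connectome with community structure.

    Edge inclusion weight is exp(-d_ij / length_scale) * (1 + bonus * same
    system).  A minimum spanning tree over Euclidean distances guarantees
    connectivity; the remaining quota of edges is drawn by weighted sampling
    without replacement, so the realized density matches the target up to
    rounding.

    The default community bonus is calibrated so that roughly 60% of a
    node's one-step diffusion mass stays within its own system, matching the
    strong community segregation real structural connectomes show at the
    first neighboring scale.
    """
    if not 0.0 < target_density < 1.0:
        raise ValueError("target_density must be in (0, 1)")
    n = parcellation.n_nodes
    d = euclidean_distance_matrix(parcellation)
    n_pairs = n * (n - 1) // 2
    target_edges = int(round(target_density * n_pairs))
    if target_edges < n - 1:
        raise ValueError(
            f"target density {target_density} gives {target_edges} edges, fewer "
            f"than the {n - 1} needed for connectivity"
        )

    rng = np.random.default_rng(seed)
    mst = minimum_spanning_tree(csr_matrix(d)).toarray()
    adj = ((mst + mst.T) > 0).astype(np.int8)

    iu, ju = np.nonzero(np.triu(np.ones((n, n), dtype=bool), 1))
    free = adj[iu, ju] == 0
    same = parcellation.system[iu] == parcellation.system[ju]
    w = np.exp(-d[iu, ju] / length_scale) * (1.0 + within_system_bonus * same)
    w = np.where(free, w, 0.0)
    n_extra = target_edges - int(adj.sum()) // 2
    if n_extra > 0:
        p = w / w.sum()
        chosen = rng.choice(iu.size, size=n_extra, replace=False, p=p)
        adj[iu[chosen], ju[chosen]] = 1
        adj[ju[chosen], iu[chosen]] = 1
    return Connectome(adj, d, parcellation=parcellation)


def gen_individual_networks(
    parcellation: Parcellation,
    n_subjects: int,
    target_density: float = 0.10,
    length_scale: float = 0.5,
    within_system_bonus: float = 1.0,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Independent per-subject connectome draws sharing one geometry."""
    child = np.random.default_rng(seed).integers(2**31, size=n_subjects)
    return [
        gen_connectome(
            parcellation, target_density, length_scale, within_system_bonus, int(s)
        ).adjacency
        for s in child
    ]


def smoothed_noise(
    parcellation: Parcellation, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One adjacency-averaging pass over i.i.d. Gaussian noise: a minimal
    spatial-autocorrelation model sufficient for spin-test realism."""
    raw = rng.normal(0.0, sd, size=parcellation.n_nodes)
    if sd == 0:
        return raw
    adj = parcellation.spatial_adjacency.astype(float)
    closed = adj + np.eye(parcellation.n_nodes)
    return (closed @ raw) / closed.sum(axis=1)


def gen_autocorrelated_map(
    parcellation: Parcellation,
    length_scale: float = 0.6,
    seed: int | None = None,
) -> np.ndarray:
    """Isotropic Gaussian-process map on the sphere (rotation-invariant).

    Samples a zero-mean Gaussian field with squared-exponential covariance
    exp(-||c_i - c_j||^2 / length_scale^2) over parcel centroids.  Because
    the covariance depends only on inter-centroid distance, the field's
    distribution is invariant under rotations -- exactly the null family the
    spin test permutes -- which makes these maps the reference
    network-independent autocorrelated maps for calibration studies.
    """
    from .parcellation import euclidean_distance_matrix as _edm

    d = _edm(parcellation)
    k = np.exp(-((d / length_scale) ** 2)) + 1e-8 * np.eye(parcellation.n_nodes)
    chol = np.linalg.cholesky(k)
    rng = np.random.default_rng(seed)
    return chol @ rng.normal(size=parcellation.n_nodes)


def gen_effect_map(
    profiles: DiffusionProfiles,
    parcellation: Parcellation,
    dominant_nodes: list[int] | None = None,
    scale_m: int | None = None,
    weights: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> EffectMap:
    """Plant a group-effect map as a weighted mixture of symmetrized diffusion
    profile rows of chosen dominant nodes, plus spatially smoothed noise.

    With an integer ``scale_m`` the mixture uses the scale-m rows exactly;
    with ``scale_m=None`` (default) each dominant node contributes the mean
    of its rows across all scales 1..M, a map that is smooth along the
    network's own wiring rather than a single-scale bump.  With no dominant
    nodes (or all-zero weights) the map is pure smoothed noise and carries an
    empty ground-truth set.
    """
    rng = np.random.default_rng(seed)
    dominant_nodes = list(dominant_nodes or [])
    if weights is None:
        weights = [1.0] * len(dominant_nodes)
    if len(weights) != len(dominant_nodes):
        raise ValueError("weights must match dominant_nodes")
    if scale_m is None:
        rows = np.mean([profiles.S_m[m] for m in profiles.scales], axis=0)
    else:
        rows = profiles.S_m[scale_m]
    beta = np.zeros(parcellation.n_nodes)
    truth: set[int] = set()
    for node, w in zip(dominant_nodes, weights):
        beta += w * rows[node]
        if w != 0:
            truth.add(int(node))
    beta += smoothed_noise(parcellation, noise_sd, rng)
    provenance = "planted_from_diffusion" if truth else "autocorrelated_null"
    return EffectMap(
        beta=beta,
        provenance=provenance,
        dominant_truth=truth,
        planted_scale=scale_m if truth else None,
    )


def gen_longitudinal_ct(
    parcellation: Parcellation,
    effect_map: EffectMap,
    n_single: int = 158,
    n_double: int = 105,
    n_triple: int = 51,
    age_range: tuple[float, float] = (6.0, 14.0),
    subject_sd: float = 0.10,
    noise_sd: float = 0.05,
    sex_effect: float = 0.0,
    baseline_mm: float = 3.0,
    baseline_spatial_sd: float = 0.15,
    seed: int | None = None,
) -> ScanTable:
    """Longitudinal CT roster with a planted adolescent-vs-child effect.

    The default counts follow a mixed design of 158 single-, 105 double- and
    51 triple-scan subjects (521 scans; 207 consecutive scan pairs).  Per
    scan, CT_ij = node baseline + beta * 1[adolescent] + sex effect + subject
    random intercept + i.i.d. noise; repeat scans are spaced ~1 year and the
    group follows the scan age at the 10-year cut.
    """
    counts = (n_single, n_double, n_triple)
    if any(c < 0 for c in counts):
        raise ValueError("subject counts must be nonnegative")
    if sum(counts) == 0:
        raise ValueError("at least one subject is required")
    lo, hi = age_range
    if not (4.0 < lo < hi < 16.0):
        raise ValueError("age_range must lie within (4, 16)")

    rng = np.random.default_rng(seed)
    n_nodes = parcellation.n_nodes
    baseline = baseline_mm + smoothed_noise(
        parcellation, baseline_spatial_sd, np.random.default_rng(0 if seed is None else seed)
    )

    rows = []
    ct_rows = []
    subject = 0
    for n_scans, n_subj in zip((1, 2, 3), counts):
        for _ in range(n_subj):
            sex = int(rng.integers(2))
            intercept = rng.normal(0.0, subject_sd)
            max_first = hi - 1.05 * (n_scans - 1)
            age = float(rng.uniform(lo, max_first))
            for k in range(n_scans):
                if k:
                    age += float(rng.uniform(0.9, 1.1))
                adolescent = age >= AGE_CUT_YEARS
                ct = (
                    baseline
                    + effect_map.beta * adolescent
                    + sex_effect * sex
                    + intercept
                    + rng.normal(0.0, noise_sd, size=n_nodes)
                )
                rows.append(
                    {
                        "subject": f"sub-{subject:04d}",
                        "scan_index": k,
                        "age": age,
                        "sex": sex,
                        "group": "adolescent" if adolescent else "child",
                    }
                )
                ct_rows.append(ct)
            subject += 1
    meta = pd.DataFrame(rows)
    return ScanTable(meta=meta, ct=np.asarray(ct_rows))


def gen_gene_panel(
    n_genes: int = 200,
    gene_sets: dict[str, int] | None = None,
    region_categories: dict[str, str] | None = None,
    ages: np.ndarray | None = None,
    divergence: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> GenePanel:
    """Gene panel with category-divergent set-level trajectories.

    Genes in a target set share a latent age trajectory whose level differs
    between dominant and non-dominant regions by ``divergence``; background
    genes are i.i.d. noise.  One sample is generated per (region, age).
    """
    gene_sets = gene_sets or {"set_a": 12}
    region_categories = region_categories or {
        **{f"dom-{i}": "dominant" for i in range(5)},
        **{f"non-{i}": "non_dominant" for i in range(6)},
    }
    ages = np.asarray(ages if ages is not None else np.linspace(4.0, 16.0, 7))
    if sum(gene_sets.values()) > n_genes:
        raise ValueError("gene sets exceed the panel size")

    rng = np.random.default_rng(seed)
    gene_names = [f"g{gi:04d}" for gi in range(n_genes)]
    set_members: dict[str, list[str]] = {}
    cursor = 0
    for name, size in gene_sets.items():
        set_members[name] = gene_names[cursor : cursor + size]
        cursor += size

    regions = list(region_categories)
    sample_rows = [
        {"region": region, "category": region_categories[region], "age": float(a)}
        for region in regions
        for a in ages
    ]
    samples = pd.DataFrame(sample_rows)
    n_samples = len(samples)

    expr = rng.normal(0.0, noise_sd, size=(n_samples, n_genes))
    age_z = (samples["age"].to_numpy() - ages.mean()) / max(ages.std(), 1e-12)
    is_dom = (samples["category"] == "dominant").to_numpy()
    for name, members in set_members.items():
        # shared latent trajectory, shifted by `divergence` in dominant regions
        latent = age_z + divergence * is_dom
        loadings = rng.uniform(0.8, 1.2, size=len(members))
        cols = [gene_names.index(g) for g in members]
        expr[:, cols] += np.outer(latent, loadings)

    expression = pd.DataFrame(
        expr, columns=gene_names, index=[f"s{si:04d}" for si in range(n_samples)]
    )
    return GenePanel(expression=expression, samples=samples, gene_sets=set_members)
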