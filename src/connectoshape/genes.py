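"""Gene-expression contrasts for dominant vs non-dominant regions.

Two analyses link connectome constraints to transcriptomics:

* **Set-level contrast** (developmental panel).  For a named gene set, the
  first principal-component score of the column-standardized set submatrix
  summarizes the set's transcription level per sample; the dominant minus
  non-dominant difference in mean PC1 score is tested against a null built
  by resampling same-size gene sets from the remaining genes (region
  categories held fixed).
* **Map-gene correlation** (adult atlas panel).  Each gene's regional
  expression map is Pearson-correlated with the dominance-likelihood map;
  two-sided spin p-values come from one shared spin ensemble of the
  likelihood map and are Benjamini-Hochberg corrected across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nulls import SurrogateEnsemble, empirical_p, gene_resamples, spin_surrogates
from .parcellation import Parcellation
from .synthetic import GenePanel


@dataclass
class ContrastResult:
    gene_set: str
    difference: float
    p: float
    null_differences: np.ndarray
    n_samples: int
    age_window: tuple[float, float]


@dataclass
class GeneMapTable:
    table: pd.DataFrame  # per gene: r, p_spin, q_fdr, significant
    positive: list[str]
    negative: list[str]
    parameters: dict = field(default_factory=dict)


def geneset_pc1(panel: GenePanel, gene_set: list[str] | str) -> np.ndarray:
    """Per-sample first principal-component score of a gene set's submatrix.

    Columns are z-scored jointly over all samples before the PCA; the sign is
    fixed so the mean loading is nonnegative.  Zero-variance genes are
    dropped with a warning.
    """
    members = panel.gene_sets[gene_set] if isinstance(gene_set, str) else list(gene_set)
    if not members:
        raise ValueError("gene set is empty")
    sub = panel.expression[members].to_numpy(float)
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 samples for a PC1 score")
    sd = sub.std(axis=0, ddof=0)
    if (sd == 0).any():
        dropped = [g for g, s in zip(members, sd) if s == 0]
        warnings.warn(f"dropping zero-variance gene(s) {dropped}", stacklevel=2)
        keep = sd > 0
        sub, sd = sub[:, keep], sd[keep]
        if sub.shape[1] == 0:
            raise ValueError("gene set empty after dropping zero-variance genes")
    z = (sub - sub.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0]
    scores = u[:, 0] * s[0]
    if loadings.mean() < 0:
        scores = -scores
    return scores


def dominant_contrast(
    panel: GenePanel,
    gene_set: str,
    age_window: tuple[float, float] = (6.0, 14.0),
    n_resamples: int = 1000,
    seed: int | None = None,
) -> ContrastResult:
    """Dominant minus non-dominant difference in mean gene-set PC1 score.

    The empirical difference (restricted to samples inside ``age_window``) is
    compared, in its observed direction, against differences from
    ``n_resamples`` same-size random gene sets drawn from the remaining
    panel genes; region categories are never permuted.
    """
    lo, hi = age_window
    in_window = (panel.samples["age"] >= lo) & (panel.samples["age"] <= hi)
    cat = panel.samples["category"].to_numpy()
    dom = in_window.to_numpy() & (cat == "dominant")
    non = in_window.to_numpy() & (cat == "non_dominant")
    if not dom.any() or not non.any():
        raise ValueError("both categories must be present within the age window")

    def category_diff(members: list[str]) -> float:
        scores = geneset_pc1(panel, members)
        return float(scores[dom].mean() - scores[non].mean())

    observed = category_diff(panel.gene_sets[gene_set])
    resamples = gene_resamples(
        list(panel.expression.columns), panel.gene_sets[gene_set], n=n_resamples, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = np.array([category_diff(members) for members in resamples])
    side = "greater" if observed >= 0 else "less"
    p = empirical_p(observed, null, side=side)
    return ContrastResult(
        gene_set=gene_set,
        difference=observed,
        p=p,
        null_differences=null,
        n_samples=int(dom.sum() + non.sum()),
        age_window=age_window,
    )


def map_gene_correlation(
    likelihood_map: np.ndarray,
    gene_maps: pd.DataFrame,
    parcellation: Parcellation,
    spin_n: int = 1000,
    fdr_alpha: float = 0.05,
    seed: int | None = None,
    spin_ensemble: SurrogateEnsemble | None = None,
) -> GeneMapTable:
    """Correlate the dominance-likelihood map with per-gene expression maps.

    One shared spin ensemble of the likelihood map provides two-sided
    empirical p-values comparable across genes; Benjamini-Hochberg controls
    the FDR over genes at ``fdr_alpha``.  Constant gene maps are skipped with
    a warning.
    """
    y = np.asarray(likelihood_map, float)
    if len(gene_maps) != y.size:
        raise ValueError("gene maps must align with the likelihood map regions")
    if spin_ensemble is None:
        spin_ensemble = spin_surrogates(y, parcellation, n=spin_n, seed=seed)
    spun = np.stack([np.asarray(s, float) for s in spin_ensemble])  # n_spins x N

    def corr_with(target: np.ndarray, x: np.ndarray) -> np.ndarray:
        tz = (target - target.mean(axis=-1, keepdims=True))
        xz = x - x.mean(axis=0, keepdims=True)
        num = tz @ xz
        den = np.sqrt((tz**2).sum(axis=-1))[..., None] * np.sqrt((xz**2).sum(axis=0))
        return num / den

    genes = list(gene_maps.columns)
    x = gene_maps.to_numpy(float)
    keep = x.std(axis=0) > 0
    if not keep.all():
        skipped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"skipping constant gene map(s) {skipped}", stacklevel=2)
    x, genes = x[:, keep], [g for g, k in zip(genes, keep) if k]

    r_obs = corr_with(y, x)
    r_null = corr_with(spun, x)  # n_spins x n_genes
    p_spin = ((np.abs(r_null) >= np.abs(r_obs)[None, :]).sum(axis=0) + 1) / (
        spun.shape[0] + 1
    )
    significant, q_fdr, *_ = multipletests(p_spin, alpha=fdr_alpha, method="fdr_bh")
    table = pd.DataFrame(
        {"gene": genes, "r": r_obs, "p_spin": p_spin, "q_fdr": q_fdr, "significant": significant}
    ).set_index("gene")
    positive = table.index[(table["significant"]) & (table["r"] > 0)].tolist()
    negative = table.index[(table["significant"]) & (table["r"] < 0)].tolist()
    return GeneMapTable(
        table=table,
        positive=positive,
        negative=negative,
        parameters={"spin_n": len(spin_ensemble), "fdr_alpha": fdr_alpha, "seed": seed},
    )
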