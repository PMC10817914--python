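"""Per-node cortical-thickness maturation maps.

Three statistical models quantify maturation from childhood to adolescence:

* **Model I** -- group contrast.  Per node, a linear mixed model of CT on
  group and sex with a per-subject random intercept; the group-term t
  statistic, signed so cortical *thinning* (child > adolescent) is positive,
  is the maturation extent.  Significance is Bonferroni-controlled across
  nodes.
* **Model II** -- developmental trajectory.  Per node, a B-spline age smooth
  with sex covariate and subject random intercept (REML fit); the maturation
  rate at an evaluation age is the first derivative of the fitted smooth by
  central finite difference.
* **Model III** -- individual rate.  Per consecutive scan pair of one
  subject, (CT_{j+1} - CT_j) / (age_{j+1} - age_j) in mm/year (negative =
  thinning).

``system_enrichment`` summarizes a map at the system level as z-scores
against a spin-test null of per-system means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .nulls import SurrogateEnsemble
from .synthetic import ScanTable


@dataclass
class MaturationMap:
    """Per-node maturation values with model provenance.

    ``value`` is a group t statistic (model1_t), a rate in mm/year at one
    evaluation age (model2_rate), or an individual rate in mm/year
    (model3_rate).  ``significance_mask`` is defined only for Model I.
    """

    value: np.ndarray
    model_tag: str
    p_value: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    alpha_corrected: float | None = None
    eval_age: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if not np.isfinite(self.value).all():
            raise ValueError("maturation values must be finite")


def _design_model1(meta: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    x = pd.DataFrame(index=meta.index)
    x["const"] = 1.0
    # child indicator: a positive coefficient means child > adolescent, i.e.
    # thinning-positive t values by construction
    x["child"] = (meta["group"] == "child").astype(float)
    for cov in covariates:
        if cov == "sex":
            x["sex"] = meta["sex"].astype(float)
        elif cov == "site":
            dummies = pd.get_dummies(meta["site"], prefix="site", drop_first=True)
            x = pd.concat([x, dummies.astype(float)], axis=1)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return x


def model1_group_t(
    scans: ScanTable,
    covariates: tuple[str, ...] = ("sex",),
    alpha: float = 0.05,
    random_slope: bool | str = False,
) -> MaturationMap:
    """Group-contrast t map (Model I) with Bonferroni significance mask.

    The mixed model is fit per node with a per-subject random intercept; with
    ``random_slope="auto"`` a random group slope is attempted first and the
    fit falls back to intercept-only (and, for all-singleton subjects or a
    failed fit, to OLS) when the richer model is unidentifiable.
    """
    meta = scans.meta
    groups_present = set(meta["group"].unique())
    if groups_present != {"child", "adolescent"}:
        raise ValueError("both child and adolescent groups must be present")
    for g in ("child", "adolescent"):
        if meta.loc[meta["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"need at least two subjects in the {g} group")

    x = _design_model1(meta, covariates)
    n_nodes = scans.n_nodes
    singleton = meta.groupby("subject")["subject"].transform("size").max() == 1

    t_vals = np.empty(n_nodes)
    p_vals = np.empty(n_nodes)
    fallbacks = 0
    for node in range(n_nodes):
        y = scans.ct[:, node]
        if np.std(y) == 0:
            raise ValueError(f"node {node} has zero CT variance")
        t, p, fb = _fit_one_node(y, x, meta, random_slope, force_ols=singleton)
        t_vals[node], p_vals[node] = t, p
        fallbacks += fb
    if fallbacks:
        warnings.warn(
            f"random-effect fit fell back for {fallbacks} node(s)", stacklevel=2
        )
    alpha_corrected = alpha / n_nodes
    return MaturationMap(
        value=t_vals,
        model_tag="model1_t",
        p_value=p_vals,
        significance_mask=p_vals < alpha_corrected,
        alpha_corrected=alpha_corrected,
    )


def _fit_one_node(
    y: np.ndarray,
    x: pd.DataFrame,
    meta: pd.DataFrame,
    random_slope: bool | str,
    force_ols: bool,
) -> tuple[float, float, int]:
    if force_ols:
        res = sm.OLS(y, x).fit()
        return float(res.tvalues["child"]), float(res.pvalues["child"]), 0

    specs = []
    if random_slope:
        specs.append(x[["const", "child"]].to_numpy())
    specs.append(np.ones((len(y), 1)))
    for k, exog_re in enumerate(specs):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x, groups=meta["subject"], exog_re=exog_re)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not np.isfinite(res.bse_fe["child"]):
                continue
            t = float(res.fe_params["child"] / res.bse_fe["child"])
            p = 2.0 * float(stats.norm.sf(abs(t)))
            return t, p, int(bool(random_slope) and k > 0)
        except (np.linalg.LinAlgError, ValueError):
            continue
    res = sm.OLS(y, x).fit()
    return float(res.tvalues["child"]), float(res.pvalues["child"]), 1


def split_scan_pairs(scans: ScanTable) -> list[tuple[int, int]]:
    """Consecutive same-subject scan pairs as (row_j, row_j+1) index tuples.

    A subject with k scans yields k-1 pairs; single-scan subjects yield none.
    """
    pairs: list[tuple[int, int]] = []
    for _, grp in scans.meta.groupby("subject", sort=False):
        order = grp.sort_values("scan_index").index.to_list()
        pairs.extend(zip(order[:-1], order[1:]))
    return pairs


def model3_individual_rate(
    scans: ScanTable, pair: tuple[int, int]
) -> MaturationMap:
    """Individual CT maturation rate (mm/year) for one consecutive scan pair."""
    j0, j1 = pair
    m0, m1 = scans.meta.loc[j0], scans.meta.loc[j1]
    if m0["subject"] != m1["subject"]:
        raise ValueError("scan pair must belong to one subject")
    gap = float(m1["age"] - m0["age"])
    if gap <= 0:
        raise ValueError("scan age gap must be positive")
    rate = (scans.ct[scans.meta.index.get_loc(j1)] - scans.ct[scans.meta.index.get_loc(j0)]) / gap
    return MaturationMap(value=rate, model_tag="model3_rate", extras={"age_gap": gap})


def _bspline_basis(ages: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    from scipy.interpolate import BSpline

    n_basis = len(knots) - degree - 1
    basis = np.empty((ages.size, n_basis))
    for k in range(n_basis):
        coef = np.zeros(n_basis)
        coef[k] = 1.0
        basis[:, k] = BSpline(knots, coef, degree)(ages)
    return basis


@dataclass
class Model2Fit:
    """Fitted age-smooth curves and their evaluation helper."""

    knots: np.ndarray
    coefs: np.ndarray  # n_nodes x n_basis spline coefficients
    intercepts: np.ndarray
    age_range: tuple[float, float]

    def smooth(self, ages: np.ndarray) -> np.ndarray:
        """Population-level fitted smooth, nodes x ages."""
        basis = _bspline_basis(np.asarray(ages, float), self.knots)
        return self.intercepts[:, None] + self.coefs @ basis.T


def model2_gam(
    scans: ScanTable,
    eval_ages: list[float],
    basis_df: int = 5,
    derivative_step: float = 0.01,
) -> tuple[list[MaturationMap], Model2Fit]:
    """Spline age-trajectory fit (Model II) and per-age maturation rates.

    Per node, CT is regressed on a B-spline basis of age (dimension
    ``basis_df``) plus sex, with a subject random intercept fit by REML; the
    rate at each evaluation age is the central finite difference of the
    fitted smooth.
    """
    ages = scans.meta["age"].to_numpy(float)
    if np.unique(np.round(ages, 6)).size < 8:
        raise ValueError("need at least 8 distinct scan ages")
    lo, hi = float(ages.min()), float(ages.max())
    h = derivative_step
    for a in eval_ages:
        if not (lo + h <= a <= hi - h):
            raise ValueError(f"eval age {a} outside the observed range [{lo}, {hi}]")

    degree = 3
    n_interior = max(basis_df - degree - 1, 0)
    interior = np.quantile(ages, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    basis = _bspline_basis(ages, knots, degree)
    basis = basis - basis.mean(axis=0)  # identifiable alongside the intercept

    x = pd.DataFrame(basis, columns=[f"b{k}" for k in range(basis.shape[1])])
    x.insert(0, "const", 1.0)
    x["sex"] = scans.meta["sex"].to_numpy(float)
    groups = scans.meta["subject"].to_numpy()
    singleton = scans.meta.groupby("subject")["subject"].transform("size").max() == 1

    n_nodes = scans.n_nodes
    coefs = np.empty((n_nodes, basis.shape[1]))
    intercepts = np.empty(n_nodes)
    for node in range(n_nodes):
        y = scans.ct[:, node]
        try:
            if singleton:
                raise ValueError("all-singleton subjects: use OLS")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, x, groups=groups).fit(
                    reml=True, method="lbfgs", maxiter=200
                )
            params = res.fe_params
        except (np.linalg.LinAlgError, ValueError):
            params = sm.OLS(y, x).fit().params
        coefs[node] = [params[f"b{k}"] for k in range(basis.shape[1])]
        intercepts[node] = params["const"]

    fit = Model2Fit(knots=knots, coefs=coefs, intercepts=intercepts, age_range=(lo, hi))
    maps = []
    for a in eval_ages:
        rate = (fit.smooth(np.array([a + h]))[:, 0] - fit.smooth(np.array([a - h]))[:, 0]) / (
            2 * h
        )
        maps.append(MaturationMap(value=rate, model_tag="model2_rate", eval_age=float(a)))
    return maps, fit


def system_enrichment(
    map_values: np.ndarray,
    labels: np.ndarray,
    spin_ensemble: SurrogateEnsemble,
) -> pd.DataFrame:
    """Per-system mean of a map expressed as z-scores against spin nulls.

    z = (observed per-system mean - null mean) / null sd; the one-sided p is
    the fraction of null means at or above the observed (positive
    enrichment).  A degenerate null (constant map) yields z = 0 with a
    warning.
    """
    values = np.asarray(map_values, float)
    labels = np.asarray(labels)
    systems = np.unique(labels)
    null_means = np.array(
        [[np.mean(np.asarray(s)[labels == lab]) for lab in systems] for s in spin_ensemble]
    )
    rows = []
    for k, lab in enumerate(systems):
        observed = values[labels == lab].mean()
        mu, sd = null_means[:, k].mean(), null_means[:, k].std(ddof=0)
        if sd == 0:
            warnings.warn(f"degenerate spin null for system {lab}; z set to 0", stacklevel=2)
            z = 0.0
        else:
            z = (observed - mu) / sd
        p = ((null_means[:, k] >= observed).sum() + 1) / (len(spin_ensemble) + 1)
        rows.append({"system": lab, "observed_mean": observed, "z": z, "p_spin": p})
    return pd.DataFrame(rows)
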