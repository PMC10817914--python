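"""Cross-validated SVR prediction of a maturation map from diffusion profiles.

Nodes are samples and the rows of the scale-m (symmetrized) diffusion matrix
are features.  A linear epsilon-SVR is trained under k-fold cross-validation;
the cost parameter C is chosen per outer training fold by inner
cross-validation over a grid of 16 powers of two (2^-5 .. 2^10), features are
z-scored with training-fold statistics only, and the prediction accuracy is
the Pearson correlation between the observed map and the assembled
out-of-fold predictions.  Significance is assessed by re-running the
identical procedure on spun target maps (spin null) and on profiles
recomputed from rewired networks (rewired null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .diffusion import DiffusionProfiles, diffusion_profiles
from .nulls import SurrogateEnsemble, empirical_p

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 11))  # 16 values, 2^-5 .. 2^10


@dataclass
class PredictionResult:
    scale: int
    accuracy_r: float
    predictions: np.ndarray
    fold_assignment: np.ndarray
    chosen_c: list[float]
    contributions: np.ndarray  # per-feature mean |linear weight|, standardized scale
    params: dict = field(default_factory=dict)
    p_spin: float | None = None
    p_rewired: float | None = None


def _fit_fold(
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_te: np.ndarray,
    c: float,
    epsilon: float,
) -> tuple[SVR, np.ndarray, np.ndarray]:
    """Fit one fold with train-only standardization of features *and* target.

    Z-scoring the target makes the epsilon-insensitive tube (default width
    0.1) scale-free, so maps in mm-scale units train as well as t-statistic
    maps; predictions are returned on the original scale.
    """
    scaler = StandardScaler().fit(x_tr)
    y_mu, y_sd = float(y_tr.mean()), float(y_tr.std())
    if y_sd == 0:
        y_sd = 1.0
    model = SVR(kernel="linear", C=c, epsilon=epsilon)
    model.fit(scaler.transform(x_tr), (y_tr - y_mu) / y_sd)
    preds = model.predict(scaler.transform(x_te)) * y_sd + y_mu
    weights = np.abs(np.asarray(model.coef_).ravel())
    return model, preds, weights


def _inner_select_c(
    x: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...],
    inner_folds: int,
    epsilon: float,
    seed: int,
) -> float:
    if len(c_grid) == 1:
        return float(c_grid[0])
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_c, best_score = float(c_grid[0]), -np.inf
    for c in c_grid:
        preds = np.empty_like(y)
        for tr, te in inner.split(x):
            _, fold_preds, _ = _fit_fold(x[tr], y[tr], x[te], c, epsilon)
            preds[te] = fold_preds
        if np.std(preds) == 0:
            score = -np.inf
        else:
            score = stats.pearsonr(y, preds).statistic
        if score > best_score:
            best_score, best_c = score, float(c)
    return best_c


def svr_predict_scale(
    profiles: DiffusionProfiles,
    map_values: np.ndarray,
    m: int,
    k_folds: int = 10,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
    inner_folds: int = 5,
    epsilon: float = 0.1,
    symmetrized: bool = True,
    drop_self: bool = False,
) -> PredictionResult:
    """Cross-validated linear SVR at one neighboring scale."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if not c_grid:
        raise ValueError("c_grid must be nonempty")
    y = np.asarray(map_values, float)
    if np.std(y) == 0:
        raise ValueError("constant target map: prediction accuracy undefined")
    x = profiles.profile(m, symmetrized=symmetrized).copy()
    if drop_self:
        np.fill_diagonal(x, 0.0)

    n = y.size
    outer = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    preds = np.empty(n)
    fold_assignment = np.empty(n, dtype=int)
    chosen_c: list[float] = []
    abs_weights = []
    for fold, (tr, te) in enumerate(outer.split(x)):
        c = _inner_select_c(x[tr], y[tr], tuple(c_grid), inner_folds, epsilon, seed + 1)
        _, fold_preds, weights = _fit_fold(x[tr], y[tr], x[te], c, epsilon)
        preds[te] = fold_preds
        fold_assignment[te] = fold
        chosen_c.append(c)
        abs_weights.append(weights)

    accuracy_r = float(stats.pearsonr(y, preds).statistic)
    return PredictionResult(
        scale=m,
        accuracy_r=accuracy_r,
        predictions=preds,
        fold_assignment=fold_assignment,
        chosen_c=chosen_c,
        contributions=np.mean(abs_weights, axis=0),
        params={
            "k_folds": k_folds,
            "c_grid": tuple(float(c) for c in c_grid),
            "seed": seed,
            "inner_folds": inner_folds,
            "epsilon": epsilon,
            "symmetrized": symmetrized,
            "drop_self": drop_self,
        },
    )


def feature_contributions(result: PredictionResult) -> np.ndarray:
    """Per-feature mean absolute linear SVR weight across outer folds."""
    return result.contributions


def prediction_significance(
    result: PredictionResult,
    map_values: np.ndarray,
    profiles: DiffusionProfiles,
    spin_ensemble: SurrogateEnsemble | None = None,
    rewired_ensemble: SurrogateEnsemble | None = None,
) -> PredictionResult:
    """Empirical p-values of the prediction accuracy against both nulls.

    The spin null re-runs the identical CV pipeline on each spun target map
    with empirical features; the rewired null recomputes scale-m profiles
    from each surrogate network and predicts the empirical target.
    """
    params = dict(result.params)
    m = result.scale

    def rerun(p: DiffusionProfiles, y: np.ndarray) -> float:
        return svr_predict_scale(
            p,
            y,
            m,
            k_folds=params["k_folds"],
            c_grid=params["c_grid"],
            seed=params["seed"],
            inner_folds=params["inner_folds"],
            epsilon=params["epsilon"],
            symmetrized=params["symmetrized"],
            drop_self=params["drop_self"],
        ).accuracy_r

    if spin_ensemble is not None:
        nulls = np.array([rerun(profiles, np.asarray(s, float)) for s in spin_ensemble])
        result.p_spin = empirical_p(result.accuracy_r, nulls, side="greater")
    if rewired_ensemble is not None:
        y = np.asarray(map_values, float)
        nulls = np.array(
            [
                rerun(diffusion_profiles(surrogate, max_scale=m), y)
                for surrogate in rewired_ensemble
            ]
        )
        result.p_rewired = empirical_p(result.accuracy_r, nulls, side="greater")
    return result
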