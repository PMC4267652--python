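"""Elastic-net arm: regress each HM on all CMs and pick the informative CMs.

Objective. Coefficients minimize the penalized residual sum of squares

    RSS(beta) + lam * [ (1 - alpha) * ||beta||_1 + (alpha / 2) * ||beta||_2^2 ]

with an unpenalized intercept. Note the mixing convention: ``alpha``
weights the *L2* component and ``1 - alpha`` the L1 component, so small
alpha means strong sparsity (the reverse of scikit-learn's ``l1_ratio``;
the mapping used internally is ``l1_ratio = 1 - alpha`` and sklearn's
``alpha = lam / (2 n)``). The quadratic component gives the grouping
effect: exactly duplicated predictors receive equal weights.

Model selection. ``alpha`` is chosen on a fixed grid by k-fold CV with a
one-standard-error rule: among all grid values whose best mean CV error is
within one SD (across folds, at the overall minimizer) of the minimum, the
smallest alpha — the most sparsity-inducing — wins. With alpha fixed, the
penalty strength is then optimized by inner CV along a path, per outer
fold, and coefficients are summarized across folds (mean, SD).

Selection rule. For one HM, a CM is reported as an interaction partner
when the magnitude of its cross-fold mean coefficient deviates upward
from the average magnitude over all CMs by at least one standard
deviation: |coef_mean| >= mu + sigma (computed on absolute values, so
activating and repressive interactions are treated symmetrically; a
``signed`` convention is also available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import DataError, ParameterError
from .signal_matrix import STATE_STANDARDIZED, SignalMatrix

logger = logging.getLogger(__name__)

#: grid over the mixing parameter (L2 weight); endpoints per the interval
#: [0.01, 0.99], interior points on a 0.1 lattice
DEFAULT_ALPHA_GRID = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)

#: number of penalty-path points for inner CV
N_PATH_ALPHAS = 50

#: folds of the inner CV that picks the penalty strength within each
#: outer training fold
INNER_PENALTY_FOLDS = 5


def _as_arrays(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in regression inputs")
    if X.ndim != 2 or y.ndim != 1 or len(X) != len(y):
        raise DataError("X must be 2-D and y 1-D with matching length")
    return X, y


def elastic_net_fit(
    X, y, alpha: float, penalty: float
) -> tuple[np.ndarray, float]:
    """Minimize RSS + penalty * [(1-alpha)||b||_1 + (alpha/2)||b||_2^2].

    Returns ``(coefficients, intercept)``. ``penalty`` is the overall
    strength ``lam`` (0 = OLS, inf = all-zero coefficients with the
    intercept at mean(y)). Deterministic.
    """
    X, y = _as_arrays(X, y)
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    if penalty < 0:
        raise ParameterError("penalty must be nonnegative")
    if np.isinf(penalty):
        return np.zeros(X.shape[1]), float(y.mean())
    n = len(y)
    model = ElasticNet(
        alpha=penalty / (2.0 * n),
        l1_ratio=1.0 - alpha,
        fit_intercept=True,
        max_iter=100_000,
        tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def elastic_net_objective(
    X, y, coef: np.ndarray, intercept: float, alpha: float, penalty: float
) -> float:
    """The penalized objective; used by optimality checks and reports."""
    X, y = _as_arrays(X, y)
    resid = y - intercept - X @ coef
    pen = (1.0 - alpha) * np.abs(coef).sum() + (alpha / 2.0) * np.square(coef).sum()
    return float(resid @ resid + penalty * pen)


def _cv_profile(
    X: np.ndarray, y: np.ndarray, grid, k: int, seed: int
) -> pd.DataFrame:
    """Best-on-path CV error per grid alpha.

    One ElasticNetCV run evaluates the whole penalty path for every mixing
    value on a shared fold assignment; for each alpha the path point with
    the smallest mean CV MSE is kept, together with the SD of the per-fold
    MSEs at that point.
    """
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=[1.0 - a for a in grid],
        alphas=N_PATH_ALPHAS,
        cv=cv,
        max_iter=20_000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    # mse_path_: (n_l1_ratio, n_path, n_folds)
    mean_path = model.mse_path_.mean(axis=2)
    sd_path = model.mse_path_.std(axis=2, ddof=1)
    best_idx = mean_path.argmin(axis=1)
    rows = []
    for i, a in enumerate(grid):
        j = best_idx[i]
        rows.append(
            {
                "alpha": a,
                "best_penalty": 2.0 * len(y) * model.alphas_[i][j],
                "mean_cv_mse": mean_path[i, j],
                "sd_cv_mse": sd_path[i, j],
            }
        )
    return pd.DataFrame(rows)


def select_alpha(
    X,
    y,
    grid=DEFAULT_ALPHA_GRID,
    k: int = 10,
    seed: int = 0,
    return_profile: bool = False,
):
    """Choose the mixing parameter by CV with a one-standard-error rule.

    Admissible values are those whose best mean CV error lies within one
    SD (across folds, taken at the overall minimizer) of the minimum; the
    smallest admissible alpha — largest L1 weight, hence sparsest — is
    returned. Ties resolve to the smaller alpha.
    """
    X, y = _as_arrays(X, y)
    grid = sorted(grid)
    if not grid:
        raise ParameterError("alpha grid is empty")
    if k > len(y):
        raise ParameterError(f"k={k} exceeds sample size {len(y)}")
    if len(grid) == 1:
        if return_profile:
            return grid[0], _cv_profile(X, y, grid, k, seed)
        return grid[0]
    profile = _cv_profile(X, y, grid, k, seed)
    i_min = int(profile["mean_cv_mse"].idxmin())
    threshold = profile.loc[i_min, "mean_cv_mse"] + profile.loc[i_min, "sd_cv_mse"]
    admissible = profile[profile["mean_cv_mse"] <= threshold]
    chosen = float(admissible["alpha"].min())
    if return_profile:
        return chosen, profile
    return chosen


def _inner_penalty_fit(
    X: np.ndarray, y: np.ndarray, alpha: float, seed: int
) -> tuple[np.ndarray, float, float]:
    """Fit with the penalty chosen by inner CV; returns (coef, icept, lam)."""
    cv = KFold(n_splits=INNER_PENALTY_FOLDS, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=1.0 - alpha,
        alphas=N_PATH_ALPHAS,
        cv=cv,
        max_iter=20_000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_), 2.0 * len(y) * model.alpha_


def cv_coefficient_summary(
    X,
    y,
    alpha: float,
    k: int = 10,
    seed: int = 0,
    predictor_names: list[str] | None = None,
):
    """Cross-fold coefficient statistics at a fixed mixing parameter.

    For each of ``k`` outer folds the model is fit on the training part
    (penalty strength chosen there by inner CV) and scored on the held-out
    part; returns per-predictor mean and SD of the coefficients across
    folds, the per-fold held-out R^2 and the per-fold penalties. Folds
    with a constant target are skipped with a warning.
    """
    X, y = _as_arrays(X, y)
    p = X.shape[1]
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(p)]
    from .expression_models import kfold_indices, _heldout_r2

    folds = kfold_indices(len(y), k, seed)
    coefs, r2s, penalties = [], [], []
    for f, held_out in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), held_out)
        if np.std(y[train]) == 0.0:
            logger.warning("fold %d has a constant target; skipped", f)
            continue
        coef, icept, lam = _inner_penalty_fit(
            X[train], y[train], alpha, seed=seed + 1000 + f
        )
        coefs.append(coef)
        penalties.append(lam)
        pred = icept + X[held_out] @ coef
        r2s.append(_heldout_r2(y[held_out], pred))
    if not coefs:
        raise DataError("every fold had a constant target")
    coefs = np.asarray(coefs)
    coef_mean = pd.Series(coefs.mean(axis=0), index=predictor_names)
    coef_sd = pd.Series(coefs.std(axis=0, ddof=1 if len(coefs) > 1 else 0),
                        index=predictor_names)
    return coef_mean, coef_sd, r2s, penalties


def select_predictors(
    coef_mean: pd.Series, convention: str = "absolute"
) -> set[tuple[str, str]]:
    """Deviation rule: keep predictors whose mean coefficient stands out.

    With the (default) absolute convention, let mu and sigma be the mean
    and SD of |coef_mean| over all predictors; a predictor is selected iff
    |coef_mean| >= mu + sigma and sigma > 0, and reported with the sign of
    its mean coefficient. The ``signed`` convention applies the same rule
    to the signed values.
    """
    if len(coef_mean) < 2:
        raise ParameterError("need at least 2 predictors for the deviation rule")
    if convention == "absolute":
        stats = coef_mean.abs()
    elif convention == "signed":
        stats = coef_mean
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    mu = float(stats.mean())
    sigma = float(stats.std(ddof=1))
    # floating-point-degenerate spread counts as zero: nothing stands out
    if not np.isfinite(sigma) or sigma <= 1e-12 * max(1.0, float(stats.abs().max())):
        return set()
    chosen = stats[stats >= mu + sigma].index if convention == "absolute" else \
        coef_mean[np.abs(coef_mean - mu) >= sigma].index
    return {
        (name, "+" if coef_mean[name] >= 0 else "-") for name in chosen
    }


@dataclass
class ElasticNetSelection:
    """Per-HM result of the elastic-net arm."""

    target_hm: str
    alpha: float
    penalty_t: float  # median of the per-fold inner-CV penalties
    coef_mean: pd.Series
    coef_sd: pd.Series
    selected: set[tuple[str, str]]  # (CM, sign)
    cv_r2: float
    per_fold_r2: list[float]
    seed: int

    def report_table(self) -> pd.DataFrame:
        selected_names = {cm for cm, _ in self.selected}
        return pd.DataFrame(
            {
                "cm": self.coef_mean.index,
                "coef_mean": self.coef_mean.values,
                "coef_sd": self.coef_sd.values,
                "selected": [c in selected_names for c in self.coef_mean.index],
                "sign": [
                    "+" if v >= 0 else "-" for v in self.coef_mean.values
                ],
            }
        )


def run_elastic_net_arm(
    matrix: SignalMatrix,
    k: int = 10,
    seed: int = 0,
    grid=DEFAULT_ALPHA_GRID,
    convention: str = "absolute",
) -> dict[str, ElasticNetSelection]:
    """Regress every HM on all CMs; return the per-HM selections."""
    matrix._require_state(STATE_STANDARDIZED, "run_elastic_net_arm")
    cms = matrix.cm_tracks
    results: dict[str, ElasticNetSelection] = {}
    X = matrix.data[cms].to_numpy()
    for hm in matrix.hm_tracks:
        y = matrix.data[hm].to_numpy()
        alpha = select_alpha(X, y, grid=grid, k=k, seed=seed)
        coef_mean, coef_sd, r2s, penalties = cv_coefficient_summary(
            X, y, alpha, k=k, seed=seed, predictor_names=cms
        )
        selected = select_predictors(coef_mean, convention=convention)
        results[hm] = ElasticNetSelection(
            target_hm=hm,
            alpha=alpha,
            penalty_t=float(np.median(penalties)),
            coef_mean=coef_mean,
            coef_sd=coef_sd,
            selected=selected,
            cv_r2=float(np.nanmean(r2s)),
            per_fold_r2=r2s,
            seed=seed,
        )
        logger.info(
            "EN arm %s: alpha=%.2f, cv R2=%.3f, selected %s",
            hm,
            alpha,
            results[hm].cv_r2,
            sorted(cm for cm, _ in selected),
        )
    return results
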