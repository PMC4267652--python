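"""Cross-validated linear prediction of marks, modifiers and expression.

Ordinary least squares with k-fold cross-validation is used to quantify
how much variance in a target track (an HM, a CM or expression) a set of
predictor tracks explains. Held-out R^2 is computed per fold as
``1 - RSS/TSS`` with the total sum of squares centered on the held-out
fold's own mean, so a useless model scores near (or below) zero. The same
machinery evaluates cross-condition transfer: fit once on one "cell
type", score on the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .signal_matrix import STATE_STANDARDIZED, SignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 10


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k near-equal folds."""
    if k < 2:
        raise ParameterError("need at least 2 folds")
    if n < k:
        raise ParameterError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit with intercept; least-norm solution if singular."""
    design = np.column_stack([np.ones(len(X)), X])
    coef, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "singular design (rank %d < %d); least-norm solution used",
            rank,
            design.shape[1],
        )
    return coef


def _heldout_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 with TSS centered on the evaluation set's own mean."""
    rss = float(np.sum((y_true - y_pred) ** 2))
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0.0:
        return float("nan")
    return 1.0 - rss / tss


@dataclass
class RegressionReport:
    """Cross-validated fit of one target on one predictor set."""

    target: str
    predictor_set: list[str]
    per_fold_r2: list[float]
    mean_r2: float
    coefficients: dict[str, float]  # fit on the full data, intercept included
    fold_assignment_seed: int


def fit_predict_cv(
    matrix: SignalMatrix,
    target: str,
    predictors: list[str],
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> RegressionReport:
    """OLS prediction of ``target`` from ``predictors`` under k-fold CV.

    ``folds`` may be passed explicitly so several predictor sets can be
    compared on identical partitions; otherwise a seeded random partition
    is drawn.
    """
    matrix._require_state(STATE_STANDARDIZED, "fit_predict_cv")
    if target in predictors:
        raise ParameterError(f"target {target!r} cannot be its own predictor")
    missing = [t for t in [target, *predictors] if t not in matrix.data.columns]
    if missing:
        raise SchemaError(f"tracks missing from matrix: {missing}")
    X = matrix.data[list(predictors)].to_numpy()
    y = matrix.data[target].to_numpy()
    if folds is None:
        folds = kfold_indices(len(y), k, seed)
    elif len(folds) != k:
        raise ParameterError("provided folds do not match k")

    per_fold = []
    for held_out in folds:
        train = np.setdiff1d(np.arange(len(y)), held_out, assume_unique=False)
        coef = _ols(X[train], y[train])
        pred = np.column_stack([np.ones(len(held_out)), X[held_out]]) @ coef
        per_fold.append(_heldout_r2(y[held_out], pred))

    full_coef = _ols(X, y)
    coefficients = {"(intercept)": float(full_coef[0])}
    coefficients.update(
        {p: float(c) for p, c in zip(predictors, full_coef[1:])}
    )
    return RegressionReport(
        target=target,
        predictor_set=list(predictors),
        per_fold_r2=per_fold,
        mean_r2=float(np.nanmean(per_fold)),
        coefficients=coefficients,
        fold_assignment_seed=seed,
    )


def transfer_evaluate(
    train: SignalMatrix,
    test: SignalMatrix,
    target: str,
    predictors: list[str],
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> tuple[float, float]:
    """Within-condition CV R^2 and cross-condition transfer R^2.

    The model is fit once on every promoter of the training condition and
    scored on the test condition (each matrix standardized on its own);
    the returned pair is ``(train_cv_r2, transfer_r2)``.
    """
    for name, sm in (("train", train), ("test", test)):
        sm._require_state(STATE_STANDARDIZED, f"transfer_evaluate ({name})")
    missing = [
        t for t in [target, *predictors] if t not in test.data.columns
    ]
    if missing:
        raise SchemaError(f"tracks missing from test matrix: {missing}")

    report = fit_predict_cv(train, target, predictors, k=k, seed=seed)
    X_train = train.data[list(predictors)].to_numpy()
    y_train = train.data[target].to_numpy()
    coef = _ols(X_train, y_train)
    X_test = test.data[list(predictors)].to_numpy()
    pred = np.column_stack([np.ones(len(X_test)), X_test]) @ coef
    transfer_r2 = _heldout_r2(test.data[target].to_numpy(), pred)
    return report.mean_r2, transfer_r2


@dataclass
class RedundancyReport:
    """Expression variance explained by HMs, CMs and both together."""

    table: pd.DataFrame  # columns: predictor_set, n_predictors, mean_r2
    differences: dict[str, float]  # pairwise mean-R^2 differences
    reports: dict[str, RegressionReport]


def redundancy_report(
    matrix: SignalMatrix,
    expression: str,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> RedundancyReport:
    """Compare HM-only, CM-only and joint prediction of expression.

    All three models share one fold assignment so the R^2 comparison is
    paired. If HMs and CMs carry redundant information about expression,
    the joint model improves only marginally on either alone.
    """
    matrix._require_state(STATE_STANDARDIZED, "redundancy_report")
    hms, cms = matrix.hm_tracks, matrix.cm_tracks
    if not hms or not cms:
        raise SchemaError("need both HM and CM tracks for a redundancy report")
    if expression not in matrix.data.columns:
        raise SchemaError(f"expression track {expression!r} not in matrix")

    folds = kfold_indices(len(matrix.data), k, seed)
    sets = {"HM": hms, "CM": cms, "HM+CM": hms + cms}
    reports = {
        label: fit_predict_cv(
            matrix, expression, tracks, k=k, seed=seed, folds=folds
        )
        for label, tracks in sets.items()
    }
    table = pd.DataFrame(
        {
            "predictor_set": list(sets),
            "n_predictors": [len(v) for v in sets.values()],
            "mean_r2": [reports[label].mean_r2 for label in sets],
        }
    )
    labels = list(sets)
    differences = {
        f"{a}-{b}": reports[a].mean_r2 - reports[b].mean_r2
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    return RedundancyReport(table=table, differences=differences, reports=reports)
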