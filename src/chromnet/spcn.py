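"""Sparse partial-correlation network over HM and CM tracks.

The partial correlation between two tracks, conditioned on every other
track in the data set, is the correlation of their residuals after both
are regressed on the remaining tracks. For the full matrix of pairwise
partial correlations this is computed at once from the precision matrix
(the inverse of the sample covariance) Omega:

    pcor(i, j) = -Omega_ij / sqrt(Omega_ii * Omega_jj)

Signals are rank-transformed first (average ranks on ties), making the
statistics a conditional analogue of Spearman correlation, robust to the
heavy tails of ChIP-Seq enrichment.

Significance uses the Fisher z-transform with effective degrees of
freedom ``n - (p - 2) - 3`` (p - 2 variables conditioned on), a two-sided
normal p-value, and Benjamini-Hochberg q-values across all pairs.

Sparsification is a conservative k-fold scheme: partial correlations,
ranks and q-values are recomputed within each training fold, and an edge
is retained only when it is significant (q below the threshold) in every
fold with a fold-consistent sign — and significant on the full data, so
the retained set is a subset of the significant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError, SchemaError
from .signal_matrix import ROLE_CM, ROLE_HM, SignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.05

#: relative ridge added to a near-singular covariance (times mean diagonal)
RIDGE_EPS = 1e-6

#: condition-number threshold above which the ridge kicks in
COND_THRESHOLD = 1e10


def _values(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, SignalMatrix):
        cols = data.chip_tracks
        return data.data[cols].to_numpy(dtype=float), cols
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def rank_transform(data) -> pd.DataFrame:
    """Columnwise ranks 1..n, ties sharing their average rank."""
    values, names = _values(data)
    if not np.all(np.isfinite(values)):
        raise DataError("rank_transform requires finite values")
    ranks = np.column_stack(
        [stats.rankdata(values[:, j], method="average") for j in range(values.shape[1])]
    )
    index = (
        data.data.index
        if isinstance(data, SignalMatrix)
        else (data.index if isinstance(data, pd.DataFrame) else range(len(values)))
    )
    return pd.DataFrame(ranks, columns=names, index=index)


def partial_correlation_matrix(data) -> pd.DataFrame:
    """All pairwise partial correlations from the inverse covariance.

    Requires more observations than variables. A covariance with condition
    number above ``COND_THRESHOLD`` is ridge-regularized (``RIDGE_EPS``
    times the mean diagonal added) with a warning.
    """
    values, names = _values(data)
    n, p = values.shape
    if n <= p:
        raise DataError(
            f"need more observations than variables (n={n}, p={p}); "
            "reduce the variable set"
        )
    cov = np.cov(values, rowvar=False, ddof=1)
    if np.linalg.cond(cov) > COND_THRESHOLD:
        eps = RIDGE_EPS * float(np.mean(np.diag(cov)))
        logger.warning(
            "covariance near-singular; adding ridge %.3g to the diagonal", eps
        )
        cov = cov + eps * np.eye(p)
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return pd.DataFrame(pcor, index=names, columns=names)


def partial_correlation_residual(x, y, Z) -> float:
    """Residual-regression definition of the partial correlation.

    Regress x and y separately on the control set Z (with intercept) and
    correlate the residuals. Quadratic per pair — used as the independent
    cross-check of the precision-matrix route.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    design = np.column_stack([np.ones(len(x)), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def edge_significance(pcor: pd.DataFrame, n: int) -> pd.DataFrame:
    """Fisher-z p-values and BH q-values for every variable pair.

    Degrees of freedom are ``n - (p - 2) - 3``: the usual Fisher-z count
    reduced by the p - 2 variables in the control set.
    """
    p = pcor.shape[0]
    df_eff = n - (p - 2) - 3
    if df_eff <= 0:
        raise ParameterError(
            f"sample size n={n} too small for p={p} variables"
        )
    names = list(pcor.columns)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            rho = float(np.clip(pcor.iloc[i, j], -1 + 1e-15, 1 - 1e-15))
            z = np.arctanh(rho) * np.sqrt(df_eff)
            pval = 2.0 * stats.norm.sf(abs(z))
            rows.append({"var1": names[i], "var2": names[j], "rho": rho, "p": pval})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def sparsify_cv(
    data,
    k: int = 10,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> tuple[set[tuple[frozenset, str]], pd.DataFrame]:
    """Retain edges significant with a consistent sign in every CV fold.

    Ranks are recomputed within each training portion (no leakage from
    held-out promoters). Returns the retained edge set — elements are
    ``(frozenset({a, b}), sign)`` — and the per-pair fold bookkeeping
    (``folds_retained`` = folds where q <= threshold, and the fold signs).
    An explicit fold partition may be supplied instead of the seeded one.
    """
    from .expression_models import kfold_indices

    values, names = _values(data)
    n, p = values.shape
    if folds is None:
        folds = kfold_indices(n, k, seed)
    else:
        k = len(folds)
    all_idx = np.arange(n)
    sig_counts: dict[tuple[str, str], int] = {}
    signs: dict[tuple[str, str], list[float]] = {}
    for held_out in folds:
        train = np.setdiff1d(all_idx, held_out)
        if len(train) <= p:
            raise ParameterError(
                f"training fold of {len(train)} rows too small for p={p}"
            )
        ranked = rank_transform(pd.DataFrame(values[train], columns=names))
        pcor = partial_correlation_matrix(ranked)
        table = edge_significance(pcor, len(train))
        for _, row in table.iterrows():
            key = (row["var1"], row["var2"])
            signs.setdefault(key, []).append(np.sign(row["rho"]))
            if row["q"] <= q_threshold:
                sig_counts[key] = sig_counts.get(key, 0) + 1

    retained: set[tuple[frozenset, str]] = set()
    records = []
    for key, fold_signs in signs.items():
        count = sig_counts.get(key, 0)
        consistent = len(set(fold_signs)) == 1 and fold_signs[0] != 0
        keep = count == k and consistent
        records.append(
            {
                "var1": key[0],
                "var2": key[1],
                "folds_retained": count,
                "sign_consistent": consistent,
                "retained": keep,
            }
        )
        if keep:
            retained.add((frozenset(key), "+" if fold_signs[0] > 0 else "-"))
    return retained, pd.DataFrame(records)


@dataclass
class PartialCorrelationNetwork:
    """Full partial-correlation matrix plus the sparsified edge set."""

    variables: list[str]
    pcor: pd.DataFrame
    edge_tests: pd.DataFrame  # var1, var2, rho, p, q, folds_retained
    retained_edges: set[tuple[frozenset, str]]
    n_samples: int
    k: int
    q_threshold: float
    seed: int


def build_spcn(
    matrix: SignalMatrix,
    k: int = 10,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    seed: int = 0,
) -> PartialCorrelationNetwork:
    """The SPCN over all HM and CM tracks of a standardized matrix.

    Full-data ranks feed the reported partial-correlation matrix and the
    significance table; the retained set additionally requires all-fold
    significance with consistent sign (and full-data significance, keeping
    it a subset of the significant pairs).
    """
    chip = matrix.chip_tracks
    if len(chip) < 3:
        raise SchemaError("SPCN needs at least 3 HM/CM tracks")
    frame = matrix.data[chip]
    ranked = rank_transform(frame)
    pcor = partial_correlation_matrix(ranked)
    tests = edge_significance(pcor, len(frame))
    cv_retained, fold_table = sparsify_cv(
        frame, k=k, q_threshold=q_threshold, seed=seed
    )
    tests = tests.merge(
        fold_table[["var1", "var2", "folds_retained", "sign_consistent"]],
        on=["var1", "var2"],
        how="left",
    )
    significant = {
        frozenset((r["var1"], r["var2"]))
        for _, r in tests.iterrows()
        if r["q"] <= q_threshold
    }
    retained = {
        (pair, sign) for pair, sign in cv_retained if pair in significant
    }
    return PartialCorrelationNetwork(
        variables=chip,
        pcor=pcor,
        edge_tests=tests,
        retained_edges=retained,
        n_samples=len(frame),
        k=k,
        q_threshold=q_threshold,
        seed=seed,
    )


@dataclass(frozen=True)
class BipartiteEdge:
    """A retained CM-HM edge with its full-data partial correlation."""

    cm: str
    hm: str
    rho: float
    sign: str


def extract_hm_cm_edges(
    network: PartialCorrelationNetwork, roles: dict[str, str]
) -> list[BipartiteEdge]:
    """Filter the retained edges to CM-HM pairs (one endpoint each)."""
    edges = []
    for pair, sign in network.retained_edges:
        a, b = sorted(pair)
        role_a, role_b = roles.get(a), roles.get(b)
        if {role_a, role_b} != {ROLE_HM, ROLE_CM}:
            continue
        cm, hm = (a, b) if role_a == ROLE_CM else (b, a)
        rho = float(network.pcor.loc[cm, hm])
        edges.append(BipartiteEdge(cm=cm, hm=hm, rho=rho, sign=sign))
    return sorted(edges, key=lambda e: (e.hm, e.cm))
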