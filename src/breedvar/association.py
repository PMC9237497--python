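"""Trait association: Spearman correlation matrices and path-coefficient
decomposition of yield into direct and indirect effects.

Path analysis solves Rxx b = rxy for the direct effects b (standardized
path coefficients), splits each predictor's total correlation with yield
into its direct effect plus indirect effects through the other predictors
(I[i,j] = r_ij * b_j), and reports the residual path
E1 = sqrt(1 - sum_i b_i r_iy).  By default the decomposition is built on
Pearson correlations — the identities r_iy = b_i + sum_j I[i,j] only hold
when b is solved against the same matrix that produced rxy — with Spearman
selectable for rank-based input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

#: Significance stars, highest threshold first.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric trait correlation matrix with p-values and star annotations.

    ``flagged`` lists trait pairs whose coefficient is undefined (a constant
    trait has no rank variance); those cells hold NaN rather than a silent 0.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    flagged: tuple[tuple[str, str], ...] = ()


def _stars(p: float) -> str:
    for threshold, symbol in STAR_LEVELS:
        if p < threshold:
            return symbol
    return ""


def spearman_matrix(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    level: str = "line",
) -> CorrelationMatrix:
    """Spearman rank correlations among traits with significance stars.

    ``table`` is a long-format trait table (already subset to one variety /
    generation as desired).  ``level`` chooses the observational unit:
    ``"line"`` correlates per-line means (pooled over treatments),
    ``"population"`` correlates per-treatment means, and ``"plot"`` uses raw
    replicate values.  P-values use the t approximation on n-2 df; the
    diagonal is exactly 1 with no star computation.
    """
    keys = {
        "line": ["variety", "generation", "treatment", "line"],
        "population": ["variety", "generation", "treatment"],
        "plot": ["variety", "generation", "treatment", "line", "replicate"],
    }
    if level not in keys:
        raise ValueError(f"unknown level {level!r}")
    wide = (
        table.groupby(keys[level] + ["trait"])["value"].mean().unstack("trait")
    )
    if traits is not None:
        missing = [t for t in traits if t not in wide.columns]
        if missing:
            raise ValueError(f"traits absent from table: {missing}")
        wide = wide[traits]
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >= 3 observations for correlation, got {n}")
    cols = list(wide.columns)
    m = len(cols)
    rho = np.eye(m)
    pmat = np.zeros((m, m))
    flagged = []
    values = wide.to_numpy()
    constant = [bool(np.ptp(values[:, j]) == 0) for j in range(m)]
    for i in range(m):
        for j in range(i + 1, m):
            if constant[i] or constant[j]:
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                flagged.append((cols[i], cols[j]))
                continue
            r = float(stats.spearmanr(values[:, i], values[:, j]).statistic)
            rho[i, j] = rho[j, i] = r
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * float(stats.t.sf(abs(t), n - 2))
            pmat[i, j] = pmat[j, i] = p
    stars = pd.DataFrame("", index=cols, columns=cols)
    for i in range(m):
        for j in range(m):
            if i != j and np.isfinite(pmat[i, j]):
                stars.iloc[i, j] = _stars(pmat[i, j])
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pmat, index=cols, columns=cols),
        stars=stars,
        n=n,
        flagged=tuple(flagged),
    )


@dataclass(frozen=True)
class PathResult:
    """Direct effects, indirect-effect matrix, and the residual path E1."""

    predictors: tuple[str, ...]
    direct: pd.Series
    indirect: pd.DataFrame  # I[i, j] = r_ij * b_j for j != i, 0 on diagonal
    total_correlation: pd.Series  # r_iy
    residual: float  # E1
    residual_clipped: bool
    ranking: tuple[str, ...]  # by |direct effect|, descending, ties by label


def solve_path(
    rxx: pd.DataFrame,
    rxy: pd.Series,
    rcond_threshold: float = 1e-10,
    ranking: str = "absolute",
) -> PathResult:
    """Solve the path equations Rxx b = rxy and decompose the correlations.

    ``rxx`` must be symmetric positive definite within tolerance (its
    reciprocal condition number at least ``rcond_threshold``), otherwise an
    error suggests removing a redundant trait.  The residual path is
    E1 = sqrt(max(0, 1 - sum b_i r_iy)); when the clip engages,
    ``residual_clipped`` flags that the decomposition over-explains unit
    variance.
    """
    labels = tuple(rxx.index)
    if list(rxx.columns) != list(labels) or list(rxy.index) != list(labels):
        raise ValueError("rxx/rxy labels must agree")
    R = rxx.to_numpy(dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rxx must be symmetric")
    rcond = 1.0 / float(np.linalg.cond(R))
    if not np.isfinite(rcond) or rcond < rcond_threshold:
        raise ValueError(
            "predictor correlation matrix is singular or near-singular "
            f"(reciprocal condition number {rcond:.3g}); remove a redundant trait"
        )
    r = rxy.to_numpy(dtype=float)
    b = np.linalg.solve(R, r)
    indirect = R * b[np.newaxis, :]
    np.fill_diagonal(indirect, 0.0)
    explained = float(b @ r)
    clipped = explained > 1.0
    residual = math.sqrt(max(0.0, 1.0 - explained))
    order = sorted(labels, key=lambda lab: (-abs(b[labels.index(lab)]), lab))
    return PathResult(
        predictors=labels,
        direct=pd.Series(b, index=list(labels), name="direct"),
        indirect=pd.DataFrame(indirect, index=list(labels), columns=list(labels)),
        total_correlation=pd.Series(r, index=list(labels), name="r_iy"),
        residual=residual,
        residual_clipped=clipped,
        ranking=tuple(order),
    )


class PathAnalysis(BaseEstimator):
    """Path-coefficient analysis of yield on its component traits.

    A scikit-learn style estimator: ``fit(X, y)`` takes the component-trait
    matrix (DataFrame or array, one row per line or population) and the
    yield vector, forms the predictor correlation matrix and the
    predictor-yield correlations with the chosen ``method``, and solves the
    path equations.

    Parameters
    ----------
    method : {"pearson", "spearman"}
        Correlation type feeding the decomposition (Pearson by default, so
        the reconstruction identities hold on the same scale the effects
        are reported on).
    rcond_threshold : float
        Reject predictor matrices whose reciprocal condition number falls
        below this.

    Attributes (after fit)
    ----------------------
    direct_effects_ : pd.Series        standardized path coefficients b
    indirect_effects_ : pd.DataFrame   I[i, j] = r_ij * b_j (diagonal 0)
    total_correlations_ : pd.Series    r_iy
    residual_ : float                  E1
    residual_clipped_ : bool
    ranking_ : tuple[str, ...]         predictors by |direct|, descending
    """

    def __init__(self, method: str = "pearson", rcond_threshold: float = 1e-10):
        self.method = method
        self.rcond_threshold = rcond_threshold

    def fit(self, X, y):
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        X = pd.DataFrame(X).copy()
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 3:
            raise ValueError("need >= 3 observations")
        X.columns = [str(c) for c in X.columns]
        if self.method == "spearman":
            X = X.rank()
            y = stats.rankdata(y)
        rxx = X.corr(method="pearson")
        rxy = pd.Series(
            [float(np.corrcoef(X[c], y)[0, 1]) for c in X.columns],
            index=X.columns,
        )
        result = solve_path(rxx, rxy, rcond_threshold=self.rcond_threshold)
        self.predictors_ = result.predictors
        self.direct_effects_ = result.direct
        self.indirect_effects_ = result.indirect
        self.total_correlations_ = result.total_correlation
        self.residual_ = result.residual
        self.residual_clipped_ = result.residual_clipped
        self.ranking_ = result.ranking
        self.result_ = result
        return self


def path_analysis(rxx: pd.DataFrame, rxy: pd.Series, **kwargs) -> PathResult:
    """Thin functional wrapper over :func:`solve_path` (correlation input)."""
    return solve_path(rxx, rxy, **kwargs)


def contribution_ranking(path: PathResult, criterion: str = "signed") -> tuple[str, ...]:
    """Predictors in increasing order of direct effect.

    ``criterion="signed"`` orders by the signed coefficient (matching the
    "<" chains of a trait-contribution narrative); ``"absolute"`` orders by
    magnitude.  Ties break lexicographically by label.
    """
    b = path.direct
    if criterion == "signed":
        key = lambda lab: (float(b[lab]), lab)
    elif criterion == "absolute":
        key = lambda lab: (abs(float(b[lab])), lab)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return tuple(sorted(path.predictors, key=key))
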