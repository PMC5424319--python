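"""Rank-based (partial) correlation with analytic and permutation P values.

Both correlation families are driven by one covariance construction.  For
a data matrix X with columns x_1..x_p:

* Spearman: columns are replaced by average ranks and the Pearson
  covariance c_ij = (1/n) sum_k (x_ik - mu_i)(x_jk - mu_j) is taken over
  the ranked columns.
* Kendall: the sign covariance
  c_ij = sum_k sum_l sign(x_ik - x_il) * sign(x_jk - x_jl)
  with sign(0) = 0.  The marginal ratio c_xy / sqrt(c_xx c_yy) is then
  algebraically identical to the tie-corrected tau-b (each unordered pair
  is counted twice in both numerator and denominator).

The partial correlation of x_i and x_j given all remaining columns comes
from the inverse covariance matrix D = C^-1:

    r_ij|S = -d_ij / (sqrt(d_ii) * sqrt(d_jj))

which for p = 2 reduces to the marginal coefficient.  Analytic P values
use a t statistic r*sqrt((n-2-k)/(1-r^2)) with n-2-k degrees of freedom
for Spearman and a normal statistic
r / sqrt(2*(2*(n-k)+5) / (9*(n-k)*(n-1-k))) for Kendall, where k is the
number of controlled covariates.

Permutation P values permute the predictor column (outcome and covariates
fixed), recompute the partial coefficient each time, and report
(B+1)/(N+1) where B counts permutations at least as extreme as the
observed value under the configured tail (default: two-sided on the
absolute coefficient).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("codonpairs")

METHODS = ("spearman", "kendall")

#: Permutations over Kendall partials cost O(n^2) per covariance entry;
#: above this operation budget N is reduced with a logged warning.
KENDALL_OP_BUDGET = 2e10


@dataclass(frozen=True)
class PermutationConfig:
    """Number of permutations, RNG seed, and tail of the permutation test."""

    n_permutations: int = 10000
    seed: int = 0
    tail: str = "two_sided_abs"  # or "greater" / "less"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail not in ("two_sided_abs", "greater", "less"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class AssociationResult:
    """One tested association between a predictor and an outcome."""

    method: str
    predictor: str
    outcome: str
    covariates: tuple[str, ...]
    coefficient: float
    analytic_p: float
    permutation_p: float | None
    n: int


@dataclass
class CovarianceModel:
    """A covariance matrix over named variables and its (lazy) inverse."""

    method: str
    names: tuple[str, ...]
    matrix: np.ndarray
    _inverse: np.ndarray | None = field(default=None, repr=False)

    @property
    def inverse(self) -> np.ndarray:
        if self._inverse is None:
            self._inverse = _safe_inverse(self.matrix, self.names)
        return self._inverse


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _safe_inverse(C: np.ndarray, names: Sequence[str]) -> np.ndarray:
    if not np.all(np.isfinite(C)) or np.linalg.cond(C) > 1e12:
        corr = _nearest_collinear(C, names)
        raise SingularCovarianceError(
            f"covariance matrix is singular or ill-conditioned; "
            f"most collinear columns: {corr}"
        )
    return np.linalg.inv(C)


def _nearest_collinear(C: np.ndarray, names: Sequence[str]) -> tuple[str, str]:
    d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
    return (names[i], names[j])


# --- covariance construction -------------------------------------------

def _rank_columns(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, X)


def _sign_matrix(x: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - x[None, :]).astype(np.int8)


def covariance_matrix(
    X: np.ndarray,
    method: str,
    names: Sequence[str] | None = None,
) -> CovarianceModel:
    """Build the Spearman (rank-Pearson) or Kendall (sign) covariance.

    X is an n x p matrix with no missing values (callers perform listwise
    deletion first); n must exceed p.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"insufficient observations: n={n} <= p={p}")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; apply listwise deletion first")
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(p))
    if method == "spearman":
        Z = _rank_columns(X)
        Z = Z - Z.mean(axis=0)
        C = (Z.T @ Z) / n
    elif method == "kendall":
        signs = [_sign_matrix(X[:, i]) for i in range(p)]
        C = np.empty((p, p))
        for i in range(p):
            for j in range(i, p):
                C[i, j] = C[j, i] = float(
                    np.sum(signs[i] * signs[j], dtype=np.int64)
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    if (np.diag(C) <= 0).any():
        idx = int(np.argmin(np.diag(C)))
        logger.warning("constant column %s: zero variance", names[idx])
    return CovarianceModel(method=method, names=names, matrix=C)


def _partial_from_inverse(D: np.ndarray, i: int, j: int) -> float:
    return float(-D[i, j] / np.sqrt(D[i, i] * D[j, j]))


# --- analytic P values --------------------------------------------------

def _analytic_p(r: float, n: int, k: int, method: str) -> float:
    if not np.isfinite(r):
        return float("nan")
    if method == "spearman":
        df = n - 2 - k
        if df <= 0:
            return float("nan")
        if abs(r) >= 1.0:
            return 0.0
        t = r * np.sqrt(df / (1.0 - r * r))
        return float(2.0 * stats.t.sf(abs(t), df))
    elif method == "kendall":
        m = n - k
        if m < 2:
            return float("nan")
        se = np.sqrt(2.0 * (2.0 * m + 5.0) / (9.0 * m * (m - 1.0)))
        return float(2.0 * stats.norm.sf(abs(r) / se))
    raise ValueError(f"unknown method {method!r}")


# --- marginal and partial coefficients ----------------------------------

def _drop_missing(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return tuple(c[mask] for c in cols)


def spearman_corr(
    x: Sequence[float], y: Sequence[float],
    predictor: str = "x", outcome: str = "y",
) -> AssociationResult:
    """Marginal Spearman correlation with a t-based analytic P value."""
    return _marginal(x, y, "spearman", predictor, outcome)


def kendall_corr(
    x: Sequence[float], y: Sequence[float],
    predictor: str = "x", outcome: str = "y",
) -> AssociationResult:
    """Marginal Kendall correlation from the sign covariance."""
    return _marginal(x, y, "kendall", predictor, outcome)


def _marginal(x, y, method, predictor, outcome) -> AssociationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    x, y = _drop_missing(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 after missing removal, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input to %s correlation; coefficient missing", method)
        return AssociationResult(method, predictor, outcome, (), float("nan"),
                                 float("nan"), None, n)
    model = covariance_matrix(np.column_stack([x, y]), method)
    C = model.matrix
    r = float(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]))
    return AssociationResult(
        method, predictor, outcome, (), r, _analytic_p(r, n, 0, method), None, n
    )


def partial_correlation(
    X: np.ndarray | pd.DataFrame,
    i: int = 0,
    j: int = 1,
    method: str = "spearman",
    names: Sequence[str] | None = None,
) -> AssociationResult:
    """Partial correlation of columns i, j given all other columns of X.

    Computed as r_ij|S = -d_ij / sqrt(d_ii d_jj) from the inverse of the
    method's covariance matrix; with p = 2 this equals the marginal
    coefficient.
    """
    if isinstance(X, pd.DataFrame):
        names = names or tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = tuple(names) if names is not None else tuple(f"x{k}" for k in range(p))
    model = covariance_matrix(X, method, names)
    r = _partial_from_inverse(model.inverse, i, j)
    k = p - 2
    covs = tuple(names[m] for m in range(p) if m not in (i, j))
    return AssociationResult(
        method, names[i], names[j], covs, r, _analytic_p(r, n, k, method), None, n
    )


# --- permutation machinery ----------------------------------------------

def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable per-association child seed below 2^31."""
    key = "\x1f".join([str(master_seed)] + [repr(p) for p in parts])
    digest = hashlib.blake2s(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _count_exceedances(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    eps = 1e-12
    if tail == "two_sided_abs":
        return int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))
    if tail == "greater":
        return int(np.sum(r_perm >= r_obs - eps))
    return int(np.sum(r_perm <= r_obs + eps))


def permutation_p(
    X: np.ndarray | pd.DataFrame,
    i: int = 0,
    j: int = 1,
    method: str = "spearman",
    config: PermutationConfig | None = None,
) -> float:
    """Permutation P value for the (partial) correlation of columns i, j.

    Column i (the predictor) is permuted; the outcome and covariates stay
    fixed and the partial coefficient is recomputed each round.  Returns
    (B+1)/(N+1).  The result is fully determined by ``config.seed``.
    """
    config = config or PermutationConfig()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    N = config.n_permutations
    if method == "kendall":
        est_ops = float(N) * p * n * n
        if est_ops > KENDALL_OP_BUDGET:
            N = max(100, int(KENDALL_OP_BUDGET / (p * n * n)))
            logger.warning(
                "Kendall permutation budget exceeded (n=%d, p=%d); "
                "reducing N from %d to %d", n, p, config.n_permutations, N,
            )
    rng = np.random.default_rng(config.seed)
    if method == "spearman":
        r_obs, r_perm = _permute_spearman(X, i, j, N, rng)
    elif method == "kendall":
        r_obs, r_perm = _permute_kendall(X, i, j, N, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    B = _count_exceedances(r_perm, r_obs, config.tail)
    return (B + 1) / (N + 1)


def _permute_spearman(X, i, j, N, rng):
    n, p = X.shape
    Z = _rank_columns(X)
    Z = Z - Z.mean(axis=0)
    C = (Z.T @ Z) / n
    names = tuple(f"x{m}" for m in range(p))
    D = _safe_inverse(C, names)
    r_obs = _partial_from_inverse(D, i, j)
    zi = Z[:, i].copy()
    r_perm = np.empty(N)
    for b in range(N):
        for _attempt in range(50):
            rng.shuffle(zi)
            Cb = C.copy()
            row = (zi @ Z) / n
            Cb[i, :] = row
            Cb[:, i] = row
            Cb[i, i] = C[i, i]
            try:
                Db = _safe_inverse(Cb, names)
            except SingularCovarianceError:
                logger.warning("singular permutation covariance; resampling")
                continue
            r_perm[b] = _partial_from_inverse(Db, i, j)
            break
        else:
            raise SingularCovarianceError("could not find non-singular permutation")
    return r_obs, r_perm


def _permute_kendall(X, i, j, N, rng):
    n, p = X.shape
    signs = [_sign_matrix(X[:, m]) for m in range(p)]
    C = np.empty((p, p))
    for a in range(p):
        for b in range(a, p):
            C[a, b] = C[b, a] = float(np.sum(signs[a] * signs[b], dtype=np.int64))
    names = tuple(f"x{m}" for m in range(p))
    D = _safe_inverse(C, names)
    r_obs = _partial_from_inverse(D, i, j)
    Si = signs[i]
    r_perm = np.empty(N)
    for b in range(N):
        for _attempt in range(50):
            perm = rng.permutation(n)
            Sp = Si[np.ix_(perm, perm)]
            Cb = C.copy()
            for m in range(p):
                if m == i:
                    continue
                Cb[i, m] = Cb[m, i] = float(np.sum(Sp * signs[m], dtype=np.int64))
            try:
                Db = _safe_inverse(Cb, names)
            except SingularCovarianceError:
                logger.warning("singular permutation covariance; resampling")
                continue
            r_perm[b] = _partial_from_inverse(Db, i, j)
            break
        else:
            raise SingularCovarianceError("could not find non-singular permutation")
    return r_obs, r_perm


# --- high-level association over a DataFrame ----------------------------

def associate(
    df: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates: Sequence[str] = (),
    method: str = "spearman",
    permutation: PermutationConfig | None = None,
    master_seed: int | None = None,
) -> AssociationResult:
    """Test one (partial) association over the rows of a DataFrame.

    Rows with a missing value in any involved column are dropped
    (listwise deletion over the exact variable set), so n varies per
    association.  When ``permutation`` is given, a permutation P value is
    computed with a child seed derived from ``master_seed`` (or the
    config's own seed) and the association's identity, so results do not
    depend on the order in which associations are run.
    """
    cols = [predictor, outcome, *covariates]
    sub = df[cols].dropna()
    n = len(sub)
    covs = tuple(covariates)
    if n < len(cols) + 1 or sub[predictor].nunique() < 2 or sub[outcome].nunique() < 2:
        logger.warning(
            "skipping %s ~ %s | %s (%s): degenerate input (n=%d)",
            predictor, outcome, covs, method, n,
        )
        return AssociationResult(method, predictor, outcome, covs,
                                 float("nan"), float("nan"), None, n)
    X = sub.to_numpy(dtype=float)
    try:
        res = partial_correlation(X, 0, 1, method, names=cols)
    except SingularCovarianceError as exc:
        logger.warning("singular covariance for %s ~ %s | %s: %s",
                       predictor, outcome, covs, exc)
        return AssociationResult(method, predictor, outcome, covs,
                                 float("nan"), float("nan"), None, n)
    res = replace(res, predictor=predictor, outcome=outcome, covariates=covs)
    if permutation is not None:
        seed = derive_seed(
            master_seed if master_seed is not None else permutation.seed,
            predictor, outcome, covs, method,
        )
        cfg = replace(permutation, seed=seed)
        res.permutation_p = permutation_p(X, 0, 1, method, cfg)
    return res


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two_sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) P value comparing two groups.

    Exact enumeration for small untied samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative.replace("_", "-"))
    return float(res.pvalue)
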