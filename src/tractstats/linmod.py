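"""Statistical kernel: OLS with coefficient t-tests, classical t-tests,
Fisher's exact test, partial correlation, and the permutation engine.

Two permutation schemes are provided for testing a single term of a
linear model:

``label_permutation``
    The tested column of the design matrix is permuted across subjects,
    everything else held fixed.  Exact under exchangeability of the
    raw labels, but ignores covariates.

``freedman_lane``
    Freedman–Lane residual permutation: the response is reduced to
    fitted values plus residuals of the model *without* the tested
    term, the residuals are permuted, and the full model is refit.
    This respects covariate structure and is the default whenever the
    model adjusts for age and sex.

Family-wise error over a family of tests is controlled by the
max-statistic method: each test's corrected p compares its observed
|t| against the permutation distribution of the family-wise maximum
|t|.  All permutation p-values use the add-one estimator
``(1 + #{null >= observed}) / (B + 1)``, which is a valid p-value for
any number of permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    SampleSizeError,
    SingularDesignError,
    TractStatsError,
)

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

class DesignMatrix:
    """Named-column design matrix; the intercept column is always present."""

    def __init__(self, terms: Sequence[str], matrix: np.ndarray):
        self.terms = list(terms)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.terms):
            raise SingularDesignError("matrix shape does not match term names")
        if "intercept" not in self.terms:
            raise SingularDesignError("design must contain an intercept term")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in design {self.terms}") from None

    def drop(self, term: str) -> "DesignMatrix":
        j = self.term_index(term)
        keep = [i for i in range(len(self.terms)) if i != j]
        return DesignMatrix([self.terms[i] for i in keep], self.matrix[:, keep])

    def with_column(self, term: str, column: np.ndarray) -> "DesignMatrix":
        out = DesignMatrix(self.terms, self.matrix.copy())
        out.matrix[:, out.term_index(term)] = column
        return out


def build_design(frame: pd.DataFrame, terms: Sequence[str]) -> DesignMatrix:
    """Assemble a design matrix from named columns of a subject frame.

    ``"intercept"`` produces a constant column; ``"a:b"`` the elementwise
    product of columns a and b (the interaction term).
    """
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(frame)))
        elif ":" in t:
            a, b = t.split(":", 1)
            cols.append(frame[a].to_numpy(float) * frame[b].to_numpy(float))
        else:
            cols.append(frame[t].to_numpy(float))
    return DesignMatrix(list(terms), np.column_stack(cols))


def _collinear_terms(X: DesignMatrix) -> list[str]:
    """Name columns that are (numerically) linear combinations of the rest."""
    M = X.matrix
    out = []
    for j in range(M.shape[1]):
        others = np.delete(M, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
        resid = M[:, j] - others @ beta
        scale = np.linalg.norm(M[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < _RANK_TOL:
            out.append(X.terms[j])
    return out


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class TermStats:
    """Inference for one model term."""
    term: str
    beta: float
    se: float
    t: float
    df: int
    p_param: float
    p_perm: float | None = None


@dataclass
class RegressionResult:
    """OLS fit summary: per-term coefficient tests plus fit diagnostics."""
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    p_param: np.ndarray
    p_perm: dict = field(default_factory=dict)
    rss: float = np.nan

    def term(self, name: str) -> TermStats:
        j = self.terms.index(name)
        return TermStats(name, float(self.beta[j]), float(self.se[j]),
                         float(self.t[j]), self.df, float(self.p_param[j]),
                         self.p_perm.get(name))


def _ols_core(X: np.ndarray, Y: np.ndarray):
    """Vectorised OLS of possibly many responses on one design.

    Returns (beta (k,m), t (k,m), rss (m,), df). ``Y`` may be 1-D or
    (n, m).  Zero residual variance yields infinite t (exact fit).
    """
    n, k = X.shape
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y2)
    resid = Y2 - X @ beta
    df = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * np.inf)
    return beta, se, t, rss, df


def ols_fit(X: DesignMatrix, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares with per-term two-sided t-tests.

    Standard errors use the unbiased residual-variance estimator with
    ``df = n - k`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.matrix.shape
    if len(y) != n:
        raise TractStatsError(f"response length {len(y)} != design rows {n}")
    if n <= k:
        raise SampleSizeError(f"need more than {k} observations, got {n}")
    if np.linalg.matrix_rank(X.matrix, tol=_RANK_TOL * n) < k:
        bad = _collinear_terms(X)
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear terms: {bad}",
            terms=bad)
    beta, se, t, rss, df = _ols_core(X.matrix, y)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t[:, 0]), df)
    p = np.where(np.isinf(t[:, 0]), 0.0, p)
    return RegressionResult(list(X.terms), beta[:, 0], se[:, 0], t[:, 0],
                            df, p, rss=float(rss[0]))


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def one_sample_t(values) -> tuple[float, int, float]:
    """One-sample t-test of mean zero: t = mean / (SD / sqrt(n)), df = n - 1."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise SampleSizeError("one-sample t needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero sample SD; one-sample t undefined")
    return one_sample_t_from_summary(float(x.mean()), float(sd), len(x))


def one_sample_t_from_summary(mean: float, sd: float, n: int):
    """Same test from printed summary statistics (mean, SD, n)."""
    if n < 2:
        raise SampleSizeError("one-sample t needs n >= 2")
    if sd <= 0:
        raise DegenerateDataError("SD must be positive")
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    return float(t), df, float(2 * stats.t.sf(abs(t), df))


def two_sample_t_pooled(a, b) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t; sign is mean(a) - mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("two-sample t needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, len(a) + len(b) - 2, 1.0
        raise DegenerateDataError("pooled variance is zero")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled two-sample t from printed (mean, SD, n) per group."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return float(t), n1 + n2 - 2, float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sided by summation of all tables (with the observed margins)
    whose hypergeometric probability does not exceed the observed one.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise TractStatsError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if np.any(tab != np.floor(tab)) or np.any(tab < 0):
            raise TractStatsError("table entries must be non-negative integers")
        tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise TractStatsError("all row and column margins must be positive")
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def partial_r2(x, y, covariates: np.ndarray | None = None) -> float:
    """Squared partial correlation of x and y given covariates.

    Both vectors are residualised on the covariates (plus an intercept)
    and the squared Pearson correlation of the residuals is returned.
    With no covariates this reduces to the ordinary squared Pearson r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if len(y) != n:
        raise TractStatsError("x and y lengths differ")
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        if C.size:
            Z = np.column_stack([Z, C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise SingularDesignError("covariate design is rank deficient")
    H = Z @ np.linalg.lstsq(Z, np.eye(n), rcond=None)[0]
    rx = x - H @ x
    ry = y - H @ y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateDataError(
            "zero residual variance; partial correlation undefined")
    r = np.corrcoef(rx, ry)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Settings for permutation inference.

    ``n_perm`` defaults to 5000, the study-scale setting; tests and
    calibration suites pass smaller values.  ``family`` optionally
    names the tests corrected jointly (bookkeeping only; the correction
    itself takes the assembled null matrix).
    """
    n_perm: int = 5000
    seed: int = 0
    scheme: str = "freedman_lane"   # or "label_permutation"
    family: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_perm < 1:
            raise TractStatsError("n_perm must be >= 1")
        if self.scheme not in ("freedman_lane", "label_permutation"):
            raise TractStatsError(f"unknown permutation scheme {self.scheme!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def perm_pvalue(observed: float, null_stats) -> float:
    """Add-one two-sided permutation p: (1 + #{|null| >= |obs|}) / (B + 1)."""
    null = np.asarray(null_stats, float)
    if null.size == 0:
        raise TractStatsError("empty null distribution")
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (null.size + 1))


def perm_null_ts(X: DesignMatrix, Y, term: str, cfg: PermutationConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Null t distribution for one term, over one or many responses.

    ``Y`` of shape (n,) or (n, m); returns (n_perm, m) of t statistics
    for the tested term under the configured scheme.  Responses share
    the permutation sequence, as max-statistic correction requires.
    """
    Y = np.asarray(Y, float)
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    n, m = Y2.shape
    j = X.term_index(term)
    rng = rng if rng is not None else cfg.rng()
    perms = np.array([rng.permutation(n) for _ in range(cfg.n_perm)])
    out = np.empty((cfg.n_perm, m))
    if cfg.scheme == "label_permutation":
        col = X.matrix[:, j]
        for b in range(cfg.n_perm):
            Xb = X.matrix.copy()
            Xb[:, j] = col[perms[b]]
            _, _, t, _, _ = _ols_core(Xb, Y2)
            out[b] = t[j]
    else:  # freedman_lane, vectorised in chunks of permutations
        reduced = X.drop(term)
        Hr_beta = np.linalg.lstsq(reduced.matrix, Y2, rcond=None)[0]
        fitted_r = reduced.matrix @ Hr_beta
        resid_r = Y2 - fitted_r
        M = X.matrix
        k = M.shape[1]
        df = n - k
        XtX_inv = np.linalg.inv(M.T @ M)
        A = XtX_inv @ M.T
        hjj = XtX_inv[j, j]
        chunk = max(1, int(4e6 // (n * m)))
        for lo in range(0, cfg.n_perm, chunk):
            P = perms[lo:lo + chunk]
            # (c, n, m) -> (n, c*m)
            Ystar = (fitted_r[None, :, :] + resid_r[P]).transpose(1, 0, 2)
            Yf = Ystar.reshape(n, -1)
            beta = A @ Yf
            resid = Yf - M @ beta
            sigma2 = np.einsum("ij,ij->j", resid, resid) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                tj = np.where(sigma2 > 0,
                              beta[j] / np.sqrt(hjj * sigma2),
                              np.sign(beta[j]) * np.inf)
            out[lo:lo + len(P)] = tj.reshape(len(P), m)
    return out


def permute_term(X: DesignMatrix, y, term: str,
                 cfg: PermutationConfig) -> np.ndarray:
    """Null t distribution (length n_perm) for one term of one model."""
    return perm_null_ts(X, np.asarray(y, float), term, cfg)[:, 0]


def signflip_null_ts(values, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """One-sample null t distribution by random sign flipping.

    ``values`` (n,) or (n, m): each permutation independently flips the
    sign of every subject's value (all m tests share the flips) and
    recomputes the one-sample t.  Exact under a null symmetric about 0.
    """
    V = np.asarray(values, float)
    V2 = V if V.ndim == 2 else V[:, None]
    n, m = V2.shape
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs[:, :, None] * V2[None, :, :]
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def maxstat_correct(observed, nulls) -> np.ndarray:
    """Max-statistic family-wise corrected p-values.

    ``observed`` (m,) and ``nulls`` (n_perm, m); corrected
    p_i = (1 + #{perm : max_j |null_{perm,j}| >= |obs_i|}) / (n_perm + 1).
    Corrected p never falls below the per-test add-one permutation p.
    """
    obs = np.atleast_1d(np.asarray(observed, float))
    null = np.asarray(nulls, float)
    if null.ndim != 2 or null.shape[1] != obs.size:
        raise TractStatsError(
            f"null matrix shape {null.shape} incompatible with family "
            f"size {obs.size}")
    maxabs = np.abs(null).max(axis=1)
    count = (maxabs[:, None] >= np.abs(obs)[None, :]).sum(axis=0)
    return (1 + count) / (null.shape[0] + 1)
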