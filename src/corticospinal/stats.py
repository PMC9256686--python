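"""Statistical kernels used across the pipeline.

Self-contained implementations of the tests the analysis needs:

* exact / approximate two-tailed Wilcoxon signed-rank (exact by dynamic
  programming over doubled midranks, so ties are handled exactly),
* fully-crossed within-subject three-way repeated-measures ANOVA,
* Holm–Bonferroni step-down adjustment,
* ordinary least squares with R², adjusted R², Gaussian-likelihood AIC/BIC
  and the model F-test,
* Pearson correlation and the paired t-test (thin scipy wrappers with the
  degenerate cases pinned down).

Conventions: adjusted R² = 1 − (1−R²)(n−1)/(n−k−1) with k the number of
non-intercept terms; AIC = n·ln(RSS/n) + 2·(k+2) counting the intercept and
the noise variance as parameters, BIC with a ln(n) penalty.  AIC/BIC are
comparable only within this fixed convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st


class DegenerateDataError(ValueError):
    """Raised when an input has no variance left to test."""


@dataclass(frozen=True)
class StatResult:
    """A single test statistic with its two-tailed p value."""

    name: str
    value: float
    p: float
    n: int
    df: tuple[float, ...] | float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")

    def to_dict(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = list(df)
        return {"name": self.name, "value": float(self.value), "p": float(self.p),
                "n": int(self.n), "df": df}


@dataclass(frozen=True)
class ModelFitMetrics:
    """Goodness-of-fit summary for a least-squares model."""

    r2: float
    adjusted_r2: float
    aic: float
    bic: float
    rss: float
    n: int
    k: int  # number of non-intercept terms

    def to_dict(self) -> dict:
        return {k: (float(v) if not isinstance(v, int) else v)
                for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class OLSFit:
    """Coefficients plus fit metrics for one least-squares model."""

    params: np.ndarray          # intercept first when fitted with one
    bse: np.ndarray
    intercept: bool
    metrics: ModelFitMetrics
    f: StatResult
    fitted: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_wplus_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each value of 2·W⁺ over all 2ⁿ sign assignments (DP)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    diffs: Sequence[float],
    zero_method: str = "wilcox",
    method: str = "auto",
    exact_limit: int = 20,
) -> StatResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    ``method="auto"`` uses the exact null (enumeration of all 2ⁿ sign
    patterns, computed by dynamic programming over doubled midranks so tied
    absolute differences are exact too) for n ≤ ``exact_limit``, and the
    normal approximation with continuity and tie correction above.

    Zero differences are dropped by default (Wilcoxon's convention);
    ``zero_method="pratt"`` ranks them first and then drops them from W⁺.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be one-dimensional")
    if np.all(d == 0):
        raise DegenerateDataError("all differences are zero")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = _st.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks = _st.rankdata(np.abs(d))
        keep = d != 0
        d, ranks = d[keep], ranks[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if n <= exact_limit else "approx"
    if method == "exact":
        doubled = np.rint(2 * ranks).astype(int)
        counts = _exact_wplus_counts(doubled)
        w2 = int(round(2 * w_plus))
        denom = 2.0 ** n
        lo = counts[: w2 + 1].sum() / denom
        hi = counts[w2:].sum() / denom
        p = min(1.0, 2.0 * min(lo, hi))
    elif method == "approx":
        mean = ranks.sum() / 2.0
        sd = math.sqrt(float(np.sum(ranks**2)) / 4.0)
        if sd == 0:
            raise DegenerateDataError("zero variance rank sum")
        # continuity correction toward the mean
        cc = 0.5 if w_plus != mean else 0.0
        z = (w_plus - mean - math.copysign(cc, w_plus - mean)) / sd
        p = 2.0 * _st.norm.sf(abs(z))
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(name="W", value=w_plus, p=p, n=n)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (fully crossed within-subject)
# ---------------------------------------------------------------------------

def _anova_term(data: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """ANOVA interaction term for a subset of axes via inclusion–exclusion.

    ``data`` has the subject on axis 0 and one factor per remaining axis;
    the returned array broadcasts to ``data.shape`` and varies only along
    ``axes``.
    """
    all_axes = tuple(range(data.ndim))
    term = np.zeros_like(data, shape=tuple(
        data.shape[a] if a in axes else 1 for a in all_axes))
    m = len(axes)
    for mask in range(2 ** m):
        subset = tuple(axes[i] for i in range(m) if mask >> i & 1)
        collapse = tuple(a for a in all_axes if a not in subset)
        sign = (-1) ** (m - len(subset))
        term = term + sign * data.mean(axis=collapse, keepdims=True)
    return term


def rm_anova_3way(
    table: pd.DataFrame,
    subject: str = "participant_id",
    factors: Sequence[str] = ("hand", "segment", "side"),
    value: str = "beta",
) -> list[StatResult]:
    """Three-way repeated-measures ANOVA on a fully-crossed within-subject table.

    Every effect (3 main, 3 two-way, 1 three-way) is tested against its own
    effect-by-subject interaction mean square.  For two-level factors every
    effect has df = (1, n−1) and F equals the squared paired t of the
    corresponding within-subject contrast.

    The table must hold exactly one value per subject per factor cell.
    """
    if len(factors) != 3:
        raise ValueError("exactly three within-subject factors are required")
    cols = [subject, *factors, value]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    levels = [sorted(table[f].unique()) for f in factors]
    subjects = sorted(table[subject].unique())
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    pivot = table.set_index([subject, *factors])[value]
    if pivot.index.has_duplicates:
        raise ValueError("more than one value per subject per cell")
    shape = (n, *(len(lv) for lv in levels))
    full = pivot.reindex(
        pd.MultiIndex.from_product([subjects, *levels], names=[subject, *factors])
    ).to_numpy()
    if np.isnan(full).any():
        raise ValueError("incomplete design: some subject×cell combinations missing")
    data = full.reshape(shape)

    results: list[StatResult] = []
    effect_sets = [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3)]
    for axes in effect_sets:
        t_eff = np.broadcast_to(_anova_term(data, axes), data.shape)
        t_err = np.broadcast_to(_anova_term(data, (0, *axes)), data.shape)
        ss_eff = float(np.sum(t_eff**2))
        ss_err = float(np.sum(t_err**2))
        df_eff = int(np.prod([len(levels[a - 1]) - 1 for a in axes]))
        df_err = df_eff * (n - 1)
        if ss_err <= 1e-300:
            raise DegenerateDataError(
                "zero error mean square for effect "
                + ":".join(factors[a - 1] for a in axes)
            )
        f_val = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(_st.f.sf(f_val, df_eff, df_err))
        results.append(
            StatResult(
                name=":".join(factors[a - 1] for a in axes),
                value=f_val,
                p=p,
                n=n,
                df=(float(df_eff), float(df_err)),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = (m - np.arange(m)) * p[order]
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Least squares
# ---------------------------------------------------------------------------

def ols_fit(X: np.ndarray, y: np.ndarray, intercept: bool = True) -> OLSFit:
    """Ordinary least squares with fit metrics and the model F-test.

    ``X`` holds the k non-intercept terms as columns; a constant column is
    prepended when ``intercept`` is true.  Raises on rank deficiency and on
    n ≤ k+1 (adjusted R² undefined).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible lengths")
    A = np.column_stack([np.ones(n), X]) if intercept else X
    p_cols = A.shape[1]
    if n <= k + (1 if intercept else 0):
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(A) < p_cols:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    params, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ params
    resid = y - fitted
    rss = float(resid @ resid)
    if intercept:
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)
    if tss <= 0:
        raise DegenerateDataError("response has zero variance")
    r2 = 1.0 - rss / tss
    df_resid = n - k - (1 if intercept else 0)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if n - k - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    else:
        adj = float("nan")
    n_params = k + (1 if intercept else 0) + 1  # + noise variance
    if rss <= 0:
        aic = bic = float("-inf")
    else:
        aic = n * math.log(rss / n) + 2.0 * n_params
        bic = n * math.log(rss / n) + math.log(n) * n_params
    metrics = ModelFitMetrics(r2=r2, adjusted_r2=adj, aic=aic, bic=bic,
                              rss=rss, n=n, k=k)
    if k >= 1:
        if rss <= 0:
            f_val, f_p = float("inf"), 0.0
        else:
            f_val = ((tss - rss) / k) / (rss / df_resid)
            f_p = float(_st.f.sf(f_val, k, df_resid))
    else:
        f_val, f_p = float("nan"), float("nan")
    f = StatResult(name="F", value=f_val, p=f_p, n=n, df=(float(k), float(df_resid)))
    sigma2 = rss / df_resid if df_resid > 0 else float("nan")
    try:
        cov = sigma2 * np.linalg.inv(A.T @ A)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover
        bse = np.full(p_cols, np.nan)
    return OLSFit(params=params, bse=bse, intercept=intercept,
                  metrics=metrics, f=f, fitted=fitted, resid=resid)


def simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line y ~ x: (slope, intercept, r, r2).

    A constant response gives slope 0, r 0; a constant explanatory variable
    is an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0:
        raise DegenerateDataError("explanatory series has zero variance")
    cov = float(xc @ yc)
    slope = cov / vx
    intercept = float(y.mean() - slope * x.mean())
    r = cov / math.sqrt(vx * vy) if vy > 0 else 0.0
    return slope, intercept, r, r * r


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson r with its two-tailed p value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant series")
    res = _st.pearsonr(x, y)
    return StatResult(name="r", value=float(res.statistic), p=float(res.pvalue),
                      n=n, df=float(n - 2))


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-tailed paired t-test; identical samples give t = 0, p = 1."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult(name="t", value=0.0, p=1.0, n=n, df=float(n - 1))
        raise DegenerateDataError("constant nonzero differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), n - 1)
    return StatResult(name="t", value=float(t), p=float(p), n=n, df=float(n - 1))
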