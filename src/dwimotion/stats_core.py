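"""Statistical machinery used by the analysis pipelines.

Nonparametric two-sample and paired tests, Benjamini–Hochberg FDR
control, an OLS group-effect model, and lifespan age-curve fits. Exact
null distributions are used wherever the classical exact test is
defined (tie-free data); with ties, the normal approximation with tie
and continuity corrections takes over.

The signed-rank test is implemented directly on top of a cached exact
null CDF so that entire feature grids (pairs × features) stay cheap to
test (:func:`signed_rank_grid`); the scalar wrapper and the grid agree
column-for-column. The normal tail approximation is noticeably
conservative at the far tail even for a hundred pairs, which would
depress family-wise null behavior of the FDR step — hence exact by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "TestResult",
    "FDRResult",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "signed_rank_grid",
    "bh_fdr",
    "glm_group_effect",
    "fit_age_curve",
]

EXACT_RANKSUM_MAX_N = 12  # exact null when min(n) <= this and no ties


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class FDRResult:
    """Benjamini–Hochberg adjusted values and rejection flags."""

    q: np.ndarray
    reject: np.ndarray
    alpha: float
    m: int


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test for independent
    samples.

    Exact null enumeration when min(n) <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections. The statistic reported is the Mann–Whitney U of the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= EXACT_RANKSUM_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), n=(x.size, y.size))


@lru_cache(maxsize=8)
def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the signed-rank statistic W+ for ``n`` tie-free
    differences, P(W+ <= w) for w = 0 .. n(n+1)/2.

    Built by dynamic programming (each rank enters W+ independently with
    probability 1/2), so the cost is O(n^3) once per n and the per-test
    cost afterwards is a table lookup.
    """
    probs = np.array([1.0])
    for r in range(1, n + 1):
        new = np.zeros(probs.size + r)
        new[: probs.size] += 0.5 * probs
        new[r:] += 0.5 * probs
        probs = new
    return np.cumsum(probs)


def _signed_rank_exact_p(w_plus: float, n: int) -> float:
    """Exact two-sided p for an integer-valued W+ under the symmetric
    tie-free null."""
    total = n * (n + 1) // 2
    cdf = _signed_rank_null_cdf(n)
    w_low = int(min(w_plus, total - w_plus))
    return float(min(1.0, 2.0 * cdf[w_low]))


def _signed_rank_approx_p(diffs: np.ndarray) -> tuple[float, float]:
    """Normal-approximation two-sided p for one vector of nonzero paired
    differences, with tie correction and 0.5 continuity correction.

    Returns (W+, p); W+ is the sum of ranks of positive differences.
    """
    n = diffs.size
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(np.abs(diffs), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return w_plus, float(min(1.0, 2.0 * stats.norm.sf(z)))


def wilcoxon_signed_rank(diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (the classical Wilcoxon
    treatment). The exact null distribution of W+ is used whenever the
    |differences| are tie-free (at any n — the null CDF is cached per
    sample size, so this stays cheap); with ties the normal
    approximation with tie and continuity corrections is used. The
    statistic reported is W+, the rank sum of positive differences.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValidationError("need at least one paired difference")
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    absd = np.abs(nz)
    has_ties = np.unique(absd).size < absd.size
    if not has_ties:
        ranks = stats.rankdata(absd)
        w_plus = float(ranks[nz > 0].sum())
        return TestResult(
            statistic=w_plus, p=_signed_rank_exact_p(w_plus, nz.size), n=(nz.size,)
        )
    w_plus, p = _signed_rank_approx_p(nz)
    return TestResult(statistic=w_plus, p=p, n=(nz.size,))


def signed_rank_grid(diffs: np.ndarray) -> np.ndarray:
    """Signed-rank p-values for every column of an (n_pairs, n_features)
    difference matrix.

    Columns whose differences are all zero get p = 1 (a degenerate
    feature carries no evidence of bias); other columns use exactly the
    same exact-or-approximate rule as :func:`wilcoxon_signed_rank`.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[0] < 1:
        raise ValidationError("diffs must be an (n_pairs, n_features) matrix")
    m = diffs.shape[1]
    pvals = np.ones(m)
    for j in range(m):
        col = diffs[:, j]
        nz = col[col != 0.0]
        if nz.size == 0:
            pvals[j] = 1.0
        elif np.unique(np.abs(nz)).size == nz.size:
            ranks = stats.rankdata(np.abs(nz))
            pvals[j] = _signed_rank_exact_p(float(ranks[nz > 0].sum()), nz.size)
        else:
            pvals[j] = _signed_rank_approx_p(nz)[1]
    return pvals


def bh_fdr(pvals, alpha: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up FDR control.

    Rejects all hypotheses with rank <= max{i : p_(i) <= i·alpha/m};
    adjusted values q_(i) = min_{j>=i} p_(j)·m/j, capped at 1. Output
    order matches input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr needs at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return FDRResult(q=q, reject=reject, alpha=alpha, m=p.size)


def glm_group_effect(value, group, age, sex) -> tuple[float, float, float]:
    """OLS of ``value`` on intercept + group + age + sex; returns the
    group coefficient, its standard error, and the two-sided t-test p.

    ``group`` and ``sex`` are binary indicators. A rank-deficient design
    raises naming the collinear column.
    """
    import statsmodels.api as sm

    y = np.asarray(value, dtype=float)
    X = np.column_stack(
        [
            np.ones(y.size),
            np.asarray(group, dtype=float),
            np.asarray(age, dtype=float),
            np.asarray(sex, dtype=float),
        ]
    )
    if y.size <= 4:
        raise ValidationError("need more than 4 observations for the GLM")
    if X.shape[0] != y.size:
        raise ValidationError("response and covariates differ in length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ["intercept", "group", "age", "sex"]
        for j in range(X.shape[1] - 1, -1, -1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValidationError(f"design matrix is rank-deficient: column '{names[j]}' is collinear")
        raise ValidationError("design matrix is rank-deficient")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def fit_age_curve(ages, motion, form: str = "quadratic") -> dict:
    """Fit a lifespan motion-vs-age curve.

    ``form='quadratic'`` fits a least-squares degree-2 polynomial (the
    default). ``form='poisson'`` fits y = a + b·t·exp(-c·t) by nonlinear
    least squares — a gamma-type lifespan form common in developmental
    curve fitting; initialization is a0 = min(y), c0 = 0.1/yr, b0 from
    the youngest observation. Returns a dict with ``form``, ``params``
    and ``fitted`` (at the input ages).
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(motion, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("ages and motion must be equal-length vectors")
    n_distinct = np.unique(t).size
    if form == "quadratic":
        if n_distinct < 3:
            raise ValidationError("quadratic fit needs >= 3 distinct ages")
        # params ordered (c0, c1, c2): y = c0 + c1 t + c2 t^2
        coeffs = np.polynomial.polynomial.polyfit(t, y, deg=2)
        fitted = np.polynomial.polynomial.polyval(t, coeffs)
        return {"form": "quadratic", "params": coeffs, "fitted": fitted}
    if form == "poisson":
        if n_distinct < 4:
            raise ValidationError("poisson-curve fit needs >= 4 distinct ages")

        def model(tt, a, b, c):
            return a + b * tt * np.exp(-c * tt)

        a0 = float(np.min(y))
        c0 = 0.1
        i0 = int(np.argmin(t))
        denom = t[i0] * np.exp(-c0 * t[i0])
        b0 = (y[i0] - a0) / denom if abs(denom) > 1e-12 else 1.0
        try:
            params, _ = optimize.curve_fit(model, t, y, p0=(a0, b0, c0), maxfev=20000)
        except RuntimeError as exc:
            raise ValidationError(f"poisson-curve fit did not converge: {exc}") from exc
        return {"form": "poisson", "params": params, "fitted": model(t, *params)}
    raise ValidationError(f"unknown age-curve form {form!r}")
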