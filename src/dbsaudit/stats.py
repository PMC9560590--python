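"""Statistical battery: t-tests, ANOVA, Pearson correlation, OLS and power.

All tests are two-sided.  The two-sample t-test uses the pooled-variance
(Student) form, whose degrees of freedom are n1 + n2 - 2.  Multiple-
comparison correction is Bonferroni: p_corrected = min(1, m * p) for a
family of m tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    """One hypothesis test: statistic, degrees of freedom, p-values."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    n: int
    p_corrected: float | None = None
    family_m: int | None = None
    extra: dict = field(default_factory=dict)

    def corrected(self, m: int) -> "StatResult":
        """Return a copy with Bonferroni correction at family size m applied."""
        out = StatResult(
            self.test, self.statistic, self.df, self.p, self.n,
            p_corrected=min(1.0, m * self.p), family_m=m, extra=dict(self.extra),
        )
        return out


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    return a


class ZeroVarianceError(ValueError):
    """The test statistic is undefined because the data have no variance."""


def paired_t(pre, post) -> StatResult:
    """Paired t-test on pre/post values: t = mean(d) / (sd(d)/sqrt(n)).

    ``d = post - pre``; df = n - 1; two-sided p.  All-zero differences give
    t = 0 (a legitimate null result); nonzero constant differences have zero
    variance and raise :class:`ZeroVarianceError` since t is undefined.
    """
    pre, post = _as1d(pre), _as1d(post)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return StatResult("paired_t", 0.0, n - 1, 1.0, n)
        raise ZeroVarianceError(
            "differences are constant and nonzero: t undefined"
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult("paired_t", float(t), n - 1, float(p), n)


def two_sample_t(a, b) -> StatResult:
    """Pooled-variance (Student) two-sample t-test; df = n1 + n2 - 2."""
    a, b = _as1d(a), _as1d(b)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0.0:
        if a.mean() == b.mean():
            raise ZeroVarianceError("both groups constant and equal: t undefined")
        t = math.inf if a.mean() > b.mean() else -math.inf
        return StatResult("two_sample_t", t, n1 + n2 - 2, 0.0, n1 + n2)
    t = (a.mean() - b.mean()) / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult("two_sample_t", float(t), df, float(p), n1 + n2)


def anova_oneway(groups) -> StatResult:
    """One-way ANOVA: F with between df = k - 1, within df = N - k."""
    arrs = [_as1d(g) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    if np.all(all_vals == all_vals[0]):
        raise ZeroVarianceError("all values identical: F undefined")
    k = len(arrs)
    N = all_vals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        return StatResult("anova_oneway", math.inf, (df_b, df_w), 0.0, N)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(F, df_b, df_w)
    return StatResult("anova_oneway", float(F), (df_b, df_w), float(p), N)


def pearson(x, y) -> StatResult:
    """Pearson correlation with r, R^2 and a t-based two-sided p.

    p is computed from t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 df.
    """
    x, y = _as1d(x), _as1d(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ZeroVarianceError("constant input: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return StatResult("pearson", r, n - 2, float(p), n, extra={"r2": r * r})


def glm_fit(response, predictors, names=None) -> tuple[np.ndarray, list[StatResult]]:
    """Ordinary least squares with intercept; per-coefficient t and p.

    ``predictors`` is an (n, p) column matrix (without intercept; one is
    always prepended).  Solved by QR.  Rank deficiency raises, naming the
    collinear columns.  Returns ``(coefficients, per-coefficient results)``
    with the intercept first.
    """
    y = _as1d(response)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and predictors disagree on n")
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    design = np.column_stack([np.ones(n), X])
    colnames = ["intercept"] + list(names)

    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [colnames[j] for j in np.nonzero(bad)[0]]
        raise ValueError(f"design is rank deficient; collinear column(s): {culprits}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - design @ beta
    dof = n - (p + 1)
    sigma2 = float(resid @ resid) / dof
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))

    results = []
    for j, name in enumerate(colnames):
        if se[j] == 0.0:
            t, pval = math.inf, 0.0
        else:
            t = beta[j] / se[j]
            pval = 2.0 * sps.t.sf(abs(t), dof)
        results.append(
            StatResult(f"glm[{name}]", float(t), dof, float(pval), n,
                       extra={"coef": float(beta[j]), "se": float(se[j])})
        )
    return beta, results


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni correction: each p -> min(1, m * p).

    ``m`` defaults to the number of p-values and must be at least that.
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError("family size m must be >= number of p-values")
    out = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
        out.append(min(1.0, m * p))
    return out


def required_n_correlation(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Minimal n detecting correlation ``r`` at the given alpha and power.

    Fisher-z approximation for a two-sided test:
    ``n = ceil(((z_{1-alpha/2} + z_power) / C)^2 + 3)`` with
    ``C = 0.5 * ln((1 + r) / (1 - r))``.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    c = 0.5 * math.log((1.0 + r) / (1.0 - r))
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return math.ceil(((z_a + z_b) / c) ** 2 + 3.0)


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-sided Fisher-z correlation test of ``r`` at size ``n``."""
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    c = 0.5 * math.log((1.0 + r) / (1.0 - r))
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(c * math.sqrt(n - 3) - z_a))


def results_table(results, family_m: int | None = None):
    """Tidy DataFrame of StatResults with Bonferroni correction applied.

    The family size defaults to the number of tests in the table; every
    result's corrected p uses that one explicit family.
    """
    import pandas as pd

    results = list(results)
    m = family_m if family_m is not None else len(results)
    rows = []
    for res in results:
        rc = res.corrected(m)
        df = rc.df
        rows.append({
            "test": rc.test,
            "statistic": rc.statistic,
            "df": str(df) if isinstance(df, tuple) else df,
            "p": rc.p,
            "p_corrected": rc.p_corrected,
            "family_m": rc.family_m,
            "n": rc.n,
            **{k: v for k, v in rc.extra.items()},
        })
    return pd.DataFrame(rows)
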