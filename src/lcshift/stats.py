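"""Cohort statistics: contingency tests, summary-statistics ANOVA with Scheffe
post hoc, two-sample t, and logistic risk-factor screening.

The one-way ANOVA here consumes group summaries (n, mean, sd) rather than raw
observations, so published summary tables can be re-analysed directly; it is
algebraically identical to raw-data one-way ANOVA on any dataset with those
summaries (between-groups sum of squares from the means, within-groups from
the sds: SSW = sum (n_i - 1) sd_i^2).

Logistic regression is a maximum-likelihood fit (Newton/IRLS via statsmodels)
with Wald confidence intervals exp(b +/- 1.96 se). The univariate ->
multivariate screen keeps candidates with univariate Wald p below a threshold
(default 0.20) and refits them jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupSummary",
    "LogisticResult",
    "chisq_test",
    "anova_from_summary",
    "scheffe_posthoc",
    "two_sample_t",
    "logistic_fit",
    "screen_and_fit",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group of a continuous variable."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def chisq_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, p). Rejects tables with an all-zero row or column
    (expected counts undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or t.sum() <= 0:
        raise ValueError("contingency table must be 2-D, nonnegative, with positive total")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero marginal row/column")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def _check_groups(groups: list[GroupSummary], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < min_n:
            raise ValueError(f"group {g.label!r} has n={g.n} < {min_n}")


def anova_from_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group n/mean/sd.

    Returns (F, df_between, df_within, p).
    """
    _check_groups(groups)
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N, k = ns.sum(), len(groups)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(N) - k
    msw = ssw / df2
    if msw == 0:
        f = np.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df1) / msw
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def scheffe_posthoc(groups: list[GroupSummary]) -> pd.DataFrame:
    """Scheffe-adjusted p-values for all pairwise mean contrasts.

    Each pairwise contrast statistic (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j)) is
    referred, after division by (k - 1), to the F(k-1, N-k) distribution.
    Symmetric; every pairwise p is at least the overall ANOVA p.
    """
    _check_groups(groups)
    k = len(groups)
    N = sum(g.n for g in groups)
    msw = sum((g.n - 1) * g.sd**2 for g in groups) / (N - k)
    labels = [g.label for g in groups]
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            if msw == 0:
                pij = 1.0 if gi.mean == gj.mean else 0.0
            else:
                f = (gi.mean - gj.mean) ** 2 / (msw * (1 / gi.n + 1 / gj.n)) / (k - 1)
                pij = float(sps.f.sf(f, k - 1, N - k))
            p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)


def two_sample_t(a: GroupSummary, b: GroupSummary, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sided independent-samples t test from summaries.

    Pooled-variance Student t by default; Welch when ``pooled=False``.
    Returns (t, df, p).
    """
    _check_groups([a, b])
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    if pooled:
        df = a.n + b.n - 2.0
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class LogisticResult:
    """Per-variable odds ratios from a logistic fit (intercept omitted)."""

    variables: list[str]
    intercept: float
    coef: dict[str, float]
    odds_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    converged: bool
    n: int
    note: str = ""
    univariate: dict[str, "LogisticResult"] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "odds_ratio": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        ).loc[self.variables]


def _as_design(X) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    return X


def logistic_fit(X, y, max_iter: int = 100) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    An intercept is always added. Constant or collinear columns are rejected
    (rank-deficient design). Non-convergence or separation is surfaced via
    ``converged``/``note`` rather than silently returned.
    """
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    const = X.std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant column(s) in design: {list(X.columns[const])}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.Logit(y, design)
    note = ""
    with np.errstate(all="ignore"):
        try:
            fit = model.fit(disp=0, maxiter=max_iter)
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception as exc:  # perfect separation raises in statsmodels
            return LogisticResult(
                variables=list(X.columns), intercept=float("nan"),
                coef={}, odds_ratio={}, ci_low={}, ci_high={}, p={},
                converged=False, n=len(y), note=f"fit failed: {exc}",
            )
    if not converged:
        note = "IRLS did not converge within iteration limit (possible separation)"
    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    cols = list(X.columns)
    with np.errstate(over="ignore"):  # separated fits legitimately yield inf CI bounds
        return LogisticResult(
            variables=cols,
            intercept=float(params["const"]),
            coef={c: float(params[c]) for c in cols},
            odds_ratio={c: float(np.exp(params[c])) for c in cols},
            ci_low={c: float(np.exp(params[c] - 1.96 * bse[c])) for c in cols},
            ci_high={c: float(np.exp(params[c] + 1.96 * bse[c])) for c in cols},
            p={c: float(pvals[c]) for c in cols},
            converged=converged,
            n=len(y),
            note=note,
        )


def screen_and_fit(X, y, threshold: float = 0.20) -> LogisticResult:
    """Univariate screen then joint logistic fit.

    Each candidate is fit alone; those with univariate Wald p < ``threshold``
    enter the multivariate model. If none passes, the univariate stage is
    returned alone with a note. Both stages are reported (``univariate``).
    """
    X = _as_design(X)
    uni = {c: logistic_fit(X[[c]], y) for c in X.columns}
    selected = [c for c in X.columns if uni[c].p.get(c, 1.0) < threshold]
    if not selected:
        out = LogisticResult(
            variables=[], intercept=float("nan"),
            coef={}, odds_ratio={}, ci_low={}, ci_high={}, p={},
            converged=True, n=len(X),
            note=f"no candidate passed the univariate p<{threshold} screen",
        )
        out.univariate = uni
        return out
    out = logistic_fit(X[selected], y)
    out.univariate = uni
    return out
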