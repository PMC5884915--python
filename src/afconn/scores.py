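"""Template-regression scores, ICC(2,1), behavioral screening, critical r.

A subject's asymmetry score (AFC-score) is the slope of a simple linear
regression of the subject's asymmetry vector on the group-mean asymmetry
vector: it measures how much of the group-typical asymmetry pattern the
subject expresses.  The same routine scores language-task lateralization
(LTL-score) on 38-element left-minus-right activity vectors.

Reliability across sessions uses the intraclass correlation for absolute
agreement, ICC(2,1): two-way random effects, single measures (Shrout &
Fleiss).  Behavioral screening uses Pearson correlations for continuous
variables and one-way ANOVA F tests for nominal ones, Bonferroni corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreFit",
    "ICCResult",
    "fit_score",
    "score_cohort",
    "icc_2_1",
    "behavioral_screen",
    "critical_r",
]


@dataclass(frozen=True)
class ScoreFit:
    """Simple-regression fit y = alpha + beta * x; ``beta`` is the score."""

    beta: float
    alpha: float
    residual_variance: float
    n_entries: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_targets: int
    k_raters: int


def fit_score(individual: np.ndarray, template: np.ndarray) -> ScoreFit:
    """Ordinary least squares of ``individual`` on ``template`` with intercept.

    The returned ``beta`` is the subject's score: the scaling needed to best
    fit the template to the individual vector.
    """
    y = np.asarray(individual, dtype=float).ravel()
    x = np.asarray(template, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: {y.size} vs {x.size}")
    if y.size < 3:
        raise ValueError("need at least 3 entries")
    xc = x - x.mean()
    ssx = xc @ xc
    if ssx == 0:
        raise ValueError("template is constant; score undefined")
    beta = (xc @ y) / ssx
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x
    dof = max(y.size - 2, 1)
    return ScoreFit(
        beta=float(beta),
        alpha=float(alpha),
        residual_variance=float(resid @ resid / dof),
        n_entries=int(y.size),
    )


def score_cohort(
    vectors: np.ndarray,
    template: np.ndarray | None = None,
    leave_one_out: bool = False,
) -> np.ndarray:
    """Score every row of ``vectors`` against a template.

    When ``template`` is None the group mean of the rows is used — including
    the scored subject by default, or excluding it with ``leave_one_out=True``
    (for bias-sensitive use; the inclusion bias is O(1/n)).
    """
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if template is not None:
        return np.array([fit_score(v, template).beta for v in vectors])
    total = vectors.sum(axis=0)
    out = np.empty(n)
    for i, v in enumerate(vectors):
        t = (total - v) / (n - 1) if leave_one_out else total / n
        out[i] = fit_score(v, t).beta
    return out


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a targets x raters matrix with no missing cells.  From the
    two-way ANOVA decomposition with mean squares for rows/targets (MSR),
    columns/raters (MSC) and error (MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval follows the F-based method of Shrout & Fleiss.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 targets by k>=2 raters matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    # Shrout & Fleiss F-based CI via Satterthwaite degrees of freedom
    ci_low, ci_high = np.nan, np.nan
    if mse > 0 and icc < 1:
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else np.inf
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    elif icc >= 1:
        ci_low = ci_high = 1.0
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_targets=n,
        k_raters=k,
    )


def behavioral_screen(
    scores: np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Screen behavioral covariates against a subject score vector.

    Continuous (numeric) variables: Pearson r with two-tailed p.  Nominal
    (non-numeric or categorical) variables: one-way ANOVA F across levels.
    Missing values are dropped pairwise, so each variable has its own n.
    Significance is flagged at ``alpha / m`` where ``m`` defaults to the
    number of variables actually tested.  Variables with fewer than 4 usable
    subjects, fewer than 2 levels, or zero variance are skipped with a
    warning and excluded from m.

    Returns a DataFrame indexed by variable with columns
    (kind, statistic, p, significant, n_used).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(covariates):
        raise ValueError("scores and covariate table must have equal length")
    rows = {}
    for name in covariates.columns:
        col = covariates[name]
        numeric = pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        )
        mask = col.notna() & np.isfinite(scores)
        n_used = int(mask.sum())
        if n_used < 4:
            warnings.warn(f"skipping {name!r}: fewer than 4 usable subjects")
            continue
        s = scores[mask.to_numpy()]
        if numeric:
            v = col[mask].to_numpy(dtype=float)
            if np.std(v) == 0 or np.std(s) == 0:
                warnings.warn(f"skipping {name!r}: zero variance")
                continue
            r, p = stats.pearsonr(v, s)
            rows[name] = ("continuous", float(r), float(p), n_used)
        else:
            groups = [s[(col[mask] == lv).to_numpy()] for lv in col[mask].unique()]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                warnings.warn(f"skipping {name!r}: fewer than 2 levels")
                continue
            f, p = stats.f_oneway(*groups)
            rows[name] = ("categorical", float(f), float(p), n_used)
    if m is None:
        m = len(rows)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["kind", "statistic", "p", "n_used"]
    )
    out["significant"] = out["p"] < (alpha / m if m else alpha)
    return out[["kind", "statistic", "p", "significant", "n_used"]]


def critical_r(n: int, m: int = 1, alpha: float = 0.05) -> float:
    """Smallest |r| that is significant two-tailed at alpha / m with n subjects.

    Uses the exact t transform r = t / sqrt(t^2 + n - 2) with t the two-tailed
    critical value of Student's t at df = n - 2.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if m < 1:
        raise ValueError("need m >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    t = stats.t.ppf(1 - (alpha / m) / 2, df)
    return float(t / np.sqrt(t**2 + df))
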