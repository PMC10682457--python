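"""Amyloid staging and the cohort-level statistical tests.

Subjects are staged from their CSF A-beta-42 concentration and cortical
amyloid-PET SUVR (cut-offs 192 ng/L and 0.872 SUVR); imaging measures are
adjusted for age and sex by OLS residualization before rank-based
association tests. Group comparisons use the pooled two-sample t-test for
continuous measures and the exact Fisher test for categorical ones; the
ordered progression of a measure across stages is tested with a
proportional-odds model, and multiplicity is handled per declared family
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CSF_AB42_CUTOFF",
    "PET_SUVR_CUTOFF",
    "STAGE_ORDER",
    "SubjectRecord",
    "TestResult",
    "classify_stage",
    "adjust_covariates",
    "spearman_assoc",
    "log_transform_ab42",
    "two_sample_ttest",
    "exact_summary_sample",
    "fisher_exact_2x2",
    "ordinal_trend",
    "fdr_bh",
    "compare_slopes",
]

CSF_AB42_CUTOFF = 192.0  # ng/L; abnormal (CSF+) strictly below
PET_SUVR_CUTOFF = 0.872  # SUVR vs composite reference; abnormal (PET+) strictly above
STAGE_ORDER = ("S1", "S2", "S3")


@dataclass
class SubjectRecord:
    """One subject's demographics, fluid/PET biomarkers, and derived imaging measures."""

    id: str
    age: float
    sex: str  # "M" or "F"
    csf_ab42: float | None = None
    csf_ttau: float | None = None
    csf_ptau: float | None = None
    suvr_baseline: float | None = None
    suvr_2y: float | None = None  # 2-year follow-up cortical SUVR (None if no follow-up)
    stage: str | None = None
    measures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.csf_ab42 is not None and self.csf_ab42 <= 0:
            raise ValueError("csf_ab42 must be positive")

    @property
    def suvr_change_2y(self) -> float | None:
        if self.suvr_2y is None or self.suvr_baseline is None:
            return None
        return self.suvr_2y - self.suvr_baseline


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    q: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def classify_stage(
    csf_ab42: float,
    suvr: float,
    csf_cut: float = CSF_AB42_CUTOFF,
    pet_cut: float = PET_SUVR_CUTOFF,
) -> str:
    """Amyloid-accumulation stage from baseline CSF A-beta-42 and cortical SUVR.

    S1 = CSF-/PET- (non-accumulator), S2 = CSF+/PET- (early accumulator),
    S3 = CSF+/PET+ (late accumulator). CSF+ means strictly below ``csf_cut``;
    PET+ means strictly above ``pet_cut``. The fourth quadrant (CSF-/PET+)
    gets its own label as it falls outside the ordered progression.
    """
    if csf_ab42 is None or suvr is None:
        raise ValueError("staging requires both csf_ab42 and suvr")
    csf_pos = csf_ab42 < csf_cut
    pet_pos = suvr > pet_cut
    if not csf_pos and not pet_pos:
        return "S1"
    if csf_pos and not pet_pos:
        return "S2"
    if csf_pos and pet_pos:
        return "S3"
    return "CSFneg_PETpos"


def adjust_covariates(
    values: np.ndarray, age: np.ndarray, sex: Sequence[str] | np.ndarray
) -> np.ndarray:
    """Residualize a measure on age and sex, restoring the grand mean.

    Sex enters as a 0/1 indicator. A constant covariate column (e.g. a
    single-sex subsample) is dropped with a warning rather than failing.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    if sex_arr.dtype.kind in "UO":
        sex_num = (sex_arr == "M").astype(float)
    else:
        sex_num = sex_arr.astype(float)
    if values.shape[0] != age.shape[0] or values.shape[0] != sex_num.shape[0]:
        raise ValueError("values, age and sex must be equal length")
    if np.any(~np.isfinite(age)) or np.any(~np.isfinite(values)):
        raise ValueError("missing covariate or measure values")
    cols = [np.ones_like(values)]
    for name, col in (("age", age), ("sex", sex_num)):
        if np.ptp(col) == 0:
            warnings.warn(f"constant covariate '{name}' dropped from adjustment", stacklevel=2)
        else:
            cols.append(col)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    return resid + values.mean()


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation with a two-sided p (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; rank correlation undefined")
    res = stats.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), int(x.size), "spearman")


def log_transform_ab42(csf_ab42: float | np.ndarray) -> float | np.ndarray:
    """Natural logarithm of the CSF A-beta-42 concentration."""
    arr = np.asarray(csf_ab42, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("csf_ab42 must be positive for the log transform")
    out = np.log(arr)
    return float(out) if out.ndim == 0 else out


def two_sample_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test, pooled-variance by default (Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no variance anywhere
        equal_means = np.isclose(a.mean(), b.mean())
        return TestResult(
            0.0 if equal_means else np.inf,
            1.0 if equal_means else 0.0,
            int(a.size + b.size),
            "t_pooled" if equal_var else "t_welch",
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        int(a.size + b.size),
        "t_pooled" if equal_var else "t_welch",
        extras={"df": float(res.df)},
    )


def exact_summary_sample(n: int, mean: float, sd: float) -> np.ndarray:
    """Construct n values whose sample mean and SD (n-1 denominator) hit the targets.

    Useful for re-running summary-only group comparisons: any statistic that
    depends on the data only through (n, mean, sd) — such as the pooled
    t-test — is exactly reproduced.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if n < 1:
            raise ValueError("need n >= 1")
        return np.full(n, float(mean))
    if n < 2:
        raise ValueError("need n >= 2 for a positive sd")
    z = np.arange(n, dtype=float)
    z -= z.mean()
    z /= z.std(ddof=1)
    return mean + sd * z


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Exact two-sided Fisher test on a 2x2 count table.

    Two-sidedness follows the min-likelihood convention: the p-value sums the
    hypergeometric probabilities of all tables (with the observed margins) no
    more probable than the observed one.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        raise ValueError("table must contain non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return TestResult(np.nan, 1.0, int(tab.sum()), "fisher_exact")
    res = stats.fisher_exact(tab, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), int(tab.sum()), "fisher_exact")


# ---------------------------------------------------------------------------
# Ordinal (proportional-odds) trend across stages


def _prop_odds_nll(params: np.ndarray, x: np.ndarray, y_codes: np.ndarray,
                   n_levels: int, ridge: float = 0.0) -> float:
    """Negative log-likelihood of the cumulative-logit proportional-odds model.

    Parameterization: thresholds a_1 < ... < a_{K-1} via a_1 and positive
    increments exp(d_j); slope b on the predictor. P(y <= j) = sigmoid(a_j - b x).
    """
    a1 = params[0]
    incs = np.exp(params[1 : n_levels - 1])
    cuts = np.concatenate([[a1], a1 + np.cumsum(incs)]) if n_levels > 2 else np.array([a1])
    b = params[-1]
    eta = np.subtract.outer(cuts, b * x)  # (K-1, n)
    cdf = special.expit(eta)
    upper = np.vstack([cdf, np.ones(x.size)])
    lower = np.vstack([np.zeros(x.size), cdf])
    probs = upper - lower  # (K, n)
    p_obs = probs[y_codes, np.arange(x.size)]
    return -np.sum(np.log(np.clip(p_obs, 1e-300, None))) + ridge * b * b


def _numeric_hessian(f, params: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = params.size
    h = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = params.copy(); pp[i] += eps; pp[j] += eps
            pm = params.copy(); pm[i] += eps; pm[j] -= eps
            mp = params.copy(); mp[i] -= eps; mp[j] += eps
            mm = params.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return h


def ordinal_trend(
    values: np.ndarray,
    stage_labels: Sequence[str],
    stage_order: Sequence[str] = STAGE_ORDER,
    reverse: bool = False,
) -> TestResult:
    """Linear-trend test of a measure across ordered stages.

    Fits a cumulative-logit proportional-odds model with the stage as the
    ordinal outcome and the measure as the predictor, and returns the
    two-sided Wald p-value on the slope. With ``reverse=True`` an OLS of the
    measure on numeric stage scores is used instead (the alternative reading
    of a trend test).
    """
    values = np.asarray(values, dtype=float)
    labels = list(stage_labels)
    if values.shape[0] != len(labels):
        raise ValueError("values and stage_labels must be equal length")
    present = [s for s in stage_order if s in labels]
    if len(present) < 2:
        raise ValueError("need at least 2 distinct stages")
    keep = np.array([s in present for s in labels])
    values = values[keep]
    codes = np.array([present.index(s) for s, k in zip(labels, keep) if k])
    n = values.size
    if reverse:
        slope, _, r, p, se = stats.linregress(codes.astype(float), values)
        return TestResult(float(slope / se), float(p), n, "trend_ols_reverse")

    x = (values - values.mean()) / values.std()  # standardize for stable optimization
    n_levels = len(present)

    from statsmodels.miscmodels.ordinal_model import OrderedModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(codes, x[:, None], distr="logit")
        fit = model.fit(method="bfgs", disp=False, maxiter=500)
    slope = float(fit.params[0])
    se = float(fit.bse[0])
    separated = (not np.isfinite(se)) or se <= 0 or abs(slope) > 15
    if not separated:
        z = slope / se
        p = 2 * stats.norm.sf(abs(z))
        return TestResult(float(z), float(p), n, "ordinal_proportional_odds",
                          extras={"slope": slope, "se": se, "penalized": False})

    # complete/quasi-separation: fall back to a ridge-penalized fit of the
    # same cumulative-logit likelihood so a finite Wald p is still reported
    warnings.warn("ordinal trend shows separation; using penalized fit", stacklevel=2)
    nll = lambda p: _prop_odds_nll(p, x, codes, n_levels, ridge=1.0)
    opt = optimize.minimize(nll, np.zeros(n_levels), method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-7})
    slope = float(opt.x[-1])
    hess = _numeric_hessian(nll, opt.x)
    try:
        se = float(np.sqrt(np.linalg.inv(hess)[-1, -1]))
    except np.linalg.LinAlgError:
        return TestResult(np.nan, np.nan, n, "ordinal_proportional_odds_failed")
    z = slope / se
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(float(z), float(p), n, "ordinal_proportional_odds_penalized",
                      extras={"slope": slope, "se": se, "penalized": True})


def fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_slopes(x: np.ndarray, y_before: np.ndarray, y_after: np.ndarray) -> TestResult:
    """Test whether the slope of y-on-x differs between two conditions.

    Stacks the two conditions and tests the condition-by-x interaction in
    ``y ~ x * condition`` by OLS. The same subjects appear in both
    conditions; the pairing is recorded in the result rather than modeled.
    """
    x = np.asarray(x, dtype=float)
    yb = np.asarray(y_before, dtype=float)
    ya = np.asarray(y_after, dtype=float)
    if not (x.shape == yb.shape == ya.shape):
        raise ValueError("x, y_before, y_after must be equal length")
    if x.size < 4:
        raise ValueError("need at least 4 subjects")
    import statsmodels.api as sm

    n = x.size
    cond = np.concatenate([np.zeros(n), np.ones(n)])
    xx = np.concatenate([x, x])
    yy = np.concatenate([yb, ya])
    design = sm.add_constant(np.column_stack([xx, cond, xx * cond]))
    fit = sm.OLS(yy, design).fit()
    t = float(fit.tvalues[-1])
    p = float(fit.pvalues[-1])
    return TestResult(t, p, n, "slope_comparison",
                      extras={"slope_before": float(fit.params[1]),
                              "slope_after": float(fit.params[1] + fit.params[3]),
                              "paired_subjects": True})
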