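"""Cohort statistics: descriptives, group comparisons, correlations,
multivariate regression with partial correlations, ICC and Bland-Altman.

Conventions: sample SD uses the n-1 denominator; IQR bounds are the 25th and
75th percentiles (linear interpolation); p-values are two-sided; the chi^2
test carries no continuity correction unless requested; missing data are
handled complete-case per analysis, and n is reported with every statistic.
The ICC variant is the two-way random-effects, absolute-agreement,
single-measure coefficient, the standard choice for inter-reader agreement.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear columns: {', '.join(self.columns)}")


@dataclasses.dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float


@dataclasses.dataclass
class RegressionResult:
    """Per-covariate OLS table plus model-level fit summaries."""

    table: pd.DataFrame  # index: covariate; columns: coefficient, std_error, t, r_partial, p
    intercept: float
    r_multiple: float
    r2: float
    r2_adjusted: float
    n: int
    k: int


@dataclasses.dataclass
class AgreementResult:
    """Agreement summaries; fields not produced by an analysis are None."""

    icc: float | None = None
    mean_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None

    def __post_init__(self) -> None:
        if self.loa_low is not None and self.loa_high is not None:
            if self.loa_low > self.loa_high + 1e-12:
                raise ValueError("loa_low must be <= loa_high")


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return pd.DataFrame([dataclasses.asdict(r) for r in cohort])


def describe(cohort, variable: str) -> dict:
    """Mean, SD, median and IQR bounds of one variable (complete-case)."""
    values = pd.to_numeric(_as_frame(cohort)[variable], errors="coerce").dropna().to_numpy(float)
    if values.size < 2:
        raise ValueError("describe requires at least 2 non-missing values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "n": int(values.size),
    }


def compare_groups(
    cohort,
    variable: str,
    group: str = "subtype",
    continuity_correction: bool = False,
) -> dict:
    """Two-group comparison: t test for continuous, chi^2 for categorical."""
    frame = _as_frame(cohort)[[variable, group]].dropna()
    levels = sorted(frame[group].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"group column must have exactly 2 levels, got {levels}")
    col = frame[variable]
    numeric = pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col)
    if numeric:
        a = col[frame[group].astype(str) == levels[0]].to_numpy(float)
        b = col[frame[group].astype(str) == levels[1]].to_numpy(float)
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be non-empty")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return {"kind": "t", "statistic": 0.0, "p": 1.0, "n": int(a.size + b.size)}
            raise ValueError("zero variance in both groups")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return {"kind": "t", "statistic": float(t), "p": float(p), "n": int(a.size + b.size)}
    table = pd.crosstab(frame[group].astype(str), col.astype(str))
    chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=continuity_correction)
    return {"kind": "chi2", "statistic": float(chi2), "p": float(p), "n": int(len(frame))}


def pearson(cohort, x: str, y: str) -> CorrelationResult:
    """Pearson product-moment correlation with its t-transform p-value."""
    frame = _as_frame(cohort)[[x, y]].dropna()
    xv = frame[x].to_numpy(float)
    yv = frame[y].to_numpy(float)
    if xv.size < 3:
        raise ValueError("pearson requires at least 3 complete pairs")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), n=int(xv.size), p_two_sided=float(res.pvalue))


def _find_collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    # Columns with a (numerically) vanishing diagonal in the QR factor are
    # linearly dependent on the preceding ones.
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in range(len(names)) if diag[j] <= tol]


def fit_multivariate(cohort, outcome: str, covariates: Sequence[str]) -> RegressionResult:
    """OLS with intercept; per-covariate t-based partial correlations.

    r_partial = t / sqrt(t^2 + df) with df = n - k - 1, signed by t;
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1).
    """
    covariates = list(covariates)
    frame = _as_frame(cohort)[[outcome, *covariates]].dropna()
    y = frame[outcome].to_numpy(float)
    X = frame[covariates].to_numpy(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _find_collinear_columns(design, ["const", *covariates])
        raise CollinearityError([c for c in bad if c != "const"] or covariates)
    fit = sm.OLS(y, design).fit()
    df = n - k - 1
    t = np.asarray(fit.tvalues[1:])
    with np.errstate(invalid="ignore"):
        r_partial = t / np.sqrt(t**2 + df)
    table = pd.DataFrame(
        {
            "coefficient": fit.params[1:],
            "std_error": fit.bse[1:],
            "t": t,
            "r_partial": r_partial,
            "p": fit.pvalues[1:],
        },
        index=pd.Index(covariates, name="covariate"),
    )
    r2 = float(fit.rsquared)
    return RegressionResult(
        table=table,
        intercept=float(fit.params[0]),
        r_multiple=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        r2_adjusted=float(fit.rsquared_adj),
        n=n,
        k=k,
    )


def icc_absolute_agreement(measurements) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is a complete subjects x raters grid.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete grid with >=2 subjects and >=2 raters")
    if not np.isfinite(x).all():
        raise ValueError("grid must be complete (no missing values)")
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("no between-subject variance")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("no between-subject variance")
    return AgreementResult(icc=float((msr - mse) / denom))


def bland_altman(a, b=None) -> AgreementResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD).

    Accepts either two aligned sequences or one sequence of (a, b) pairs.
    """
    if b is None:
        pairs = np.asarray(a, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        av, bv = pairs[:, 0], pairs[:, 1]
    else:
        av = np.asarray(a, dtype=float)
        bv = np.asarray(b, dtype=float)
        if av.shape != bv.shape:
            raise ValueError("paired sequences must have equal length")
    if av.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    diffs = av - bv
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
    )
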