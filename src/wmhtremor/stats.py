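"""Cohort statistics: group tests, correlations, adjustment, model ledger.

Implements the study's statistical plan on a per-subject cohort table:
t-tests for group comparisons (pooled Student by default, Welch by flag),
Mann-Whitney U for ordinal scores, Pearson chi-square for categorical
variables, Pearson/Spearman correlations, linear residualization for
covariate adjustment, and a cascade of linear regressions:

* Model 1 — outcome ~ age + disease duration (patients only);
* Model 2 — Model 1 + age-adjusted total WMH volume;
* Models 3.x — one per merged atlas ROI, the ROI volume adjusted for total
  WMH volume entered alone, with Bonferroni correction across the family.

Outcomes are tremor severity (TETRAS part 2) and mean accelerometric
frequency.  Conventions: two-sided p-values throughout; the Mann-Whitney U
counts x-wins (pairs where x > y, plus half-ties); missing data are handled
by listwise deletion per model with the per-model n recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "RegressionResult",
    "LedgerReport",
    "two_sample_t",
    "two_sample_t_from_data",
    "mann_whitney_u",
    "chi_square",
    "pearson",
    "spearman",
    "residualize",
    "ols_fit",
    "bonferroni",
    "vascular_burden_score",
    "run_model_ledger",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    p: float
    method: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.coefficient <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    ``variant="pooled"`` is the classical Student test (equal variances);
    ``"welch"`` uses the Satterthwaite approximation.  Degenerate zero-
    variance inputs: equal means give p = 1 by convention, unequal means
    give p = 0 flagged as degenerate.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, f"t ({variant})", df=float(n1 + n2 - 2))
        return TestResult(
            np.inf, 0.0, f"t ({variant})", df=float(n1 + n2 - 2), degenerate=True
        )
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(float(t), float(p), f"t ({variant})", df=df)


def two_sample_t_from_data(x, y, variant: str = "pooled") -> TestResult:
    """Raw-data overload of :func:`two_sample_t` (sample SD, ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, variant
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test; U counts x-wins.

    Uses the exact null distribution when there are no ties and
    n1·n2 <= 400, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size * y.size <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), f"Mann-Whitney U ({method})")


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column: chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), "Pearson chi-square", df=float(dof))


def _check_corr_inputs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlation requires finite values")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance in a correlation input")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-approximation p."""
    x, y = _check_corr_inputs(x, y)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), int(x.size), float(p), "Pearson r")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties), two-sided p."""
    x, y = _check_corr_inputs(x, y)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), int(x.size), float(p), "Spearman rho")


def residualize(y, covariate) -> np.ndarray:
    """Residuals of a simple least-squares fit of y on the covariate.

    Used for age adjustment of total WMH volume and for adjusting each ROI
    volume for the total WMH volume, so the adjusted variable can enter a
    regression alongside the covariate.  Residuals are mean-zero by
    construction.  A constant covariate degenerates to mean-centering (with
    a warning).
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if y.size != c.size:
        raise ValueError("y and covariate must have equal length")
    if y.size < 3:
        raise ValueError("residualization requires n >= 3")
    if c.std(ddof=0) == 0:
        warnings.warn("constant covariate: returning mean-centered values")
        return y - y.mean()
    slope, intercept = np.polyfit(c, y, 1)
    return y - (slope * c + intercept)


@dataclass
class RegressionResult:
    """Ordinary least squares fit summary.

    ``coefficients`` includes the intercept under ``"const"``;
    ``standardized_beta`` is coefficient × sd(predictor)/sd(outcome) for
    each non-intercept predictor.
    """

    coefficients: dict[str, float]
    standardized_beta: dict[str, float]
    coefficient_p: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    df_model: float
    df_resid: float
    model_p: float
    n: int

    def __post_init__(self) -> None:
        if self.adjusted_r_squared > self.r_squared + 1e-12:
            raise ValueError("adjusted R² cannot exceed R²")
        if self.f_statistic < 0:
            raise ValueError("F statistic must be non-negative")


def ols_fit(design: pd.DataFrame, outcome) -> RegressionResult:
    """OLS of the outcome on the design columns (intercept added).

    Raises a singularity error naming the collinear columns on a
    rank-deficient design.
    """
    design = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(design) != y.size:
        raise ValueError("design and outcome lengths differ")
    n, p = design.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        bad = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).values)
            == np.linalg.matrix_rank(X.values)
        ]
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    betas = {}
    for c in design.columns:
        sd_x = design[c].std(ddof=1)
        betas[c] = float(fit.params[c] * sd_x / sd_y) if sd_y > 0 else float("nan")
    # Intercept-only comparisons make fvalue NaN; report F=0, p=1 then.
    f = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
    f_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        standardized_beta=betas,
        coefficient_p={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=f,
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        model_p=f_p,
        n=int(fit.nobs),
    )


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m for m simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def vascular_burden_score(hypertension, hyperlipidemia, diabetes, coronary, cerebrovascular):
    """Vascular burden 0–5: the sum of five binary risk/disease indicators.

    Components: arterial hypertension, hyperlipidemia, diabetes mellitus,
    coronary artery disease, cerebrovascular disease.
    """
    comps = [hypertension, hyperlipidemia, diabetes, coronary, cerebrovascular]
    vals = [int(c) for c in comps]
    if any(v not in (0, 1) for v in vals):
        raise ValueError("components must be binary (0/1)")
    return sum(vals)


@dataclass
class LedgerReport:
    """Regression cascade results mirroring the study's model table.

    ``table`` has one row per (outcome, model) with R², adjusted R², F,
    model p, the standardized beta and p of the WMH predictor added at that
    step, and the per-model n.  ``bonferroni_level`` applies to the Model
    3.x family (alpha / number of merged ROIs).
    """

    table: pd.DataFrame
    alpha: float
    bonferroni_level: float
    roi_columns: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.roi_columns)


def _roi_columns(cohort: pd.DataFrame) -> list[str]:
    return sorted(
        c
        for c in cohort.columns
        if c.startswith("wmh_") and c.endswith("_mm3") and c != "total_wmh_mm3"
    )


def run_model_ledger(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    outcomes: tuple[str, ...] = ("tetras_part2", "mean_frequency"),
    include_covariates_in_roi_models: bool = False,
    min_n: int = 10,
) -> LedgerReport:
    """Fit Model 1 / Model 2 / Models 3.x for each outcome on the ET subset.

    Model 1: age + disease duration.  Model 2: Model 1 plus age-adjusted
    total WMH volume.  Model 3.x: per merged ROI, the ROI volume adjusted
    for total WMH volume entered alone (optionally alongside the Model 1
    covariates).  The Bonferroni level alpha/m is attached to the 3.x
    family, m = number of merged ROIs.  Listwise deletion per model.
    """
    required = {"group", "age", "disease_duration", "total_wmh_mm3", *outcomes}
    missing = required - set(cohort.columns)
    if missing:
        raise KeyError(f"cohort table missing required columns: {sorted(missing)}")
    et = cohort[cohort["group"] == "ET"].copy()
    roi_cols = _roi_columns(cohort)
    m = len(roi_cols)
    level = bonferroni(alpha, m) if m else alpha
    rows = []

    for outcome in outcomes:
        base_cols = ["age", "disease_duration", "total_wmh_mm3", outcome]
        data = et.dropna(subset=base_cols)
        if len(data) < min_n:
            raise ValueError(
                f"only {len(data)} complete ET subjects for outcome {outcome!r}; need >= {min_n}"
            )
        y = data[outcome].to_numpy()

        fit1 = ols_fit(data[["age", "disease_duration"]], y)
        rows.append(_row(outcome, "1", "age + disease_duration", fit1, None, None))

        adj_wmh = residualize(data["total_wmh_mm3"].to_numpy(), data["age"].to_numpy())
        design2 = data[["age", "disease_duration"]].copy()
        design2["wmh_age_adjusted"] = adj_wmh
        fit2 = ols_fit(design2, y)
        rows.append(
            _row(
                outcome,
                "2",
                "model 1 + age-adjusted total WMH",
                fit2,
                fit2.standardized_beta["wmh_age_adjusted"],
                fit2.coefficient_p["wmh_age_adjusted"],
            )
        )

        for i, roi in enumerate(roi_cols, start=1):
            sub = data.dropna(subset=[roi])
            adj_roi = residualize(sub[roi].to_numpy(), sub["total_wmh_mm3"].to_numpy())
            if include_covariates_in_roi_models:
                design3 = sub[["age", "disease_duration"]].copy()
                design3["roi_wmh_adjusted"] = adj_roi
            else:
                design3 = pd.DataFrame({"roi_wmh_adjusted": adj_roi}, index=sub.index)
            fit3 = ols_fit(design3, sub[outcome].to_numpy())
            rows.append(
                _row(
                    outcome,
                    f"3.{i}",
                    roi,
                    fit3,
                    fit3.standardized_beta["roi_wmh_adjusted"],
                    fit3.coefficient_p["roi_wmh_adjusted"],
                )
            )

    return LedgerReport(
        table=pd.DataFrame(rows),
        alpha=alpha,
        bonferroni_level=level,
        roi_columns=roi_cols,
    )


def _row(outcome, model_id, predictors, fit: RegressionResult, beta, beta_p) -> dict:
    return {
        "outcome": outcome,
        "model": model_id,
        "predictors": predictors,
        "n": fit.n,
        "r_squared": fit.r_squared,
        "adjusted_r_squared": fit.adjusted_r_squared,
        "f_statistic": fit.f_statistic,
        "model_p": fit.model_p,
        "wmh_beta": beta,
        "wmh_p": beta_p,
    }
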