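"""Statistical pipeline for diet-score / inflammation associations.

Log transformation of skewed biomarkers (natural log, so that exponentiating
a fitted coefficient recovers a multiplicative effect), two-group
comparisons, pairwise Pearson correlation matrices with Cohen magnitude
labels, ordinary-least-squares models with standardised coefficients and
collinearity diagnostics, exp(beta) back-transformation, descriptive
quartile summaries, and the Pearson-correlation power computation (Fisher-z
approximation and Monte-Carlo simulation).

Models follow the study design: model 1 adjusts the diet score for age,
gender and year of data collection; model 2 additionally for waist
circumference, physical-activity tertile and CVD-risk class — except for
the Vegetarian Lifestyle Index, whose model 2 omits physical activity
because activity is already a score component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

#: Biomarkers analysed on the natural-log scale (right-skewed).
LOG_SCALE_OUTCOMES = frozenset({"hscrp", "paf"})

#: Scores whose model 2 omits the physical-activity covariate.
ACTIVITY_ADJUSTED_SCORES = frozenset({"vegetarian"})

MODEL1_COVARIATES = ("age", "gender_female", "year_2022")
MODEL2_EXTRA = ("waist_cm", "activity", "risk_high")
CONTINUOUS_COVARIATES = frozenset({"age", "waist_cm"})


class InferenceError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class ModelFit:
    """One fitted model: outcome x diet score x covariate set."""

    outcome: str
    score: str
    model_id: int
    beta_std: float
    se_beta: float
    p_value: float
    exp_beta: float
    pct_change: float
    n_used: int
    vif: dict[str, float] = field(default_factory=dict)
    tolerance: dict[str, float] = field(default_factory=dict)
    log_outcome: bool = False
    stratum: str | None = None


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p_value: float
    n: int

    @property
    def magnitude(self) -> str:
        return correlation_magnitude(self.r)


def correlation_magnitude(r: float) -> str:
    """Cohen label: |r| 0.1-0.29 small, 0.30-0.50 medium, 0.51-1 large."""
    a = abs(r)
    if a >= 0.51:
        return "large"
    if a >= 0.30:
        return "medium"
    if a >= 0.10:
        return "small"
    return "negligible"


def log_transform(values, participant_ids=None) -> np.ndarray:
    """Natural log of positive concentrations; NaN passes through as missing."""
    arr = np.asarray(values, dtype=float)
    bad = np.asarray((arr <= 0) & ~np.isnan(arr)).nonzero()[0]
    if bad.size:
        if participant_ids is not None:
            ids = [participant_ids[i] for i in bad[:5]]
            raise InferenceError(f"non-positive values for participants {ids}")
        raise InferenceError(f"non-positive values at positions {bad[:5].tolist()}")
    with np.errstate(invalid="ignore"):
        return np.log(arr)


def group_compare(values, groups, distribution_normal: bool):
    """Two-group comparison: independent t-test if normal, else Mann-Whitney U.

    Returns (statistic, two-sided p).  Missing values are dropped pairwise.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    levels = np.unique(g)
    if len(levels) != 2:
        raise InferenceError(f"need exactly two groups, got {len(levels)}")
    a = v[g == levels[0]]
    b = v[g == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise InferenceError("both groups must be non-empty")
    if distribution_normal:
        stat, p = stats.ttest_ind(a, b)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def is_normal(values, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality screen used for automated test selection."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise InferenceError("need >=3 observations for a normality check")
    return stats.shapiro(v).pvalue >= alpha


def pearson_matrix(frame: pd.DataFrame, columns: list[str] | None = None):
    """Pairwise-complete Pearson correlations with two-sided p values.

    Returns (r matrix, p matrix, n matrix) as DataFrames; the r matrix is
    symmetric with unit diagonal.  A constant column yields NaN r, flagged
    rather than silently zeroed.
    """
    cols = columns or list(frame.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(frame))
    for i in range(k):
        for j in range(i + 1, k):
            sub = frame[[cols[i], cols[j]]].dropna()
            if len(sub) < 3:
                raise InferenceError(
                    f"fewer than 3 complete pairs for {cols[i]}/{cols[j]}"
                )
            x = sub[cols[i]].to_numpy(float)
            y = sub[cols[j]].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
            n[i, j] = n[j, i] = len(sub)
    idx = pd.Index(cols)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise InferenceError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def model_covariates(score: str, model_id: int, include_year: bool = True) -> list[str]:
    """Covariate set for a given model; vegetarian model 2 omits activity."""
    if model_id not in (1, 2):
        raise InferenceError(f"model_id must be 1 or 2, got {model_id}")
    covs = [c for c in MODEL1_COVARIATES if include_year or c != "year_2022"]
    if model_id == 2:
        extra = [
            c for c in MODEL2_EXTRA
            if not (c == "activity" and score in ACTIVITY_ADJUSTED_SCORES)
        ]
        covs += extra
    return covs


def fit_model(
    frame: pd.DataFrame,
    outcome: str,
    score: str,
    model_id: int,
    log_outcome: bool | None = None,
    include_year: bool = True,
    stratum: str | None = None,
) -> ModelFit:
    """OLS of a (possibly log) biomarker on a diet score plus covariates.

    The outcome and continuous predictors (score, age, waist) are z-scored;
    binary covariates enter as 0/1 indicators and the activity tertile as an
    ordinal 0/1/2.  The reported coefficient is the standardised beta for
    the diet score, with exp(beta) and percent change attached.  Rows with
    any missing model variable are dropped (complete-case).  VIF and
    tolerance are computed on the design matrix.
    """
    covs = model_covariates(score, model_id, include_year)
    needed = [outcome, score] + covs
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise InferenceError(f"frame missing columns: {missing_cols}")
    sub = frame[needed].dropna()
    n_used = len(sub)
    if n_used < len(needed) + 2:
        raise InferenceError(f"too few complete cases ({n_used}) for the model")

    if log_outcome is None:
        log_outcome = outcome in LOG_SCALE_OUTCOMES
    y = sub[outcome].to_numpy(float)
    if log_outcome:
        y = log_transform(y)
    y = _zscore(y)

    design = pd.DataFrame(index=sub.index)
    design[score] = _zscore(sub[score].to_numpy(float))
    for c in covs:
        x = sub[c].to_numpy(float)
        design[c] = _zscore(x) if c in CONTINUOUS_COVARIATES else x

    exog = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise InferenceError(
            f"rank-deficient design (rank {rank} < {exog.shape[1]}); "
            f"most collinear pair: {worst}"
        )
    res = sm.OLS(y, exog).fit()

    vif: dict[str, float] = {}
    X = exog.to_numpy()
    for i, col in enumerate(exog.columns):
        if col == "const":
            continue
        vif[col] = float(variance_inflation_factor(X, i))
    tolerance = {c: 1.0 / v for c, v in vif.items()}

    beta = float(res.params[score])
    exp_beta, pct_change = back_transform(beta)
    return ModelFit(
        outcome=outcome,
        score=score,
        model_id=model_id,
        beta_std=beta,
        se_beta=float(res.bse[score]),
        p_value=float(res.pvalues[score]),
        exp_beta=exp_beta,
        pct_change=pct_change,
        n_used=n_used,
        vif=vif,
        tolerance=tolerance,
        log_outcome=bool(log_outcome),
        stratum=stratum,
    )


def back_transform(beta: float) -> tuple[float, float]:
    """exp(beta) and the percent change 100 x (1 - exp(beta)).

    For a natural-log outcome, exp(beta) is the multiplicative effect of a
    one-unit score increase; e.g. exp(beta) = 0.70 reads as a 30% reduction.
    """
    if not math.isfinite(beta):
        raise InferenceError("beta must be finite")
    exp_beta = math.exp(beta)
    return exp_beta, 100.0 * (1.0 - exp_beta)


def quartile_summary(
    frame: pd.DataFrame, score: str, marker: str
) -> pd.DataFrame:
    """Descriptive mean marker concentration per quartile of a diet score.

    Quartiles cut at the 25/50/75 rank percentiles; ties collapse bins with
    a warning rather than failing.  Excluded from any modelling by design.
    """
    sub = frame[[score, marker]].dropna()
    if sub[score].nunique() < 4:
        raise InferenceError(
            f"need >=4 distinct {score} values to form quartiles"
        )
    q = pd.qcut(sub[score].rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"])
    out = sub.groupby(q, observed=True)[marker].agg(["mean", "count"])
    out.index.name = "quartile"
    return out.rename(columns={"mean": f"{marker}_mean", "count": "n"})


def power_pearson(
    n: int,
    rho: float,
    alpha: float = 0.05,
    method: str = "fisher_z",
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Power of the two-sided Pearson correlation test.

    ``fisher_z`` uses the normal approximation on atanh(r) with standard
    error 1/sqrt(n-3); ``simulation`` draws bivariate-normal samples and
    counts two-sided rejections at level alpha.
    """
    if n < 4:
        raise InferenceError("n must be >= 4")
    if not 0 < abs(rho) < 1:
        raise InferenceError("rho must satisfy 0 < |rho| < 1")
    if not 0 < alpha < 1:
        raise InferenceError("alpha must lie in (0, 1)")
    if method == "fisher_z":
        z = math.atanh(rho) * math.sqrt(n - 3)
        crit = stats.norm.ppf(1 - alpha / 2)
        return float(stats.norm.cdf(z - crit) + stats.norm.cdf(-z - crit))
    if method == "simulation":
        if reps < 100:
            raise InferenceError("need >=100 simulation replicates")
        rng = np.random.default_rng(seed)
        # x ~ N(0,1); y = rho*x + sqrt(1-rho^2)*e gives corr(x, y) = rho
        x = rng.standard_normal((reps, n))
        e = rng.standard_normal((reps, n))
        y = rho * x + math.sqrt(1.0 - rho**2) * e
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        # two-sided p of the exact t test on r with n-2 df (as pearsonr reports)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        return float((p < alpha).mean())
    raise InferenceError(f"unknown method {method!r}")
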