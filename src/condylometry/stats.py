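"""Two-level statistics for paired-condyle cohorts.

A cohort is a long-format table, one row per condyle and at most two rows
per subject. The two condyles of a subject are correlated, so all
regressions are random-intercept linear models

    y_ij = beta0 + sum_c beta_c x_cij + b_i + e_ij,
    b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2),

estimated by REML, with Wald 95% confidence intervals and two-sided
p-values from the normal approximation. The module also provides the
ICC(A,1) reliability coefficient (single-measurement, absolute-agreement,
two-way model) with its F-based confidence interval, the power of the
two-sided pooled-variance t-test via the noncentral t distribution, and
per-category volume summaries.

Sex is coded F = 0, M = 1 throughout; categorical analyses use Class I,
normodivergent and normal growth as reference levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .classification import (DIVERGENCE_CLASSES, GROWTH_CLASSES,
                             SKELETAL_CLASSES, classify_table)

__all__ = [
    "COHORT_COLUMNS",
    "validate_cohort",
    "EffectEstimate",
    "RegressionResult",
    "ICCResult",
    "PowerSpec",
    "fit_random_intercept",
    "analyze_study",
    "icc_a1",
    "two_sample_power",
    "round_power",
    "group_summaries",
]

COHORT_COLUMNS = ("subject_id", "side", "volume_mm3", "sex", "age_years",
                  "anb_deg", "divergence_deg", "gonial_deg")

#: Continuous covariates analyzed against condylar volume.
STUDY_COVARIATES = ("anb_deg", "divergence_deg", "gonial_deg")

#: Label axis → (column produced by classification, level order, reference).
CATEGORICAL_AXES = {
    "skeletal_class": (SKELETAL_CLASSES, "I"),
    "divergence_class": (DIVERGENCE_CLASSES, "normo"),
    "growth_class": (GROWTH_CLASSES, "normal"),
}

_Z975 = float(sps.norm.ppf(0.975))


def validate_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract; returns the (unmodified) frame."""
    missing = [c for c in COHORT_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {', '.join(missing)}")
    if len(data) == 0:
        raise ValueError("cohort table is empty")
    per_subject = data.groupby("subject_id")["side"].agg(["count", "nunique"])
    if (per_subject["count"] > 2).any():
        bad = per_subject.index[per_subject["count"] > 2].tolist()
        raise ValueError(f"more than two condyles for subject(s): {bad}")
    if (per_subject["count"] != per_subject["nunique"]).any():
        bad = per_subject.index[per_subject["count"] != per_subject["nunique"]].tolist()
        raise ValueError(f"duplicate side within subject(s): {bad}")
    if not set(data["side"]) <= {"R", "L"}:
        raise ValueError(f"side must be 'R' or 'L', got {sorted(set(data['side']))}")
    if not set(data["sex"]) <= {"F", "M"}:
        raise ValueError(f"sex must be 'F' or 'M', got {sorted(set(data['sex']))}")
    if (data["volume_mm3"] <= 0).any():
        raise ValueError("condylar volumes must be positive")
    return data


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect estimate: slope, Wald 95% CI and two-sided p."""

    slope: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RegressionResult:
    """Random-intercept fit: per-covariate effects and variance components."""

    effects: dict[str, EffectEstimate]
    intercept: EffectEstimate
    tau2: float     # between-subject variance (mm^6 when the outcome is mm^3)
    sigma2: float   # residual (within-subject) variance
    n_subjects: int
    n_condyles: int
    outcome: str = "volume_mm3"


@dataclass
class ICCResult:
    """ICC(A,1) with its F-based 95% CI and the two-way mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample, two-sided pooled-variance t-test power
    calculation: group means (mm^3), common SD (mm^3), group sizes, alpha."""

    mean1: float
    mean2: float
    sd: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(f"group sizes must be >= 2, got {self.n1}, {self.n2}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _design_matrix(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric fixed-effects design (no constant); sex coded F=0, M=1."""
    cols = {}
    for c in covariates:
        if c == "sex":
            cols[c] = (data["sex"] == "M").astype(float)
        else:
            cols[c] = pd.to_numeric(data[c], errors="raise").astype(float)
    return pd.DataFrame(cols, index=data.index)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    full = np.linalg.matrix_rank(x)
    if full == x.shape[1]:
        return
    # name a minimal set of columns whose removal restores full rank
    culprits = []
    keep = list(range(x.shape[1]))
    for j in range(x.shape[1] - 1, -1, -1):
        trial = [i for i in keep if i != j]
        if np.linalg.matrix_rank(x[:, trial]) == np.linalg.matrix_rank(x[:, keep]):
            culprits.append(names[j])
            keep = trial
        if np.linalg.matrix_rank(x[:, keep]) == len(keep):
            break
    raise ValueError("design matrix is rank deficient; collinear column(s): "
                     + ", ".join(sorted(culprits)))


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str = "volume_mm3",
    covariates: list[str] | tuple[str, ...] = (),
) -> RegressionResult:
    """REML random-intercept regression of ``outcome`` on ``covariates``.

    ``data`` follows the cohort-table convention (``subject_id`` defines
    the grouping; ``sex`` may appear among the covariates and is coded
    F=0, M=1). Requires at least 3 subjects and a full-rank design.
    Confidence intervals and p-values are Wald, from the normal
    approximation; the between-subject variance is floored at zero by the
    REML boundary.
    """
    covariates = list(covariates)
    n_subjects = data["subject_id"].nunique()
    if n_subjects < 3:
        raise ValueError(f"need at least 3 subjects, got {n_subjects}")
    y = pd.to_numeric(data[outcome], errors="raise").astype(float)
    xdf = _design_matrix(data, covariates)
    exog = np.column_stack([np.ones(len(data)), xdf.to_numpy()])
    names = ["const"] + covariates
    _check_full_rank(exog, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y.to_numpy(), exog, groups=data["subject_id"].to_numpy())
        fit = model.fit(reml=True)
    params = np.asarray(fit.fe_params, dtype=float)
    bse = np.asarray(fit.bse_fe, dtype=float)

    def est(i: int) -> EffectEstimate:
        z = params[i] / bse[i] if bse[i] > 0 else np.inf * np.sign(params[i])
        return EffectEstimate(
            slope=float(params[i]),
            ci_low=float(params[i] - _Z975 * bse[i]),
            ci_high=float(params[i] + _Z975 * bse[i]),
            p_value=float(2.0 * sps.norm.sf(abs(z))),
        )

    return RegressionResult(
        effects={name: est(i) for i, name in enumerate(names) if i > 0},
        intercept=est(0),
        tau2=max(float(np.asarray(fit.cov_re)[0, 0]), 0.0),
        sigma2=float(fit.scale),
        n_subjects=int(n_subjects),
        n_condyles=int(len(data)),
        outcome=outcome,
    )


def _stratified(data: pd.DataFrame, outcome: str, covariates: list[str]):
    """Per-sex fits adjusted by the given covariates; small strata are
    reported as unavailable rather than failing the whole analysis."""
    out = {}
    for sex in ("F", "M"):
        stratum = data[data["sex"] == sex]
        n = stratum["subject_id"].nunique()
        if n < 3:
            out[sex] = {"unavailable": f"only {n} subject(s) in the {sex} stratum"}
            continue
        out[sex] = fit_random_intercept(stratum, outcome, covariates)
    return out


def analyze_study(data: pd.DataFrame, outcome: str = "volume_mm3") -> dict:
    """The study's two-level analysis battery.

    For each continuous covariate (ANB, divergence, gonial angle): a crude
    fit, a fit adjusted by sex and age, and per-sex fits adjusted by age.
    For each label axis (skeletal class, divergence class, growth class):
    indicator-coded crude and sex+age-adjusted fits against the reference
    level (Class I / normodivergent / normal growth). Labels are computed
    from the angle columns; the gonial label uses each row's gonial angle.
    """
    validate_cohort(data)
    labeled = classify_table(data, gonial_col="gonial_deg")
    report: dict = {"continuous": {}, "categorical": {}}
    for cov in STUDY_COVARIATES:
        try:
            report["continuous"][cov] = {
                "crude": fit_random_intercept(data, outcome, [cov]),
                "adjusted": fit_random_intercept(data, outcome, [cov, "sex", "age_years"]),
                "stratified": _stratified(data, outcome, [cov, "age_years"]),
            }
        except ValueError as exc:  # e.g. a covariate constant across the cohort
            report["continuous"][cov] = {"unavailable": str(exc)}
    for axis, (levels, reference) in CATEGORICAL_AXES.items():
        dummies = labeled.copy()
        names = []
        for level in levels:
            if level == reference:
                continue
            col = f"{axis}[{level}]"
            dummies[col] = (labeled[axis] == level).astype(float)
            names.append(col)
        present = [n for n in names
                   if 0 < dummies[n].sum() < len(dummies)]  # drop empty/degenerate levels
        try:
            report["categorical"][axis] = {
                "reference": reference,
                "crude": fit_random_intercept(dummies, outcome, present),
                "adjusted": fit_random_intercept(dummies, outcome,
                                                 present + ["sex", "age_years"]),
            }
        except ValueError as exc:
            report["categorical"][axis] = {"reference": reference,
                                           "unavailable": str(exc)}
    return report


def icc_a1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): single-measurement, absolute-agreement, two-way model.

    ``ratings`` is an ``n_subjects x k_raters`` matrix with no missing
    cells. The point estimate is

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    from the two-way mean squares; the confidence interval uses the
    F-distribution method with Satterthwaite degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"ratings must be a 2D matrix, got {x.ndim}D")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing cells; no imputation is performed")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ValueError("degenerate ratings: no variance anywhere in the table")
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        lo = hi = icc  # perfect agreement: the interval degenerates
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a):
            lo = hi = icc
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     ms_rows=msr, ms_cols=msc, ms_error=mse,
                     n_subjects=n, k_raters=k)


def two_sample_power(spec: PowerSpec) -> float:
    """Power of the two-sided pooled-variance t-test under ``spec``.

    Computed from the noncentral t distribution with
    ``df = n1 + n2 - 2`` and noncentrality
    ``|mean1 - mean2| / (sd * sqrt(1/n1 + 1/n2))``.
    """
    df = spec.n1 + spec.n2 - 2
    nc = abs(spec.mean1 - spec.mean2) / (spec.sd * np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2))
    tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    return float(power)


def round_power(power: float) -> float:
    """Display rounding: half-up to two decimals (whole percent)."""
    return float(Decimal(repr(power)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def group_summaries(
    data: pd.DataFrame,
    by: str,
    levels: tuple[str, ...] | None = None,
    value: str = "volume_mm3",
) -> pd.DataFrame:
    """Per-category condyle counts and volume summary statistics.

    One row per level of ``by`` (all declared levels appear; empty levels
    get count 0): n_condyles, median, mean, min, max and sample SD (n-1).
    """
    if levels is None:
        levels = CATEGORICAL_AXES.get(by, (None,))[0]
        if levels == (None,):
            levels = tuple(pd.unique(data[by]))
    rows = []
    for level in levels:
        v = data.loc[data[by] == level, value].to_numpy(dtype=float)
        if v.size == 0:
            rows.append((level, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
            rows.append((level, v.size, float(np.median(v)), float(v.mean()),
                         float(v.min()), float(v.max()), sd))
    return pd.DataFrame(rows, columns=[by, "n_condyles", "median", "mean",
                                       "min", "max", "sd"]).set_index(by)
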