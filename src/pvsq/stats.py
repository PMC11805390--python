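"""Cohort-level statistics over per-exam PVS measurements.

Two complementary analyses:

* **Full model** — a linear mixed model over all exams,

      PVS = b0 + b1*TP + b2*Anesthesia + b3*Age + b4*Sex + b5*DOSE + b6*Shunt

  with time point and dose as unordered categoricals (baselines 0M and
  RD), a per-patient random intercept to absorb within-patient
  correlation, REML estimation, and Bonferroni-adjusted pairwise
  contrasts (one family per comparison set: 6 TP pairs, 3 dose pairs,
  single tests for anesthesia/sex/shunt).

* **Paired model** — per-patient changes between consecutive time
  points (0M-3M, 3M-12M, 12M-FollowUp) restricted to exams acquired
  under matched anesthesia and shunt conditions, tested against zero
  with one-sample t-tests per dose level and compared across dose
  levels with one-way ANOVA. No multiplicity adjustment is applied in
  the paired model.

Plus the quality-control outlier rule (|x - mean| > k*SD, default k=2,
with a seeded random in-range review sample) and the pooled age
regression (OLS of the response on age).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import DOSE_LEVELS, TP_LEVELS, validate_cohort_frame

logger = logging.getLogger(__name__)

PERIODS = (("0M", "3M"), ("3M", "12M"), ("12M", "FollowUp"))
RESPONSES = ("pvs_ratio_permil", "pvs_volume_cm3")


def bonferroni(p: float, family_size: int) -> float:
    """p_adj = min(1, m*p); never smaller than the raw p."""
    return float(min(1.0, family_size * p))


@dataclass
class FullModelFit:
    """REML mixed-model fit of the full fixed-effect structure."""

    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    contrasts: pd.DataFrame  # family, level_a, level_b, estimate, se, stat, p, p_adj
    random_intercept_variance: float
    residual_variance: float
    n_obs: int
    n_patients: int
    n_dropped: int
    response: str
    method: str  # "mixedlm-reml" or "ols-degenerate"
    converged: bool
    df_method: str = "wald-normal (large-sample)"


def _term_levels(df: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "tp": [t for t in TP_LEVELS if t in set(df["tp"])],
        "dose": [d for d in DOSE_LEVELS if d in set(df["dose"])],
    }


def _build_formula(response: str, df: pd.DataFrame) -> tuple[str, list[str]]:
    """Assemble the fixed-effect formula, dropping single-level terms."""
    terms = []
    dropped = []
    lv = _term_levels(df)
    if len(lv["tp"]) > 1:
        terms.append("C(tp, Treatment('0M'))" if "0M" in lv["tp"] else "C(tp)")
    else:
        dropped.append("tp")
    for col in ("anesthesia", "shunt", "sex"):
        if df[col].nunique() > 1:
            terms.append(f"C({col})")
        else:
            dropped.append(col)
    if df["age_years"].nunique() > 1:
        terms.append("age_years")
    else:
        dropped.append("age_years")
    if len(lv["dose"]) > 1:
        terms.append("C(dose, Treatment('RD'))" if "RD" in lv["dose"] else "C(dose)")
    else:
        dropped.append("dose")
    for name in dropped:
        warnings.warn(
            f"covariate {name!r} has a single observed level and was dropped",
            stacklevel=3,
        )
    if not terms:
        terms = ["1"]
    return f"{response} ~ " + " + ".join(terms), dropped


def _categorical_coef_name(names: Sequence[str], col: str, level: str) -> str | None:
    for n in names:
        if f"C({col}" in n and n.endswith(f"[T.{level}]"):
            return n
    return None


def _pairwise_contrasts(
    fe_names: Sequence[str],
    fe_params: np.ndarray,
    fe_cov: np.ndarray,
    df: pd.DataFrame,
) -> pd.DataFrame:
    """Wald contrasts for every TP pair and dose pair, plus single tests
    for anesthesia, shunt and sex; Bonferroni within each family."""
    rows = []
    lv = _term_levels(df)
    families = [("tp", lv["tp"]), ("dose", lv["dose"])]
    for col, levels in families:
        pairs = list(combinations(levels, 2))
        if len(pairs) == 0:
            continue
        m = len(pairs)
        for a, b in pairs:
            vec = np.zeros(len(fe_names))
            ok = True
            for level, sign in ((a, 1.0), (b, -1.0)):
                name = _categorical_coef_name(fe_names, col, level)
                if name is not None:
                    vec[list(fe_names).index(name)] = sign
                # baseline level contributes 0
            est = float(vec @ fe_params)
            se = float(np.sqrt(vec @ fe_cov @ vec))
            if se == 0:
                stat, p = np.nan, np.nan
            else:
                stat = est / se
                p = 2.0 * sps.norm.sf(abs(stat))
            rows.append(
                {
                    "family": col,
                    "level_a": a,
                    "level_b": b,
                    "estimate": est,
                    "se": se,
                    "stat": stat,
                    "p_value": p,
                    "p_adj": bonferroni(p, m) if np.isfinite(p) else np.nan,
                }
            )
    for col in ("anesthesia", "shunt", "sex"):
        name = next((n for n in fe_names if f"C({col})" in n), None)
        if name is None:
            continue
        i = list(fe_names).index(name)
        est = float(fe_params[i])
        se = float(np.sqrt(fe_cov[i, i]))
        stat = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(stat)) if np.isfinite(stat) else np.nan
        rows.append(
            {
                "family": col,
                "level_a": name.split("[T.")[-1].rstrip("]"),
                "level_b": "baseline",
                "estimate": est,
                "se": se,
                "stat": stat,
                "p_value": p,
                "p_adj": p,  # family of size 1
            }
        )
    return pd.DataFrame(rows)


def fit_full_model(table: pd.DataFrame, response: str = "pvs_ratio_permil") -> FullModelFit:
    """Fit the full mixed model to a cohort table.

    Rows with a missing response or missing covariates are dropped and
    counted. With at least two patients the model is fitted by REML
    with a per-patient random intercept; if the pooled OLS fit is
    numerically exact (zero residual variance) the REML problem is
    degenerate and the OLS solution is returned with zero variances.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    df = validate_cohort_frame(table)
    n0 = len(df)
    df = df.dropna(subset=[response, "age_years"]).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("fit_full_model: dropped %d rows with missing values", n_dropped)
    if df["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients to fit the mixed model")

    formula, _dropped_terms = _build_formula(response, df)

    # degenerate (noise-free) case: REML is singular, OLS is exact
    ols = smf.ols(formula, data=df).fit()
    scale = float(np.mean(df[response] ** 2)) or 1.0
    if ols.ssr / (scale * len(df)) < 1e-18:
        fe_names = list(ols.params.index)
        fe_cov = np.zeros((len(fe_names), len(fe_names)))
        contrasts = _pairwise_contrasts(fe_names, ols.params.to_numpy(), fe_cov, df)
        return FullModelFit(
            coefficients=ols.params,
            std_errors=pd.Series(0.0, index=fe_names),
            p_values=pd.Series(np.nan, index=fe_names),
            contrasts=contrasts,
            random_intercept_variance=0.0,
            residual_variance=0.0,
            n_obs=len(df),
            n_patients=df["patient_id"].nunique(),
            n_dropped=n_dropped,
            response=response,
            method="ols-degenerate",
            converged=True,
        )

    model = smf.mixedlm(formula, data=df, groups=df["patient_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=True, method=["lbfgs", "bfgs"])
        except np.linalg.LinAlgError:
            # gradient-based REML can hit a singular profiled system when
            # the random-intercept variance sits on the zero boundary;
            # Powell is derivative-free and robust there
            result = model.fit(reml=True, method="powell", maxiter=2000)
    fe_names = list(result.fe_params.index)
    k = len(fe_names)
    fe_cov = np.asarray(result.cov_params())[:k, :k]
    contrasts = _pairwise_contrasts(fe_names, result.fe_params.to_numpy(), fe_cov, df)
    return FullModelFit(
        coefficients=result.fe_params,
        std_errors=pd.Series(result.bse_fe, index=fe_names),
        p_values=pd.Series(result.pvalues[:k], index=fe_names),
        contrasts=contrasts,
        random_intercept_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        n_obs=len(df),
        n_patients=df["patient_id"].nunique(),
        n_dropped=n_dropped,
        response=response,
        method="mixedlm-reml",
        converged=bool(result.converged),
    )


def confint_fixed(fit: FullModelFit, name: str, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for one fixed-effect coefficient."""
    z = sps.norm.ppf(0.5 + level / 2.0)
    est = float(fit.coefficients[name])
    se = float(fit.std_errors[name])
    return est - z * se, est + z * se


def group_summaries(
    table: pd.DataFrame,
    by: str,
    response: str = "pvs_ratio_permil",
) -> pd.DataFrame:
    """Per-level mean, sample SD (n-1 denominator) and n of a response.

    Levels with no non-missing observations are reported with n=0 and
    NaN mean/SD as an explicit marker.
    """
    if by not in ("tp", "dose", "shunt", "anesthesia", "sex"):
        raise ValueError(f"cannot summarize by {by!r}")
    df = validate_cohort_frame(table)
    df = df.dropna(subset=[response])
    level_order = {
        "tp": TP_LEVELS,
        "dose": DOSE_LEVELS,
        "shunt": ("no", "yes"),
        "anesthesia": ("no", "yes"),
        "sex": ("F", "M"),
    }[by]
    rows = []
    for level in level_order:
        x = df.loc[df[by] == level, response].to_numpy(dtype=float)
        rows.append(
            {
                "level": level,
                "n": len(x),
                "mean": float(np.mean(x)) if len(x) else np.nan,
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def age_regression(
    table: pd.DataFrame,
    response: str = "pvs_ratio_permil",
) -> tuple[float, float, float]:
    """Pooled OLS of the response on age: (slope, intercept, r).

    Slope units are permil/year for the ratio and cm^3/year for the
    volume.
    """
    df = validate_cohort_frame(table).dropna(subset=[response])
    ages = df["age_years"].to_numpy(dtype=float)
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct ages")
    if np.var(ages) == 0:
        raise ValueError("zero age variance")
    res = sps.linregress(ages, df[response].to_numpy(dtype=float))
    return float(res.slope), float(res.intercept), float(res.rvalue)


def build_paired_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient changes between consecutive time points.

    A patient contributes to a period only when both exams exist, both
    responses are measured, and the anesthesia and shunt flags match
    across the pair. Delta = later minus earlier. Columns:
    patient_id, period, dose, delta_ratio_permil, delta_volume_cm3.
    """
    df = validate_cohort_frame(table)
    rows = []
    for pid, sub in df.groupby("patient_id", sort=True):
        by_tp = {r.tp: r for r in sub.itertuples(index=False)}
        for early, late in PERIODS:
            if early not in by_tp or late not in by_tp:
                continue
            a, b = by_tp[early], by_tp[late]
            if a.anesthesia != b.anesthesia or a.shunt != b.shunt:
                continue
            if any(
                pd.isna(v)
                for v in (a.pvs_ratio_permil, b.pvs_ratio_permil,
                          a.pvs_volume_cm3, b.pvs_volume_cm3)
            ):
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "period": f"{early}-{late}",
                    "dose": a.dose,
                    "delta_ratio_permil": b.pvs_ratio_permil - a.pvs_ratio_permil,
                    "delta_volume_cm3": b.pvs_volume_cm3 - a.pvs_volume_cm3,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "period", "dose", "delta_ratio_permil", "delta_volume_cm3"],
    )


def test_deltas(deltas: pd.DataFrame, response: str = "delta_ratio_permil") -> pd.DataFrame:
    """One-sample t-tests per period x dose cell and dose ANOVA per period.

    Each cell is tested two-sided against zero; cells with n < 2 or zero
    SD are reported as untestable (NaN statistics) rather than raising.
    The one-way ANOVA compares dose levels within each period. No
    multiplicity adjustment is applied.
    """
    if response not in ("delta_ratio_permil", "delta_volume_cm3"):
        raise ValueError(f"unknown delta response {response!r}")
    rows = []
    period_order = [f"{a}-{b}" for a, b in PERIODS]
    for period in period_order:
        sub = deltas[deltas["period"] == period]
        if len(sub) == 0:
            continue
        groups = [
            sub.loc[sub["dose"] == d, response].to_numpy(dtype=float)
            for d in DOSE_LEVELS
        ]
        testable = [g for g in groups if len(g) >= 2 and np.std(g, ddof=1) > 0]
        if len(testable) >= 2:
            f_stat, f_p = sps.f_oneway(*testable)
        else:
            f_stat, f_p = np.nan, np.nan
        for dose, x in zip(DOSE_LEVELS, groups):
            n = len(x)
            mean = float(np.mean(x)) if n else np.nan
            sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
            if n >= 2 and sd > 0:
                t_stat, p = sps.ttest_1samp(x, 0.0)
                t_stat, p = float(t_stat), float(p)
                testable_flag = True
            else:
                t_stat, p = np.nan, np.nan
                testable_flag = False
            rows.append(
                {
                    "period": period,
                    "dose": dose,
                    "n": n,
                    "mean_delta": mean,
                    "sd_delta": sd,
                    "t_stat": t_stat,
                    "df": n - 1 if n else np.nan,
                    "p_value": p,
                    "testable": testable_flag,
                    "anova_F": float(f_stat) if np.isfinite(f_stat) else np.nan,
                    "anova_p": float(f_p) if np.isfinite(f_p) else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OutlierReport:
    flagged: list[int]
    review_sample: list[int] = field(default_factory=list)
    mean: float = np.nan
    sd: float = np.nan


def flag_outliers(
    values: Sequence[float],
    k: float = 2.0,
    n_review: int = 20,
    seed: int = 0,
) -> OutlierReport:
    """Indices with |x - mean| > k * sample SD, plus a seeded random
    sample of in-range indices for manual review (default 20)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return OutlierReport(flagged=[], review_sample=[], mean=mean, sd=sd)
    flagged = np.flatnonzero(np.abs(x - mean) > k * sd)
    in_range = np.setdiff1d(np.arange(len(x)), flagged)
    rng = np.random.default_rng(seed)
    n_pick = min(n_review, len(in_range))
    review = rng.choice(in_range, size=n_pick, replace=False) if n_pick else np.array([], int)
    return OutlierReport(
        flagged=sorted(int(i) for i in flagged),
        review_sample=sorted(int(i) for i in review),
        mean=mean,
        sd=sd,
    )
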