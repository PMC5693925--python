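"""Group-level inference on fitted hemodynamic records.

Repeated measurements (several probe placements per site, seven sites,
unequal male/female group sizes) are handled with linear mixed-effects
models: the demographic factor of interest (sex, or gestational age) is
the fixed effect, and subject, hemisphere side and cortical lobe enter as
random intercepts — a random intercept per subject plus variance
components for side and lobe.  Subject-level associations with
gestational age are additionally summarized with Pearson correlations,
and demographic group comparisons with two-sample t-tests.  Repetitions
at the same site are collapsed by median before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

HEMODYNAMIC_PARAMS = ("hbt_um", "so2_frac", "cbfi_cm2s", "cmro2i")


@dataclass
class StatsResult:
    """One fitted contrast with its uncertainty."""

    parameter: str
    contrast: str
    estimate: float
    std_error: float
    p_value: float
    n_obs: int
    model: str


class DegenerateDesignError(ValueError):
    pass


def split_location(location: str) -> tuple[str, str]:
    """Split a site label into (lobe, side) on the final underscore."""
    lobe, _, side = location.rpartition("_")
    return (lobe, side) if lobe else (location, "")


def annotate_sides(records: pd.DataFrame) -> pd.DataFrame:
    """Add side/lobe columns derived from the location label."""
    out = records.copy()
    parts = out["location"].map(split_location)
    out["lobe"] = [p[0] for p in parts]
    out["side"] = [p[1] for p in parts]
    return out


def aggregate_repetitions(records: pd.DataFrame,
                          value_columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Collapse repetitions to one record per subject × location (median).

    Only QC-passed repetitions contribute when a ``qc_pass`` column is
    present; locations where every repetition failed QC are dropped.
    """
    df = records
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    if df.empty:
        return df.drop(columns=["repetition"], errors="ignore")
    if value_columns is None:
        value_columns = tuple(
            c for c in df.columns
            if c not in ("subject_id", "location", "repetition", "qc_pass",
                         "side", "lobe", "sex")
            and pd.api.types.is_numeric_dtype(df[c])
        )
    grouped = (df.groupby(["subject_id", "location"], sort=True)[list(value_columns)]
               .median().reset_index())
    return grouped


def _merge_demographics(records: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("subject_id", "sex", "ga_weeks") if c in subjects.columns]
    merged = records.merge(subjects[cols], on="subject_id", how="left")
    return annotate_sides(merged)


def _subject_mean_ttest(data: pd.DataFrame, parameter: str) -> StatsResult:
    """Fallback: two-sample t-test on per-subject means."""
    means = data.groupby(["subject_id", "sex"])[parameter].mean().reset_index()
    m = means.loc[means["sex"] == "M", parameter]
    f = means.loc[means["sex"] == "F", parameter]
    t, p = sps.ttest_ind(m, f, equal_var=False)
    diff = float(m.mean() - f.mean())
    se = float(np.sqrt(m.var(ddof=1) / len(m) + f.var(ddof=1) / len(f)))
    return StatsResult(parameter, "sex M-F", diff, se, float(p), len(means),
                       "welch t-test on subject means (LME fallback)")


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc: dict[str, str]) -> sm.regression.mixed_linear_model.MixedLMResults:
    model = sm.MixedLM.from_formula(
        formula, groups="subject_id", re_formula="1",
        vc_formula=vc, data=data,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        return model.fit(reml=True, method="lbfgs")


def _between_subject_pvalue(estimate: float, se: float, n_subjects: int) -> float:
    """Two-sided p for a subject-level fixed effect.

    Uses a t reference with n_subjects − 2 degrees of freedom: the Wald
    normal approximation is anticonservative when the effective sample
    size is the number of subjects rather than the number of records.
    """
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    df = max(n_subjects - 2, 1)
    return float(2.0 * sps.t.sf(abs(estimate / se), df))


def lme_sex_contrast(records: pd.DataFrame, subjects: pd.DataFrame,
                     parameter: str, lobe: str | None = None) -> StatsResult:
    """Male−female contrast from a mixed model with subject/side/lobe intercepts.

    ``lobe`` restricts the data to one cortical lobe first (the lobe
    variance component is then dropped from the model).  A singular or
    failed fit falls back to a Welch t-test on subject means.
    """
    data = _merge_demographics(records, subjects)
    if lobe is not None:
        data = data[data["lobe"] == lobe]
    data = data.dropna(subset=[parameter, "sex"])
    if data.groupby("sex")["subject_id"].nunique().reindex(["M", "F"]).fillna(0).min() < 2:
        raise DegenerateDesignError("need at least 2 subjects per sex")
    if data[parameter].nunique() == 1:
        return StatsResult(parameter, "sex M-F", 0.0, 0.0, 1.0, len(data),
                           "degenerate: constant response")
    vc = {"side": "0 + C(side)"}
    if lobe is None and data["lobe"].nunique() > 1:
        vc["lobe"] = "0 + C(lobe)"
    try:
        fit = _fit_mixedlm(f"{parameter} ~ C(sex, Treatment('F'))", data, vc)
        name = [n for n in fit.fe_params.index if n.startswith("C(sex")]
        est = float(fit.fe_params[name[0]])
        se = float(fit.bse[name[0]])
        p = _between_subject_pvalue(est, se, data["subject_id"].nunique())
        if not np.isfinite(se) or not np.isfinite(p):
            raise ValueError("singular mixed-model fit")
        return StatsResult(parameter, "sex M-F", est, se, p, len(data),
                           "MixedLM: sex fixed; subject intercept + side/lobe variance components")
    except (ValueError, np.linalg.LinAlgError):
        return _subject_mean_ttest(data, parameter)


def lme_ga_trend(records: pd.DataFrame, subjects: pd.DataFrame,
                 parameter: str) -> StatsResult:
    """Gestational-age slope from a mixed model (sex/side/lobe random)."""
    data = _merge_demographics(records, subjects)
    data = data.dropna(subset=[parameter, "ga_weeks"])
    if data["ga_weeks"].nunique() < 2:
        raise DegenerateDesignError("gestational age does not vary in the cohort")
    # sex has only two levels: too few for a stable variance component, so
    # subject-level heterogeneity (including sex) is carried by the subject
    # intercept
    vc = {"side": "0 + C(side)", "lobe": "0 + C(lobe)"}
    vc = {k: v for k, v in vc.items() if data[k].nunique() > 1}
    try:
        fit = _fit_mixedlm(f"{parameter} ~ ga_weeks", data, vc)
        est = float(fit.fe_params["ga_weeks"])
        se = float(fit.bse["ga_weeks"])
        p = _between_subject_pvalue(est, se, data["subject_id"].nunique())
        if not np.isfinite(se) or not np.isfinite(p):
            raise ValueError("singular mixed-model fit")
        return StatsResult(parameter, "GA slope per week", est, se, p, len(data),
                           "MixedLM: GA fixed; subject intercept + side/lobe variance components")
    except (ValueError, np.linalg.LinAlgError):
        means = data.groupby("subject_id").agg(
            y=(parameter, "mean"), ga=("ga_weeks", "first")).dropna()
        res = sps.linregress(means["ga"], means["y"])
        return StatsResult(parameter, "GA slope per week", float(res.slope),
                           float(res.stderr), float(res.pvalue), len(means),
                           "OLS on subject means (LME fallback)")


def pearson_ga(records: pd.DataFrame, subjects: pd.DataFrame,
               parameter: str) -> tuple[float, float]:
    """Pearson R (two-sided p) between GA and per-subject mean of a parameter."""
    data = records.merge(subjects[["subject_id", "ga_weeks"]], on="subject_id")
    means = data.groupby("subject_id").agg(
        y=(parameter, "mean"), ga=("ga_weeks", "first")).dropna()
    if len(means) < 3:
        raise DegenerateDesignError("need at least 3 subjects")
    if means["y"].std() == 0 or means["ga"].std() == 0:
        raise DegenerateDesignError("zero variance: Pearson R undefined")
    r, p = sps.pearsonr(means["ga"], means["y"])
    return float(r), float(p)


def demographics_ttest(subjects: pd.DataFrame, field: str) -> StatsResult:
    """Two-sample Student's t-test of a demographic field between sexes."""
    m = subjects.loc[subjects["sex"] == "M", field].dropna()
    f = subjects.loc[subjects["sex"] == "F", field].dropna()
    if len(m) < 2 or len(f) < 2:
        raise DegenerateDesignError("need at least 2 subjects per group")
    t, p = sps.ttest_ind(m, f, equal_var=True)
    pooled_var = ((len(m) - 1) * m.var(ddof=1) + (len(f) - 1) * f.var(ddof=1)) \
        / (len(m) + len(f) - 2)
    se = float(np.sqrt(pooled_var * (1 / len(m) + 1 / len(f))))
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return StatsResult(field, "sex M-F", float(m.mean() - f.mean()), se,
                       float(p), len(m) + len(f), "two-sample t-test")


def percent_side_difference(records: pd.DataFrame, parameter: str) -> float:
    """Right-vs-left percent difference, 100·(mean_R − mean_L)/mean_L.

    Computed on raw means over all lateralized records (midline sites
    excluded).
    """
    data = annotate_sides(records)
    right = data.loc[data["side"] == "right", parameter].mean()
    left = data.loc[data["side"] == "left", parameter].mean()
    if not np.isfinite(left) or left == 0:
        raise DegenerateDesignError("no left-hemisphere records")
    return float(100.0 * (right - left) / left)
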