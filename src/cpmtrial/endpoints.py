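"""Headache-diary endpoint derivation.

Turns day-level diary rows into per-subject 28-day endpoints:

* A *migraine day* is a calendar day with a headache lasting 4 or more
  hours that meets the ICHD-3 criteria, or a day on which acute
  migraine-specific medication (a triptan or ergot derivative) was used.
* MMD / MHD / medication-use days are counted over recorded days; a period
  with at least 14 recorded days (>= 50% of 28) is prorated to 28 days by
  scaling each count by 28/observed, while a period with fewer than 14
  recorded days is treated as missing.
* A *responder* achieves a 50% or greater reduction in MMDs from baseline.
* Missing endpoint changes are handled by seeded multiple imputation under
  a per-arm normal model with parameter uncertainty, pooled by Rubin's
  rules.

MHD is not given an explicit definition in the migraine-day convention
above; here a medication-only migraine day (medication taken, no recorded
headache) counts toward MHD as well, so MMD <= MHD always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EndpointError",
    "MonthlyCounts",
    "classify_migraine_day",
    "migraine_day_flags",
    "monthly_counts",
    "responder_flag",
    "derive_endpoints",
    "impute_missing",
    "ImputationBundle",
    "pool_mean_difference",
    "read_diary",
    "ENDPOINT_CHANGE_COLUMNS",
]

#: minimum recorded days for a period to be evaluable (>= 50% of 28)
MIN_OBSERVED_DAYS = 14
#: responder threshold: >= 50% reduction in MMDs from baseline
RESPONDER_THRESHOLD = 0.5

ENDPOINT_CHANGE_COLUMNS = [
    "mmd_change",
    "mhd_change",
    "med_days_change",
    "vas_change",
    "hit6_change",
    "msq_rr_change",
    "msq_rp_change",
    "msq_ef_change",
]


class EndpointError(ValueError):
    """Invalid diary data or endpoint derivation request."""


def classify_migraine_day(day: Mapping) -> bool:
    """Migraine-day rule for a single recorded diary day.

    True iff (headache AND duration >= 4 h AND meets ICHD-3 criteria) OR
    migraine-specific acute medication was used.  Unrecorded days are an
    error: callers must filter them out first.
    """
    if int(day["recorded"]) != 1:
        raise EndpointError("cannot classify an unrecorded diary day")
    by_headache = (
        bool(day["headache"])
        and float(day["duration_hours"]) >= 4.0
        and bool(day["meets_icdh3"])
    )
    return by_headache or day["med_class"] == "migraine_specific"


def migraine_day_flags(recorded: pd.DataFrame) -> pd.Series:
    """Vectorized migraine-day rule over recorded diary rows."""
    if (recorded["recorded"] != 1).any():
        raise EndpointError("cannot classify unrecorded diary days")
    by_headache = (
        (recorded["headache"] == 1)
        & (recorded["duration_hours"] >= 4.0)
        & (recorded["meets_icdh3"] == 1)
    )
    return by_headache | (recorded["med_class"] == "migraine_specific")


@dataclass
class MonthlyCounts:
    """Counts for one 28-day period; prorated values are real-valued."""

    mmd: float
    mhd: float
    med_days: float
    observed_days: int
    missing: bool


def monthly_counts(period: pd.DataFrame) -> MonthlyCounts:
    """MMD/MHD/medication-day counts for one period of <= 28 diary rows.

    Counts run over recorded days only.  14 <= observed < 28 prorates each
    count by 28/observed; observed < 14 yields missing counts (NaN) with
    the missing flag set.  Proration conserves rates exactly:
    prorated/28 == raw/observed.
    """
    if len(period) > 28:
        raise EndpointError(f"period has {len(period)} rows; at most 28 expected")
    if period["day_index"].duplicated().any():
        dupes = period.loc[period["day_index"].duplicated(), "day_index"].tolist()
        raise EndpointError(f"duplicate day_index values: {dupes}")
    recorded = period[period["recorded"] == 1]
    observed = int(len(recorded))
    if observed < MIN_OBSERVED_DAYS:
        return MonthlyCounts(np.nan, np.nan, np.nan, observed, True)
    mig = migraine_day_flags(recorded)
    mmd = float(mig.sum())
    mhd = float(((recorded["headache"] == 1) | mig).sum())
    med = float(recorded["med_class"].isin(["nonspecific", "migraine_specific"]).sum())
    factor = 28.0 / observed
    return MonthlyCounts(mmd * factor, mhd * factor, med * factor, observed, False)


def responder_flag(baseline_mmd: float, treatment_mmd: float) -> bool:
    """>= 50% reduction in MMDs from baseline (inclusive at exactly 50%)."""
    if not (np.isfinite(baseline_mmd) and np.isfinite(treatment_mmd)):
        raise EndpointError("responder status requires both MMD values")
    if baseline_mmd <= 0:
        raise EndpointError(
            "baseline MMD must be positive (zero is a data error under the "
            "trial's eligibility criteria)"
        )
    return (baseline_mmd - treatment_mmd) / baseline_mmd >= RESPONDER_THRESHOLD


def derive_endpoints(
    diary: pd.DataFrame, subjects: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-subject endpoint records from a day-level diary.

    Returns one row per subject with per-period counts, 28-day changes
    (treatment minus baseline; negative = improvement), the responder
    flag, and the missing flag (set when either period has fewer than 14
    recorded days).  If a ``subjects`` table is given, its arm/score
    columns are merged in.
    """
    required = {"subject_id", "period", "day_index", "recorded"}
    if not required.issubset(diary.columns):
        raise EndpointError(f"diary missing columns: {sorted(required - set(diary.columns))}")
    rows = []
    for sid, sub in diary.groupby("subject_id", sort=True):
        per = {}
        for period in ("baseline", "treatment"):
            per[period] = monthly_counts(sub[sub["period"] == period])
        base, treat = per["baseline"], per["treatment"]
        missing = base.missing or treat.missing
        row = {
            "subject_id": sid,
            "baseline_mmd": base.mmd,
            "treatment_mmd": treat.mmd,
            "baseline_mhd": base.mhd,
            "treatment_mhd": treat.mhd,
            "baseline_med_days": base.med_days,
            "treatment_med_days": treat.med_days,
            "observed_days_baseline": base.observed_days,
            "observed_days_treatment": treat.observed_days,
            "mmd_change": treat.mmd - base.mmd,
            "mhd_change": treat.mhd - base.mhd,
            "med_days_change": treat.med_days - base.med_days,
            "missing": missing,
        }
        if missing:
            row["responder"] = np.nan
        elif base.mmd <= 0:
            warnings.warn(
                f"{sid}: baseline MMD is 0; responder status undefined", RuntimeWarning
            )
            row["responder"] = np.nan
        else:
            row["responder"] = float(responder_flag(base.mmd, treat.mmd))
        if "arm" in diary.columns:
            row["arm"] = sub["arm"].iloc[0]
        rows.append(row)
    records = pd.DataFrame(rows)
    if subjects is not None:
        extra = subjects.drop(columns=[c for c in ("arm",) if c in records.columns],
                              errors="ignore")
        records = records.merge(extra, on="subject_id", how="left")
        # dropouts with an unevaluable treatment period also lack scores
        score_cols = [c for c in ENDPOINT_CHANGE_COLUMNS if c in records.columns]
        if score_cols:
            records["missing"] = records["missing"] | records[score_cols].isna().any(axis=1)
    return records


# ---------------------------------------------------------------------------
# multiple imputation


@dataclass
class ImputationBundle:
    """m completed endpoint tables plus the imputation bookkeeping."""

    datasets: list[pd.DataFrame]
    columns: list[str]
    seed: int
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.m = len(self.datasets)


def impute_missing(
    records: pd.DataFrame,
    columns: Sequence[str] | None = None,
    m: int = 10,
    seed: int = 0,
    arm_col: str = "arm",
) -> ImputationBundle:
    """Multiple imputation of missing endpoint changes.

    Each missing value is drawn from a per-arm normal model with parameter
    uncertainty: the variance is drawn from its scaled inverse chi-square
    posterior and the mean from its conditional normal, then the value
    itself from N(mean, variance).  With no missing data all m datasets
    equal the input.  Columns default to whichever endpoint-change columns
    are present.
    """
    if arm_col not in records.columns:
        raise EndpointError(f"records need an {arm_col!r} column for imputation")
    if columns is None:
        columns = [c for c in ENDPOINT_CHANGE_COLUMNS if c in records.columns]
    columns = list(columns)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    datasets = []
    for _ in range(m):
        filled = records.copy()
        for arm, idx in records.groupby(arm_col).groups.items():
            sub = records.loc[idx]
            for col in columns:
                obs = sub[col].dropna().to_numpy(dtype=float)
                n_missing = int(sub[col].isna().sum())
                if len(obs) == 0:
                    raise EndpointError(f"arm {arm!r} has no observed values for {col!r}")
                if n_missing == 0:
                    continue
                if len(obs) < 2:
                    raise EndpointError(
                        f"arm {arm!r} needs >= 2 observed values of {col!r} to impute"
                    )
                n0 = len(obs)
                s2 = obs.var(ddof=1)
                sigma2 = (n0 - 1) * s2 / rng.chisquare(n0 - 1)
                mu = rng.normal(obs.mean(), np.sqrt(sigma2 / n0))
                draws = rng.normal(mu, np.sqrt(sigma2), size=n_missing)
                missing_idx = sub.index[sub[col].isna()]
                filled.loc[missing_idx, col] = draws
        datasets.append(filled)
    return ImputationBundle(datasets=datasets, columns=columns, seed=seed)


def rubin_pool(estimates: np.ndarray, variances: np.ndarray) -> dict:
    """Rubin's rules: pooled estimate, total variance, df, 95% CI, p.

    Total variance T = W + (1 + 1/m) B where W is the mean within-imputation
    variance and B the between-imputation variance of the estimates.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    m = q.size
    qbar = q.mean()
    wbar = w.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t = wbar + (1 + 1 / m) * b
    if b > 0 and m > 1:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
    else:
        df = np.inf
    se = np.sqrt(t)
    if np.isfinite(df):
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else np.nan
    else:
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else np.nan
    return {
        "estimate": float(qbar),
        "variance": float(t),
        "within_variance": float(wbar),
        "between_variance": float(b),
        "df": float(df),
        "ci_low": float(qbar - crit * se),
        "ci_high": float(qbar + crit * se),
        "p": float(p),
    }


def pool_mean_difference(
    bundle: ImputationBundle,
    column: str,
    arm_col: str = "arm",
    arms: tuple[str, str] = ("real", "sham"),
) -> dict:
    """Pooled between-arm mean difference (first arm minus second) across
    the imputed datasets."""
    ests, variances = [], []
    for df in bundle.datasets:
        g1 = df.loc[df[arm_col] == arms[0], column].to_numpy(dtype=float)
        g2 = df.loc[df[arm_col] == arms[1], column].to_numpy(dtype=float)
        ests.append(g1.mean() - g2.mean())
        variances.append(g1.var(ddof=1) / len(g1) + g2.var(ddof=1) / len(g2))
    return rubin_pool(np.array(ests), np.array(variances))


def read_diary(path: str | Path) -> pd.DataFrame:
    """Read a diary CSV (schema written by the trial simulator)."""
    df = pd.read_csv(path, keep_default_na=True)
    required = {"subject_id", "period", "day_index", "recorded"}
    missing = required - set(df.columns)
    if missing:
        raise EndpointError(f"{path}: diary missing columns {sorted(missing)}")
    if "med_class" in df.columns:
        df["med_class"] = df["med_class"].fillna("")
    return df
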