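"""Randomized-trial statistics.

Between-arm comparisons of diary endpoints: the Wilcoxon rank-sum test
with the Hodges-Lehmann median-difference estimate and rank-sum-inverted
confidence interval for non-normal outcomes, Welch/pooled t tests for
normal ones, a logistic model for the responder proportion, Pearson's
chi-square for categorical beliefs, the Bang Blinding Index per arm, a
two-sample sample-size/power helper, and table-style summaries with the
trial's percentage formatting (one decimal, ties away from zero).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RankSumResult",
    "MeanDiffResult",
    "ORResult",
    "BBIResult",
    "PowerSpec",
    "hl_rank_sum",
    "mean_diff_ttest",
    "responder_logistic",
    "chi_square_test",
    "bang_blinding_index",
    "power_two_sample_t",
    "power_at_n",
    "summarize_endpoints",
    "pct",
    "format_percent",
    "render_markdown",
]

#: switch from the exact rank-sum distribution to the normal approximation
EXACT_PAIR_LIMIT = 400


@dataclass
class RankSumResult:
    hl_estimate: float
    ci_low: float
    ci_high: float
    statistic: float          # Mann-Whitney U of group 1 over group 2
    p: float
    exact_ci: bool


@dataclass
class MeanDiffResult:
    mean1: float
    mean2: float
    se1: float
    se2: float
    difference: float         # mean1 - mean2
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class BBIResult:
    """Bang Blinding Index for one arm: (correct - incorrect) / total,
    'unknown' answers included in the denominator; 0 is ideal blinding."""

    index: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class PowerSpec:
    mean1: float = 2.2
    mean2: float = 1.6
    sd1: float = 2.0
    sd2: float = 3.0
    alpha: float = 0.05
    power: float = 0.80


@functools.lru_cache(maxsize=64)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Null distribution of the Mann-Whitney U statistic (no ties).

    counts[u] is the number of arrangements of n + m ranks giving U = u;
    the classic recurrence f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u).
    """
    tables = {}
    for i in range(n + 1):
        for j in range(m + 1):
            size = i * j + 1
            row = np.zeros(size, dtype=object)
            if i == 0 or j == 0:
                row[0] = 1
            else:
                prev_i = tables[(i - 1, j)]
                prev_j = tables[(i, j - 1)]
                for u in range(size):
                    a = prev_i[u - j] if 0 <= u - j < prev_i.size else 0
                    b = prev_j[u] if u < prev_j.size else 0
                    row[u] = a + b
            tables[(i, j)] = row
    return tuple(int(v) for v in tables[(n, m)])


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = _u_counts(n, m)
    total = sum(counts)
    u = int(round(u))
    lo = sum(counts[: u + 1]) / total            # P(U <= u)
    hi = sum(counts[u:]) / total                 # P(U >= u)
    return min(1.0, 2.0 * min(lo, hi))


def _exact_ci_order(n: int, m: int, alpha: float) -> int:
    """1-based order statistic k of the sorted pairwise differences such
    that (D_(k), D_(nm+1-k)) is a >= 1-alpha confidence interval."""
    counts = _u_counts(n, m)
    total = sum(counts)
    acc = 0
    c = -1
    for u, cnt in enumerate(counts):
        acc += cnt
        if acc / total <= alpha / 2.0:
            c = u
        else:
            break
    return max(c + 1, 1)


def hl_rank_sum(x, y, alpha: float = 0.05) -> RankSumResult:
    """Wilcoxon rank-sum comparison with the Hodges-Lehmann shift estimate.

    The point estimate is the median of all n*m pairwise differences
    x_i - y_j; the CI inverts the rank-sum test (order statistics of the
    sorted pairwise differences at the Wilcoxon critical values - exact
    null distribution for n*m <= 400, normal approximation beyond).  The
    two-sided p uses the exact distribution when there are no ties and
    n*m <= 400, otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n, m = x.size, y.size
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    hl = float(np.median(diffs))

    has_ties = np.unique(np.concatenate([x, y])).size < n + m
    exact = (n * m <= EXACT_PAIR_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    u = float(res.statistic)
    p = _exact_two_sided_p(u, n, m) if exact else float(res.pvalue)

    if n * m <= EXACT_PAIR_LIMIT:
        k = _exact_ci_order(n, m, alpha)
        exact_ci = True
    else:
        sigma = np.sqrt(n * m * (n + m + 1) / 12.0)
        z = stats.norm.isf(alpha / 2.0)
        k = int(np.floor(n * m / 2.0 - z * sigma)) + 1
        k = min(max(k, 1), n * m // 2 if n * m > 1 else 1)
        exact_ci = False
    ci_low = float(diffs[k - 1])
    ci_high = float(diffs[n * m - k])
    return RankSumResult(hl, ci_low, ci_high, u, float(p), exact_ci)


def mean_diff_ttest(x, y, alpha: float = 0.05, equal_var: bool = False) -> MeanDiffResult:
    """Independent two-sample t comparison (Welch by default).

    Single-value groups are accepted as degenerate summaries: the mean
    difference is still reported, with NaN inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least 1 value")
    m1, m2 = float(x.mean()), float(y.mean())
    diff = m1 - m2
    if x.size < 2 or y.size < 2:
        return MeanDiffResult(m1, m2, np.nan, np.nan, diff, np.nan, np.nan, np.nan)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups; t test undefined")
    n1, n2 = x.size, y.size
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(1 - alpha / 2.0, df)
    return MeanDiffResult(
        m1, m2, float(np.sqrt(v1 / n1)), float(np.sqrt(v2 / n2)),
        diff, float(diff - crit * se), float(diff + crit * se), float(p),
    )


def responder_logistic(flags, arm) -> ORResult:
    """Logistic model responder ~ arm; OR = exp(coefficient), Wald 95% CI.

    ``arm`` is an indicator (1 = active arm).  Complete separation (an arm
    with all-identical outcomes) is an error suggesting an exact method.
    """
    flags = np.asarray(flags, dtype=float)
    arm = np.asarray(arm, dtype=float)
    if flags.shape != arm.shape:
        raise ValueError("flags and arm indicators must align")
    if np.unique(arm).size < 2:
        raise ValueError("both arms must be represented")
    if np.unique(flags).size < 2:
        raise ValueError("both responder outcomes must be present")
    for a in np.unique(arm):
        if np.unique(flags[arm == a]).size < 2:
            raise ValueError(
                "complete separation (an arm has a single outcome); "
                "use an exact method (exact logistic regression or Fisher's test)"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(flags, sm.add_constant(arm)).fit(disp=False)
    coef = fit.params[1]
    lo, hi = fit.conf_int()[1]
    return ORResult(float(np.exp(coef)), float(np.exp(lo)), float(np.exp(hi)),
                    float(fit.pvalues[1]))


def chi_square_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts.

    Returns (statistic, p) with (rows-1)(cols-1) degrees of freedom;
    ``yates`` applies the continuity correction (2x2 only).  Any expected
    count below 1 triggers a warning.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("need a 2-D table of non-negative counts")
    res = stats.chi2_contingency(table, correction=yates)
    if (res.expected_freq < 1).any():
        warnings.warn("expected cell count below 1; chi-square approximation is poor",
                      RuntimeWarning)
    return float(res.statistic), float(res.pvalue)


def bang_blinding_index(correct: int, incorrect: int, unknown: int = 0) -> BBIResult:
    """Bang Blinding Index for one arm from guess counts.

    index = (n_correct - n_incorrect) / n_total with "unknown" in the
    denominator; the 95% CI is the Wald interval from the multinomial
    variance of p_correct - p_incorrect.
    """
    for name, v in (("correct", correct), ("incorrect", incorrect), ("unknown", unknown)):
        if v < 0:
            raise ValueError(f"{name} count must be non-negative")
    n = correct + incorrect + unknown
    if n < 1:
        raise ValueError("arm total must be at least 1")
    pc, pi = correct / n, incorrect / n
    index = pc - pi
    var = (pc + pi - index**2) / n
    half = stats.norm.isf(0.025) * np.sqrt(max(var, 0.0))
    return BBIResult(float(index), float(index - half), float(index + half), n)


def power_two_sample_t(spec: PowerSpec = PowerSpec()) -> int:
    """Required n per group for a two-sample t test with unequal SDs.

    Iterates the standard formula n = (t_{1-a/2} + t_{1-b})^2 (s1^2 + s2^2)
    / delta^2 with Welch degrees of freedom until stable.
    """
    delta = abs(spec.mean1 - spec.mean2)
    if delta == 0:
        raise ValueError("zero effect size: required n is infinite")
    if spec.sd1 <= 0 or spec.sd2 <= 0:
        raise ValueError("SDs must be positive")
    if not (0 < spec.alpha < 1 and 0 < spec.power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    var = spec.sd1**2 + spec.sd2**2
    za = stats.norm.isf(spec.alpha / 2.0)
    zb = stats.norm.isf(1 - spec.power)
    n = (za + zb) ** 2 * var / delta**2
    for _ in range(100):
        df = _welch_df(spec.sd1, spec.sd2, max(n, 2.0))
        ta = stats.t.isf(spec.alpha / 2.0, df)
        tb = stats.t.isf(1 - spec.power, df)
        n_new = (ta + tb) ** 2 * var / delta**2
        if abs(n_new - n) < 1e-9:
            n = n_new
            break
        n = n_new
    return int(np.ceil(n))


def _welch_df(sd1: float, sd2: float, n: float) -> float:
    v1, v2 = sd1**2 / n, sd2**2 / n
    return (v1 + v2) ** 2 / (v1**2 / (n - 1) + v2**2 / (n - 1))


def power_at_n(spec: PowerSpec, n_per_group: int) -> float:
    """Achieved power of the two-sample t test at a given n per group."""
    delta = abs(spec.mean1 - spec.mean2)
    se = np.sqrt((spec.sd1**2 + spec.sd2**2) / n_per_group)
    df = _welch_df(spec.sd1, spec.sd2, n_per_group)
    tcrit = stats.t.isf(spec.alpha / 2.0, df)
    ncp = delta / se
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


# ---------------------------------------------------------------------------
# formatting and table-style summaries


def pct(k, n) -> float:
    """Percentage 100*k/n rounded to one decimal, ties away from zero."""
    value = Decimal(100) * Decimal(str(k)) / Decimal(str(n))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percent(k, n) -> str:
    return f"{pct(k, n):.1f}%"


def _fmt_median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f} to {q3:.1f})"


def _fmt_mean_se(v: np.ndarray) -> str:
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
    return f"{v.mean():.1f} ({se:.1f})"


DEFAULT_MEDIAN_OUTCOMES = [
    "mmd_change", "mhd_change", "med_days_change", "vas_change",
    "msq_rr_change", "msq_rp_change", "msq_ef_change",
]
DEFAULT_MEAN_OUTCOMES = ["hit6_change"]
DEFAULT_BINARY_OUTCOMES = ["responder"]


def summarize_endpoints(
    records: pd.DataFrame,
    arm_col: str = "arm",
    arms: tuple[str, str] = ("real", "sham"),
    median_outcomes: list[str] | None = None,
    mean_outcomes: list[str] | None = None,
    binary_outcomes: list[str] | None = None,
    primary: str = "mmd_change",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table-style per-outcome summary of two arms.

    Skewed outcomes get per-arm median (IQR) and a Hodges-Lehmann median
    difference with rank-sum CI/p; normal ones get mean (SE) and a Welch
    mean difference; binary ones get per-arm percentage (SE) and a
    logistic odds ratio.  Secondary endpoints are flagged exploratory
    (no multiplicity adjustment is applied).
    """
    if median_outcomes is None:
        median_outcomes = [c for c in DEFAULT_MEDIAN_OUTCOMES if c in records.columns]
    if mean_outcomes is None:
        mean_outcomes = [c for c in DEFAULT_MEAN_OUTCOMES if c in records.columns]
    if binary_outcomes is None:
        binary_outcomes = [c for c in DEFAULT_BINARY_OUTCOMES if c in records.columns]
    g1_all = records[records[arm_col] == arms[0]]
    g2_all = records[records[arm_col] == arms[1]]
    if g1_all.empty or g2_all.empty:
        raise ValueError(f"both arms {arms} must be present in records")

    rows = []

    def _arm_values(col):
        return (g1_all[col].dropna().to_numpy(dtype=float),
                g2_all[col].dropna().to_numpy(dtype=float))

    for col in median_outcomes:
        v1, v2 = _arm_values(col)
        res = hl_rank_sum(v1, v2, alpha=alpha)
        rows.append({
            "outcome": col,
            arms[0]: _fmt_median_iqr(v1),
            arms[1]: _fmt_median_iqr(v2),
            "estimate_type": "HL median difference",
            "estimate": res.hl_estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p": res.p,
            "exploratory": col != primary,
        })
    for col in mean_outcomes:
        v1, v2 = _arm_values(col)
        res = mean_diff_ttest(v1, v2, alpha=alpha)
        rows.append({
            "outcome": col,
            arms[0]: _fmt_mean_se(v1),
            arms[1]: _fmt_mean_se(v2),
            "estimate_type": "mean difference",
            "estimate": res.difference,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p": res.p,
            "exploratory": col != primary,
        })
    for col in binary_outcomes:
        v1, v2 = _arm_values(col)
        def _pct_se(v):
            p_hat = v.mean()
            se = 100 * np.sqrt(p_hat * (1 - p_hat) / v.size)
            return f"{pct(v.sum(), v.size):.1f} ({se:.1f})"
        flags = np.concatenate([v1, v2])
        ind = np.concatenate([np.ones(v1.size), np.zeros(v2.size)])
        try:
            orr = responder_logistic(flags, ind)
            est, lo, hi, p = orr.odds_ratio, orr.ci_low, orr.ci_high, orr.p
        except ValueError as exc:
            warnings.warn(f"{col}: {exc}", RuntimeWarning)
            est = lo = hi = p = np.nan
        rows.append({
            "outcome": col,
            arms[0]: _pct_se(v1),
            arms[1]: _pct_se(v2),
            "estimate_type": "odds ratio",
            "estimate": est,
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
            "exploratory": col != primary,
        })
    return pd.DataFrame(rows)


def render_markdown(summary: pd.DataFrame) -> str:
    """Render a summary DataFrame as a plain markdown table."""
    df = summary.copy()
    for col in ("estimate", "ci_low", "ci_high"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    if "p" in df.columns:
        df["p"] = df["p"].map(
            lambda v: "" if pd.isna(v) else ("<.001" if v < 0.001 else f"{v:.3f}")
        )
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)
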