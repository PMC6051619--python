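"""Diagnostic-accuracy statistics: ROC, cutoffs, CIs, group tests, ICC.

The toolbox a reader study needs to turn per-nodule indicator values and
pathology labels into the usual accuracy tables:

* nonparametric (Mann-Whitney) empirical AUC with DeLong variance,
  confidence intervals and the paired DeLong test for correlated ROC
  curves;
* Youden-index cutoff selection with MedCalc-style observed-value
  reporting ("<= 1.16" for indicators lowered by disease, "> 1.17" for
  indicators raised by it);
* confusion-table metrics (sensitivity, specificity, PPV, NPV, FPR, FNR,
  Youden's index) with exact Clopper-Pearson intervals;
* Student/Welch two-sample t (raw data or published mean +/- SD
  summaries), Pearson chi-square, one-sample Kolmogorov-Smirnov normality
  (with a Lilliefors option), two-way absolute-agreement ICC with an
  F-based interval, and the standard diagnostic-study sample-size formula
  N = ceil(z^2 p (1-p) / delta^2).

Directions: an indicator is "positive-if-low" when lower values indicate
malignancy (the ADCs) and "positive-if-high" when higher values do (the
high-b signal ratio).  Where a direction is not given it is auto-detected
as the one giving AUC >= 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POSITIVE_IF_LOW",
    "POSITIVE_IF_HIGH",
    "ConfusionTable",
    "YoudenResult",
    "DeLongResult",
    "TTestResult",
    "IccResult",
    "DiagnosticSummary",
    "empirical_auc",
    "youden_cutoff",
    "confusion_stats",
    "clopper_pearson_ci",
    "delong_compare",
    "auc_ci",
    "two_group_t",
    "chi_square",
    "ks_normality",
    "icc",
    "diagnostic_sample_size",
    "evaluate_indicator",
]

POSITIVE_IF_LOW = "positive-if-low"
POSITIVE_IF_HIGH = "positive-if-high"


# ---------------------------------------------------------------------------
# Core containers

@dataclass(frozen=True)
class ConfusionTable:
    """2x2 diagnostic table against the pathology reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float            # observed-value cutoff as printed ("<= c" / "> c")
    midpoint: float          # midpoint between cutoff and the next score
    direction: str
    sensitivity: float       # proportion
    specificity: float       # proportion
    youden: float
    table: ConfusionTable


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    test: str  # "student" | "welch"


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# Helpers

def _as_pos_neg(scores, labels, positive_label):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _orient(x: np.ndarray, direction: str) -> np.ndarray:
    if direction == POSITIVE_IF_HIGH:
        return x
    if direction == POSITIVE_IF_LOW:
        return -x
    raise ValueError(f"unknown direction {direction!r}")


def _auto_direction(pos: np.ndarray, neg: np.ndarray) -> str:
    """Direction under which the empirical AUC is >= 0.5."""
    auc_high = _pair_auc(pos, neg)
    return POSITIVE_IF_HIGH if auc_high >= 0.5 else POSITIVE_IF_LOW


def _pair_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC for oriented scores (higher = more diseased)."""
    gt = pos[:, None] > neg[None, :]
    eq = pos[:, None] == neg[None, :]
    return float((gt + 0.5 * eq).mean())


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    gt = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = gt.mean(axis=1)
    v01 = gt.mean(axis=0)
    return v10, v01, float(gt.mean())


# ---------------------------------------------------------------------------
# ROC / AUC

def empirical_auc(pos_scores, neg_scores, direction: str = POSITIVE_IF_HIGH) -> float:
    """Mann-Whitney empirical AUC: fraction of correctly ordered
    (positive, negative) pairs under ``direction``, ties counted 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    return _pair_auc(_orient(pos, direction), _orient(neg, direction))


def youden_cutoff(scores, labels, direction: str | None = None,
                  positive_label=1) -> YoudenResult:
    """Cutoff maximizing Youden's index J = sensitivity + specificity - 1.

    The search runs over observed score values; the decision rule is
    "score <= c is positive" for positive-if-low indicators and
    "score > c is positive" for positive-if-high ones, matching how
    printed cutoffs are quoted.  Ties on J break toward higher
    sensitivity, then the more extreme threshold.  The midpoint between
    the reported cutoff and the adjacent observed value is also returned.
    """
    pos, neg = _as_pos_neg(scores, labels, positive_label)
    if direction is None:
        direction = _auto_direction(pos, neg)
    opos, oneg = _orient(pos, direction), _orient(neg, direction)
    # Oriented rule: predict positive when oriented score > c.
    values = np.unique(np.concatenate([opos, oneg]))
    if values.size == 1:
        warnings.warn("degenerate single-valued scores; Youden index is 0")
        c = values[0]
        tp = int((opos > c).sum())
        table = ConfusionTable(tp=tp, fp=int((oneg > c).sum()),
                               fn=pos.size - tp, tn=int((oneg <= c).sum()))
        cut = float(c if direction == POSITIVE_IF_HIGH else -c)
        return YoudenResult(cut, cut, direction, 0.0, 1.0, 0.0, table)

    best = None
    for c in values:
        sens = float((opos > c).mean())
        spec = float((oneg <= c).mean())
        j = sens + spec - 1.0
        key = (j, sens, c)  # larger oriented c = more extreme positive region
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    _, c, sens, spec, j = best
    # For positive-if-high the printed rule is "> c" at the observed value
    # just below the positive region; for positive-if-low it is "<= c'"
    # where c' = -next observed oriented value... the oriented "> c" rule
    # on negated scores is "score < -c", printed as "<= largest observed
    # score strictly below -c".
    idx = int(np.searchsorted(values, c))
    nxt = values[idx + 1] if idx + 1 < values.size else c
    midpoint_oriented = (c + nxt) / 2.0
    if direction == POSITIVE_IF_HIGH:
        cutoff = float(c)
        midpoint = float(midpoint_oriented)
    else:
        # oriented values are negated scores; positive region is score < -c,
        # i.e. score <= largest observed value below -c, which is -nxt.
        cutoff = float(-nxt) if nxt != c else float(-c)
        midpoint = float(-midpoint_oriented)
    tp = int((opos > c).sum())
    fp = int((oneg > c).sum())
    table = ConfusionTable(tp=tp, fp=fp, fn=pos.size - tp, tn=neg.size - fp)
    return YoudenResult(cutoff, midpoint, direction, sens, spec, j, table)


def confusion_stats(t: ConfusionTable) -> dict[str, float]:
    """Accuracy metrics from a 2x2 table; percentages except Youden.

    Undefined ratios (zero denominators) are reported as NaN, never 0.
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else math.nan

    sens = ratio(t.tp, t.tp + t.fn)
    spec = ratio(t.tn, t.tn + t.fp)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(t.tp, t.tp + t.fp),
        "npv": ratio(t.tn, t.tn + t.fn),
        "fpr": ratio(t.fp, t.fp + t.tn),
        "fnr": ratio(t.fn, t.fn + t.tp),
        "youden": (sens + spec) / 100.0 - 1.0 if not (math.isnan(sens) or math.isnan(spec)) else math.nan,
    }
    return out


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) interval, in percent."""
    if not (0 <= successes <= n) or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    hi = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return 100.0 * float(lo), 100.0 * float(hi)


def _delong_auc_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong (structural-component) variance, oriented scores."""
    v10, v01, auc = _placements(pos, neg)
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95, direction: str | None = None,
           positive_label=1) -> tuple[float, float]:
    """DeLong-variance normal interval for the AUC, truncated to [0, 1]."""
    pos, neg = _as_pos_neg(scores, labels, positive_label)
    if direction is None:
        direction = _auto_direction(pos, neg)
    auc, var = _delong_auc_var(_orient(pos, direction), _orient(neg, direction))
    if auc in (0.0, 1.0):
        warnings.warn("degenerate AUC; interval is one-sided")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def delong_compare(scores_a, scores_b, labels, direction_a: str | None = None,
                   direction_b: str | None = None, positive_label=1) -> DeLongResult:
    """Paired DeLong test for two correlated AUCs on the same cases.

    Each indicator is oriented by its own direction (auto-detected as the
    AUC >= 0.5 orientation when unspecified) before comparison, since an
    indicator lowered by disease and one raised by it are only comparable
    after orientation.  Returns both AUCs, the z statistic of their
    difference and a two-sided normal p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("both indicators must score the same cases")
    is_pos = labels == positive_label
    if is_pos.sum() < 2 or (~is_pos).sum() < 2:
        raise ValueError("need at least 2 cases per class")
    pa, na = a[is_pos], a[~is_pos]
    pb, nb = b[is_pos], b[~is_pos]
    if direction_a is None:
        direction_a = _auto_direction(pa, na)
    if direction_b is None:
        direction_b = _auto_direction(pb, nb)
    pa, na = _orient(pa, direction_a), _orient(na, direction_a)
    pb, nb = _orient(pb, direction_b), _orient(nb, direction_b)

    v10a, v01a, auc_a = _placements(pa, na)
    v10b, v01b, auc_b = _placements(pb, nb)
    m, n = pa.size, na.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
        p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Group comparison and normality

def two_group_t(a=None, b=None, mode: str = "auto", alpha_var: float = 0.05,
                summary_a: tuple[float, float, int] | None = None,
                summary_b: tuple[float, float, int] | None = None) -> TTestResult:
    """Two-sample t test from raw data or (mean, SD, n) summaries.

    ``mode`` is "student" (pooled variance), "welch", or "auto", which
    selects Welch when a two-sided F test rejects variance equality at
    ``alpha_var``.  Published tables usually give only mean +/- SD per
    group; the summary form reproduces the test exactly from those.
    """
    if summary_a is None:
        if a is None or b is None:
            raise ValueError("provide raw samples or summary statistics")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per group")
        summary_a = (a.mean(), a.std(ddof=1), a.size)
        summary_b = (b.mean(), b.std(ddof=1), b.size)
    m1, s1, n1 = summary_a
    m2, s2, n2 = summary_b
    v1, v2 = s1**2, s2**2

    if mode == "auto":
        if v1 == 0 or v2 == 0:
            mode = "student"
        else:
            f = v1 / v2
            pf = 2 * min(stats.f.cdf(f, n1 - 1, n2 - 1), stats.f.sf(f, n1 - 1, n2 - 1))
            mode = "welch" if pf < alpha_var else "student"

    if mode == "student":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif mode == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError("mode must be 'student', 'welch' or 'auto'")
    if se == 0:
        t = 0.0  # zero variance, equal means convention
    else:
        t = (m1 - m2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), test=mode)


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 (or RxC) contingency table."""
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def ks_normality(values, method: str = "asymptotic") -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov distance to a fitted normal.

    ``method`` "asymptotic" uses the classical KS p-value against the
    normal with the sample mean and SD; "lilliefors" corrects the p-value
    for the estimated parameters (Monte-Carlo/table based).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("need n >= 4")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("constant data has no normality to test")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(vals, dist="norm")
        return float(d), float(p)
    if method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'lilliefors'")
    res = stats.kstest(vals, "norm", args=(vals.mean(), sd))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Agreement and design

def icc(ratings, level: float = 0.95) -> IccResult:
    """Two-way single-measure absolute-agreement ICC, ICC(A,1).

    ``ratings`` is an (n_cases, k_readings) array.  The estimate and the
    F-based confidence interval follow the standard mean-squares
    formulation (random cases, fixed-or-random readers, absolute
    agreement).  Zero between-case variance yields ICC 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need at least 5 cases x 2 readings")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    if np.allclose(row_means.var(), 0):
        warnings.warn("zero between-case variance; ICC is 0")
        return IccResult(0.0, math.nan, math.nan)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom

    alpha = 1.0 - level
    a = k * est / (n * (1 - est)) if est < 1 else math.inf
    b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else math.inf
    if math.isinf(a):
        return IccResult(float(est), math.nan, math.nan)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return IccResult(float(est), float(lo), float(hi))


def diagnostic_sample_size(p: float, delta: float, alpha: float = 0.05) -> int:
    """Minimum group size N = ceil(z_{alpha/2}^2 p (1-p) / delta^2).

    ``p`` is the anticipated sensitivity or specificity and ``delta`` the
    acceptable half-width of its confidence interval.  Floored at 1.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    z = stats.norm.ppf(1 - alpha / 2)
    return max(1, math.ceil(z**2 * p * (1 - p) / delta**2))


# ---------------------------------------------------------------------------
# Full indicator evaluation

#: Class labels counted as diseased for each comparison group.  The PTC
#: group includes microcarcinomas (PTMC is a size-defined subset of PTC).
_POSITIVE_SETS = {"PTC": {"PTC", "PTMC"}, "PTMC": {"PTMC"}}


@dataclass(frozen=True)
class DiagnosticSummary:
    """Everything one row of an accuracy table needs for one indicator."""

    indicator: str
    comparison_group: str
    direction: str
    cutoff: float
    cutoff_midpoint: float
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float          # percent
    sensitivity_ci: tuple[float, float]
    specificity: float          # percent
    specificity_ci: tuple[float, float]
    ppv: float
    npv: float
    fpr: float
    fnr: float
    youden: float
    table: ConfusionTable
    n_positive: int
    n_negative: int


def evaluate_indicator(cohort: pd.DataFrame, indicator: str,
                       comparison_group: str = "PTC",
                       benign_label: str = "benign",
                       level: float = 0.95) -> DiagnosticSummary:
    """Full ROC evaluation of one indicator against pathology labels.

    Selects benign rows plus the comparison group (PTC includes PTMC
    rows; PTMC uses microcarcinomas only), auto-detects the indicator's
    direction, and chains AUC + DeLong CI, Youden cutoff, the confusion
    table at that cutoff, and Clopper-Pearson intervals for sensitivity
    and specificity.
    """
    if indicator not in cohort.columns:
        raise KeyError(f"indicator column {indicator!r} missing from cohort")
    pos_set = _POSITIVE_SETS.get(comparison_group, {comparison_group})
    keep = cohort["class_label"].isin(pos_set | {benign_label})
    sub = cohort.loc[keep]
    scores = sub[indicator].to_numpy(dtype=float)
    labels = sub["class_label"].isin(pos_set).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("cohort must contain benign and diseased rows")

    pos, neg = scores[labels], scores[~labels]
    direction = _auto_direction(pos, neg)
    auc = empirical_auc(pos, neg, direction)
    ci = auc_ci(scores, labels, level=level, direction=direction, positive_label=True)
    yr = youden_cutoff(scores, labels, direction=direction, positive_label=True)
    t = yr.table
    cs = confusion_stats(t)
    sens_ci = clopper_pearson_ci(t.tp, t.tp + t.fn, level)
    spec_ci = clopper_pearson_ci(t.tn, t.tn + t.fp, level)
    return DiagnosticSummary(
        indicator=indicator,
        comparison_group=comparison_group,
        direction=direction,
        cutoff=yr.cutoff,
        cutoff_midpoint=yr.midpoint,
        auc=auc,
        auc_ci=ci,
        sensitivity=cs["sensitivity"],
        sensitivity_ci=sens_ci,
        specificity=cs["specificity"],
        specificity_ci=spec_ci,
        ppv=cs["ppv"],
        npv=cs["npv"],
        fpr=cs["fpr"],
        fnr=cs["fnr"],
        youden=cs["youden"],
        table=t,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )
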