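"""Statistical machinery tests with independent oracles.

Brute-force pair counting for the AUC, exhaustive search for the Youden
cutoff, binomial tail sums for Clopper-Pearson, paired bootstrap for the
DeLong variance, scipy for the t test and pingouin for the ICC.
"""

import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from thyrodwi.diagnostics import (
    POSITIVE_IF_HIGH,
    POSITIVE_IF_LOW,
    ConfusionTable,
    auc_ci,
    chi_square,
    clopper_pearson_ci,
    confusion_stats,
    delong_compare,
    diagnostic_sample_size,
    empirical_auc,
    evaluate_indicator,
    icc,
    ks_normality,
    two_group_t,
    youden_cutoff,
)
from thyrodwi.phantom import BENIGN_GROUP, PTC_GROUP, generate_cohort


def brute_force_auc(pos, neg):
    """Independent oracle: explicit double loop over all (pos, neg) pairs."""
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestEmpiricalAuc:
    def test_fully_separated(self):
        assert empirical_auc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_identical_multisets(self):
        assert empirical_auc([1, 2, 2, 3], [1, 2, 2, 3]) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        pos = r.integers(0, 10, size=r.integers(2, 20)).astype(float)
        neg = r.integers(0, 10, size=r.integers(2, 20)).astype(float)
        assert empirical_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    def test_direction_flip_complements(self, rng):
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 30)
        hi = empirical_auc(pos, neg, POSITIVE_IF_HIGH)
        lo = empirical_auc(pos, neg, POSITIVE_IF_LOW)
        assert hi + lo == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(1, 1, 25)
        neg = rng.normal(0, 1, 25)
        assert empirical_auc(np.exp(pos), np.exp(neg)) == pytest.approx(
            empirical_auc(pos, neg))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1.0])


def brute_force_youden(scores, labels, direction):
    """Exhaustive search over every observed threshold for max J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = -np.inf
    for c in np.unique(scores):
        if direction == POSITIVE_IF_HIGH:
            pred = scores > c
        else:
            pred = scores <= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec - 1.0)
    return best


class TestYoudenCutoff:
    def test_perfect_separation(self):
        scores = np.r_[np.full(5, 2.0), np.full(5, 8.0)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        res = youden_cutoff(scores, labels)
        assert res.youden == pytest.approx(1.0)
        assert res.midpoint == pytest.approx(5.0)
        assert 2.0 <= res.cutoff < 8.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        r = np.random.default_rng(100 + seed)
        scores = np.round(r.normal(size=20), 1)
        labels = r.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        res = youden_cutoff(scores, labels, direction=POSITIVE_IF_HIGH)
        assert res.youden == pytest.approx(
            brute_force_youden(scores, labels.astype(bool), POSITIVE_IF_HIGH))
        # the reported cutoff must reproduce the reported operating point
        pred = scores > res.cutoff
        assert pred[labels == 1].mean() == pytest.approx(res.sensitivity)
        assert (~pred[labels == 0]).mean() == pytest.approx(res.specificity)

    def test_negated_scores_flip_direction_same_j(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        hi = youden_cutoff(scores, labels, direction=POSITIVE_IF_HIGH)
        lo = youden_cutoff(-scores, labels, direction=POSITIVE_IF_LOW)
        assert hi.youden == pytest.approx(lo.youden)
        assert lo.cutoff == pytest.approx(-hi.cutoff) or lo.midpoint == pytest.approx(-hi.midpoint)

    def test_degenerate_scores_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            res = youden_cutoff([1.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res.youden == 0.0


class TestConfusionStats:
    def test_reported_accuracy_table_ptc(self):
        s = confusion_stats(ConfusionTable(tp=50, fp=9, fn=2, tn=53))
        assert round(s["sensitivity"], 2) == 96.15
        assert round(s["specificity"], 2) == 85.48
        assert round(s["ppv"], 2) == 84.75
        assert round(s["npv"], 2) == 96.36
        assert round(s["fpr"], 2) == 14.52
        assert round(s["fnr"], 2) == 3.85
        assert round(s["youden"], 2) == 0.82

    def test_reported_accuracy_table_micro(self):
        s = confusion_stats(ConfusionTable(tp=31, fp=9, fn=2, tn=53))
        assert round(s["sensitivity"], 2) == 93.94
        assert round(s["ppv"], 2) == 77.50
        assert round(s["fnr"], 2) == 6.06
        assert round(s["youden"], 2) == 0.79

    def test_all_correct(self):
        s = confusion_stats(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        assert s["sensitivity"] == 100.0 and s["specificity"] == 100.0
        assert s["youden"] == pytest.approx(1.0)

    def test_identities_hold(self, rng):
        for _ in range(10):
            t = ConfusionTable(*rng.integers(1, 50, size=4))
            s = confusion_stats(t)
            assert s["fpr"] + s["specificity"] == pytest.approx(100.0)
            assert s["fnr"] + s["sensitivity"] == pytest.approx(100.0)
            assert s["youden"] == pytest.approx(
                (s["sensitivity"] + s["specificity"]) / 100 - 1)

    def test_zero_denominator_is_nan_not_zero(self):
        s = confusion_stats(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
        assert math.isnan(s["sensitivity"])
        assert math.isnan(s["ppv"])


def cp_tail_oracle(successes, n, level=0.95):
    """Root-find the binomial tail sums defining the exact interval."""
    from scipy.optimize import brentq

    alpha = 1 - level

    def upper_tail(p):  # P(X >= successes | p) - alpha/2
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
                   for k in range(successes, n + 1)) - alpha / 2

    def lower_tail(p):  # P(X <= successes | p) - alpha/2
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
                   for k in range(0, successes + 1)) - alpha / 2

    lo = 0.0 if successes == 0 else brentq(upper_tail, 1e-12, 1 - 1e-12)
    hi = 1.0 if successes == n else brentq(lower_tail, 1e-12, 1 - 1e-12)
    return 100 * lo, 100 * hi


class TestClopperPearson:
    def test_published_sensitivity_interval(self):
        lo, hi = clopper_pearson_ci(50, 52)
        assert round(lo, 1) == 86.8
        assert round(hi, 1) == 99.5

    def test_published_specificity_interval(self):
        lo, hi = clopper_pearson_ci(53, 62)
        assert round(lo, 1) == 74.2
        assert round(hi, 1) == 93.1

    def test_boundary_all_successes(self):
        lo, hi = clopper_pearson_ci(20, 20)
        assert hi == 100.0
        assert lo > 0

    @pytest.mark.parametrize("successes,n", [(53, 62), (3, 10), (0, 15), (7, 7)])
    def test_matches_tail_sum_oracle(self, successes, n):
        got = clopper_pearson_ci(successes, n)
        expected = cp_tail_oracle(successes, n)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_coverage_is_conservative(self):
        # exact coverage by pmf enumeration must be >= the nominal level
        for p in (0.1, 0.5, 0.9):
            for n in (20, 50):
                coverage = sum(
                    sps.binom.pmf(k, n, p)
                    for k in range(n + 1)
                    if clopper_pearson_ci(k, n)[0] <= 100 * p <= clopper_pearson_ci(k, n)[1]
                )
                assert coverage >= 0.95


class TestDeLong:
    def test_identical_indicators_give_z_zero(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:4] = [0, 0, 1, 1]
        res = delong_compare(scores, scores, labels,
                             direction_a=POSITIVE_IF_HIGH, direction_b=POSITIVE_IF_HIGH)
        assert res.z == 0.0
        assert res.p == 1.0
        assert res.auc_a == res.auc_b

    def test_variance_matches_paired_bootstrap(self):
        r = np.random.default_rng(77)
        m = n = 15
        latent_pos = r.normal(1.0, 1.0, m)
        latent_neg = r.normal(0.0, 1.0, n)
        a = np.r_[latent_pos + 0.3 * r.normal(size=m), latent_neg + 0.3 * r.normal(size=n)]
        b = np.r_[latent_pos + 0.6 * r.normal(size=m), latent_neg + 0.6 * r.normal(size=n)]
        labels = np.r_[np.ones(m), np.zeros(n)].astype(int)
        res = delong_compare(a, b, labels, direction_a=POSITIVE_IF_HIGH,
                             direction_b=POSITIVE_IF_HIGH)
        assert res.z != 0
        var_delong = ((res.auc_a - res.auc_b) / res.z) ** 2

        B = 10_000
        ip = r.integers(0, m, size=(B, m))
        ineg = r.integers(0, n, size=(B, n))

        def boot_auc(scores):
            pos = scores[:m][ip]          # (B, m)
            neg = scores[m:][ineg]        # (B, n)
            cmpm = (pos[:, :, None] > neg[:, None, :]) + 0.5 * (
                pos[:, :, None] == neg[:, None, :])
            return cmpm.mean(axis=(1, 2))

        diff = boot_auc(a) - boot_auc(b)
        var_boot = diff.var(ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.4)

    def test_published_ranking_of_comparisons(self):
        # Cohorts drawn from the published group summaries must show the
        # three-point ADC much closer to the two-point high-b ADC than to
        # any signal-ratio indicator (mean |z| ordering over replicates).
        others = ["SIR_b0", "SIR_b800", "SIR_b2000", "ADC_b0_800", "ADC_b0_2000"]
        sums = {k: 0.0 for k in others}
        reps = 500
        for i in range(reps):
            df = generate_cohort((BENIGN_GROUP, PTC_GROUP), seed=10_000 + i)
            labels = (df.class_label != "benign").astype(int).to_numpy()
            ref = df["ADC_b0_800_2000"].to_numpy()
            for k in others:
                res = delong_compare(ref, df[k].to_numpy(), labels)
                sums[k] += abs(res.z)
        mean_z = {k: v / reps for k, v in sums.items()}
        for sir in ("SIR_b0", "SIR_b800", "SIR_b2000"):
            assert mean_z[sir] > mean_z["ADC_b0_2000"]
        assert mean_z["ADC_b0_2000"] == min(mean_z.values())


class TestAucCi:
    def test_identical_groups_interval_contains_half(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        lo, hi = auc_ci(scores, labels, direction=POSITIVE_IF_HIGH)
        assert lo <= 0.5 <= hi

    def test_width_shrinks_like_root_n(self):
        widths = {}
        for n in (50, 200):
            r = np.random.default_rng(5)
            scores = np.r_[r.normal(1, 1, n), r.normal(0, 1, n)]
            labels = np.r_[np.ones(n), np.zeros(n)].astype(int)
            lo, hi = auc_ci(scores, labels)
            widths[n] = hi - lo
        assert 1.5 < widths[50] / widths[200] < 2.7

    def test_against_bootstrap_percentile_interval(self):
        r = np.random.default_rng(8)
        m = n = 30
        scores = np.r_[r.normal(1, 1, m), r.normal(0, 1, n)]
        labels = np.r_[np.ones(m), np.zeros(n)].astype(int)
        lo, hi = auc_ci(scores, labels, direction=POSITIVE_IF_HIGH)
        boots = []
        for _ in range(3000):
            bp = r.choice(scores[:m], m)
            bn = r.choice(scores[m:], n)
            boots.append(empirical_auc(bp, bn))
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.06)
        assert hi == pytest.approx(bhi, abs=0.06)


class TestTwoGroupT:
    def test_identical_groups(self):
        res = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_published_summary_welch(self):
        # high-b signal-ratio group summaries: 1.53 +/- 0.95 (n=62) vs
        # 1.93 +/- 0.98 (n=52); printed p = 0.031 from unrounded data
        res = two_group_t(summary_a=(1.53, 0.95, 62), summary_b=(1.93, 0.98, 52),
                          mode="welch")
        assert res.p == pytest.approx(0.031, abs=0.005)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, 12)
        b = r.normal(0.5, 2, 17)
        for mode, equal_var in (("student", True), ("welch", False)):
            res = two_group_t(a, b, mode=mode)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert res.t == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    def test_auto_selects_welch_for_unequal_variances(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 6, 40)
        assert two_group_t(a, b, mode="auto").test == "welch"
        c = rng.normal(0, 1, 40)
        assert two_group_t(a, c, mode="auto").test == "student"


class TestChiSquare:
    def test_balanced_table(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        table = np.array([[10.0, 20.0], [30.0, 40.0]])
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        stat_oracle = ((table - expected) ** 2 / expected).sum()
        stat, p = chi_square(table)
        assert stat == pytest.approx(stat_oracle)
        assert p == pytest.approx(sps.chi2.sf(stat_oracle, 1))

    def test_row_swap_invariance(self):
        assert chi_square([[12, 7], [5, 20]]) == pytest.approx(
            chi_square([[5, 20], [12, 7]]))


class TestKsNormality:
    def test_normal_sample_small_distance(self, rng):
        d, p = ks_normality(rng.normal(10, 2, 500))
        assert d < 0.05
        assert p > 0.05

    def test_affine_invariance(self, rng):
        x = rng.normal(size=100)
        d1, _ = ks_normality(x)
        d2, _ = ks_normality(5.0 * x + 37.0)
        assert d1 == pytest.approx(d2)

    def test_exponential_sample_rejected_with_lilliefors(self):
        rejections = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=200)
            _, p = ks_normality(x, method="lilliefors")
            rejections += p < 0.05
        assert rejections >= 18

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([3.0] * 10)


class TestIcc:
    def test_duplicated_column_is_one(self, rng):
        x = rng.normal(size=20)
        res = icc(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=30)
        ratings = np.column_stack([x + rng.normal(0, 0.4, 30),
                                   x + 0.2 + rng.normal(0, 0.4, 30)])
        res = icc(ratings)
        long = pd.DataFrame({
            "case": np.repeat(np.arange(30), 2),
            "reader": np.tile([0, 1], 30),
            "score": ratings.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="case", raters="reader",
                                 ratings="score").set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
        lo, hi = row.iloc[-1]  # CI column (rounded to 2 d.p. by pingouin)
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_hand_anova_on_toy_matrix(self):
        x = np.array([[9.0, 2.0], [4.5, 4.0], [7.0, 6.0],
                      [5.0, 3.0], [8.0, 7.0], [6.0, 5.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(x).icc == pytest.approx(expected)

    def test_simulated_reader_agreement_magnitude(self):
        # case SD 1.0, reader error SD 0.33 -> ICC ~ 1/(1+0.33^2) ~ 0.90,
        # the magnitude reported for repeated nodule measurements
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            truth = r.normal(0, 1.0, 62)
            ratings = np.column_stack([truth + r.normal(0, 0.33, 62),
                                       truth + r.normal(0, 0.33, 62)])
            vals.append(icc(ratings).icc)
        assert np.mean(vals) == pytest.approx(0.90, abs=0.04)

    def test_zero_between_case_variance_warns(self):
        x = np.column_stack([np.full(6, 3.0), np.full(6, 3.0)])
        with pytest.warns(UserWarning):
            res = icc(x + np.zeros_like(x))
        assert res.icc == 0.0


class TestSampleSize:
    def test_published_design(self):
        assert diagnostic_sample_size(0.85, 0.1, 0.05) == 49

    def test_independent_formula_evaluation(self):
        assert diagnostic_sample_size(0.5, 0.05, 0.05) == 385

    def test_huge_delta_floors_at_one(self):
        assert diagnostic_sample_size(0.85, 100.0) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diagnostic_sample_size(1.5, 0.1)
        with pytest.raises(ValueError):
            diagnostic_sample_size(0.5, 0.0)


class TestEvaluateIndicator:
    def test_separable_cohort_is_perfect(self):
        import pandas as pd

        df = pd.DataFrame({
            "class_label": ["benign"] * 10 + ["PTC"] * 10,
            "ADC_b0_800_2000": np.r_[np.linspace(1.5, 2.0, 10), np.linspace(0.5, 1.0, 10)],
        })
        s = evaluate_indicator(df, "ADC_b0_800_2000", "PTC")
        assert s.auc == 1.0
        assert s.youden == pytest.approx(1.0)
        assert s.direction == POSITIVE_IF_LOW
        assert 1.0 <= s.cutoff < 1.5

    def test_ptmc_subgroup_uses_micro_rows_only(self):
        import pandas as pd

        df = pd.DataFrame({
            "class_label": ["benign"] * 6 + ["PTC"] * 4 + ["PTMC"] * 5,
            "ADC_b0_800_2000": np.r_[np.full(6, 1.5), np.full(4, 0.8), np.full(5, 0.9)],
        })
        s = evaluate_indicator(df, "ADC_b0_800_2000", "PTMC")
        assert s.n_positive == 5
        ptc = evaluate_indicator(df, "ADC_b0_800_2000", "PTC")
        assert ptc.n_positive == 9  # microcarcinomas are a subset of carcinomas

    def test_missing_indicator_column(self):
        import pandas as pd

        df = pd.DataFrame({"class_label": ["benign", "PTC"]})
        with pytest.raises(KeyError):
            evaluate_indicator(df, "SIR_b0")
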