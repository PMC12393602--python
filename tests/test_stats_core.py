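"""Statistical kernels against independent oracles and known identities."""

import numpy as np
import pytest
from scipy import stats as sps

from cnvmeta.stats_core import (
    NonIdentifiableModelError,
    StratifiedCountTable,
    StratumCounts,
    adjust_two_rounds,
    cmh_test,
    fisher_or,
    fit_burden_logistic,
    genomic_lambda,
    minp_permutation,
)


def textbook_cmh(tables):
    """Independently coded reference: score statistic, p, MH common OR."""
    num = var = R = S = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        n1, n0, m1, m0 = a + b, c + d, a + c, b + d
        if min(n1, n0, m1, m0) == 0:
            continue
        num += a - n1 * m1 / n
        var += n1 * n0 * m1 * m0 / (n ** 2 * (n - 1))
        R += a * d / n
        S += b * c / n
    stat = num ** 2 / var
    return stat, sps.chi2.sf(stat, 1), (R / S if S > 0 else np.inf)


def random_tables(rng, n_strata, max_cell=30):
    out = []
    for _ in range(n_strata):
        while True:
            t = tuple(int(x) for x in rng.integers(0, max_cell + 1, size=4))
            a, b, c, d = t
            # require an informative stratum so the statistic is defined
            if min(a + b, c + d, a + c, b + d) > 0:
                out.append(t)
                break
    return out


class TestCMH:
    def test_single_stratum_matches_implied_sample_or(self):
        res = cmh_test([(5, 5197, 1, 8666)])
        assert res.or_mh == pytest.approx(8.34, abs=0.005)

    def test_identical_null_strata_give_null_result(self):
        t = [(10, 90, 10, 90), (10, 90, 10, 90)]
        res = cmh_test(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0
        assert res.or_mh == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(100):
            tables = random_tables(rng, int(rng.integers(1, 5)))
            res = cmh_test(tables)
            if res.degenerate:
                continue
            stat, p, or_mh = textbook_cmh(tables)
            assert res.statistic == pytest.approx(stat, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)
            if np.isfinite(or_mh):
                assert res.or_mh == pytest.approx(or_mh, rel=1e-8)

    def test_matches_statsmodels_stratified_table(self, rng):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        for _ in range(30):
            tables = random_tables(rng, 3)
            arr = np.array([[[a, b], [c, d]] for a, b, c, d in tables])
            arr = np.transpose(arr, (1, 2, 0))  # 2x2xk
            st = sm_ct.StratifiedTable(arr.astype(float))
            res = cmh_test(tables)
            assert res.statistic == pytest.approx(
                float(st.test_null_odds(correction=False).statistic), abs=1e-8
            )
            assert res.or_mh == pytest.approx(float(st.oddsratio_pooled), rel=1e-8)
            lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
            assert res.ci_low == pytest.approx(float(lo), rel=1e-6)
            assert res.ci_high == pytest.approx(float(hi), rel=1e-6)

    def test_stratum_order_and_empty_strata_invariance(self, rng):
        tables = random_tables(rng, 3)
        base = cmh_test(tables)
        shuffled = cmh_test(tables[::-1])
        padded = cmh_test(tables + [(0, 50, 0, 70)])
        for other in (shuffled, padded):
            assert other.statistic == pytest.approx(base.statistic, rel=1e-12)
            assert other.or_mh == pytest.approx(base.or_mh, rel=1e-12)

    def test_all_degenerate_strata_flagged(self):
        res = cmh_test([(0, 10, 0, 10), (0, 5, 0, 5)])
        assert res.degenerate and res.p == 1.0 and res.or_mh is None

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            res = cmh_test(random_tables(rng, 2))
            if res.ci_low is not None:
                assert res.ci_low <= res.or_mh <= res.ci_high

    def test_simpson_reversal_controlled(self):
        """Pooling strata with opposite case mixes inflates the crude OR;
        the stratified common OR stays near the within-stratum truth (1)."""
        # same carrier rates for case/control within each stratum,
        # but rates and case fractions both differ across strata
        t1 = (5, 95, 45, 855)    # 5% carriers, 10% cases
        t2 = (180, 720, 20, 80)  # 20% carriers, 90% cases
        res = cmh_test([t1, t2])
        assert res.or_mh == pytest.approx(1.0, abs=0.05)
        assert res.p > 0.5
        pooled = (t1[0] + t2[0], t1[1] + t2[1], t1[2] + t2[2], t1[3] + t2[3])
        crude_or = (pooled[0] * pooled[3]) / (pooled[1] * pooled[2])
        assert crude_or > 2.0  # confounding visibly inflates the crude OR

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cmh_test([])


class TestStratumCounts:
    def test_carriers_bounded_by_totals(self):
        with pytest.raises(ValueError):
            StratumCounts("s", case_carriers=6, case_total=5,
                          control_carriers=0, control_total=5)

    def test_duplicate_stratum_rejected(self):
        s = StratumCounts("s", 1, 10, 1, 10)
        with pytest.raises(ValueError):
            StratifiedCountTable("L", "DEL", (s, s))


class TestFisher:
    def test_printed_rate_table(self):
        or_, p = fisher_or(5, 5197, 1, 8666)
        assert or_ == pytest.approx(8.34, abs=0.005)
        assert p == pytest.approx(0.03, abs=0.005)

    def test_degenerate_tables(self):
        assert fisher_or(1, 1, 1, 1) == (1.0, 1.0)
        or_, _ = fisher_or(3, 7, 3, 7)
        assert or_ == pytest.approx(1.0)
        or_, _ = fisher_or(2, 5, 0, 7)
        assert or_ == np.inf

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_or(0, 0, 0, 0)


def simulate_burden_cohort(rng, n=2000, true_or=1.5):
    group = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    base = np.where(group == "A", -0.4, 0.4)
    burden = rng.poisson(1.0, size=n).astype(float)
    logit = base + np.log(true_or) * burden
    status = rng.random(n) < 1 / (1 + np.exp(-logit))
    lrr = rng.normal(0.12, 0.02, size=n)
    nraw = rng.poisson(3, size=n)
    return status.astype(int), burden, group, lrr, nraw


class TestBurdenLogistic:
    def test_recovers_planted_or_with_nominal_coverage(self, rng):
        covered = 0
        n_rep = 25
        for _ in range(n_rep):
            status, burden, group, lrr, nraw = simulate_burden_cohort(rng)
            res = fit_burden_logistic(status, burden, group, lrr, nraw)
            if res.ci_low <= 1.5 <= res.ci_high:
                covered += 1
        assert covered >= int(0.8 * n_rep)  # 95% nominal, binomial slack

    def test_null_effect_centered_at_zero(self, rng):
        logors = []
        for _ in range(40):
            status, burden, group, lrr, nraw = simulate_burden_cohort(rng, true_or=1.0)
            res = fit_burden_logistic(status, burden, group, lrr, nraw)
            logors.append(np.log(res.or_mh))
        mean = np.mean(logors)
        se = np.std(logors, ddof=1) / np.sqrt(len(logors))
        assert abs(mean) < 3 * se + 0.02

    def test_constant_burden_not_identifiable(self, rng):
        status, burden, group, lrr, nraw = simulate_burden_cohort(rng)
        with pytest.raises(NonIdentifiableModelError):
            fit_burden_logistic(status, np.zeros_like(burden), group, lrr, nraw)

    def test_perfect_separation_detected(self):
        n = 200
        status = np.array([0] * 100 + [1] * 100)
        burden = status.astype(float) * 5  # separates perfectly
        group = np.array(["A", "B"] * 100)
        with pytest.raises(NonIdentifiableModelError):
            fit_burden_logistic(status, burden, group,
                                np.full(n, 0.1), np.full(n, 2))


class TestMinPPermutation:
    def _toy(self, rng, n_loci=4, p_carrier=0.3, n_per=20):
        carrier = rng.random((2 * n_per, n_loci)) < p_carrier
        strata = [np.arange(n_per), np.arange(n_per, 2 * n_per)]
        is_case = np.zeros(2 * n_per, bool)
        is_case[: n_per // 2] = True
        is_case[n_per: n_per + n_per // 2] = True
        return carrier, strata, is_case

    def test_no_carriers_gives_unit_pvalues(self, rng):
        carrier = np.zeros((40, 5))
        strata = [np.arange(20), np.arange(20, 40)]
        is_case = np.tile([True] * 10 + [False] * 10, 2)
        res = minp_permutation(carrier, strata, is_case, n_perm=200, seed=0)
        assert np.all(res.p_observed == 1.0)
        assert res.null.threshold == 1.0
        assert np.all(res.p_adjusted == 1.0)

    def test_deterministic_given_seed(self, rng):
        carrier, strata, is_case = self._toy(rng)
        a = minp_permutation(carrier, strata, is_case, n_perm=500, seed=9)
        b = minp_permutation(carrier, strata, is_case, n_perm=500, seed=9)
        assert np.array_equal(a.null.min_p, b.null.min_p)
        assert a.null.threshold == b.null.threshold
        assert np.array_equal(a.p_adjusted, b.p_adjusted)

    def test_adjusted_p_monotone_in_observed_p(self, rng):
        carrier, strata, is_case = self._toy(rng, n_loci=8)
        res = minp_permutation(carrier, strata, is_case, n_perm=1000, seed=1)
        order = np.argsort(res.p_observed)
        assert np.all(np.diff(res.p_adjusted[order]) >= 0)

    def test_adjusted_p_at_least_raw_p(self, rng):
        carrier, strata, is_case = self._toy(rng, n_loci=8)
        res = minp_permutation(carrier, strata, is_case, n_perm=1000, seed=2)
        assert np.all(res.p_adjusted >= res.p_observed - 1e-12)

    def test_small_n_perm_warns(self, rng):
        carrier, strata, is_case = self._toy(rng)
        with pytest.warns(UserWarning, match="n_perm"):
            minp_permutation(carrier, strata, is_case, n_perm=50, seed=0)

    def test_empty_loci_rejected(self):
        with pytest.raises(ValueError):
            minp_permutation(np.zeros((10, 0)), [np.arange(10)],
                             np.zeros(10, bool), n_perm=200)


class TestAdjustTwoRounds:
    @pytest.mark.parametrize("p,expected", [(0.25, 0.50), (0.70, 1.0), (1.0, 1.0)])
    def test_doubling_capped_at_one(self, p, expected):
        assert adjust_two_rounds(p) == pytest.approx(expected)

    def test_monotone_and_idempotent_at_one(self, rng):
        ps = np.sort(rng.uniform(1e-6, 1.0, size=50))
        out = adjust_two_rounds(ps)
        assert np.all(np.diff(out) >= 0)
        assert adjust_two_rounds(1.0) == 1.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            adjust_two_rounds(bad)


class TestGenomicLambda:
    def test_null_median_is_unity(self):
        assert genomic_lambda([0.5]) == pytest.approx(1.0)

    def test_uniform_pvalues_calibrated(self, rng):
        p = rng.uniform(size=10_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.05)

    def test_inflation_under_halved_pvalues(self, rng):
        p = rng.uniform(size=10_000)
        assert genomic_lambda(np.clip(p / 2, 1e-12, 1.0)) > 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda([])
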