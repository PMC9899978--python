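"""Outcome-association statistics: closed forms, oracles and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from numpy.random import default_rng
from scipy import stats as sps

from arimap import GeneratorConfig, generate_cohort
from arimap.stats import (
    compare_repeated,
    cox_univariate,
    km_logrank,
    logrank_statistic,
    outcome_associations,
    roc_analysis,
    site_chisquare,
    univariate_linear,
    univariate_logistic,
)


class TestCompareRepeated:
    def test_identical_time_points_give_null_result(self):
        df = pd.DataFrame({0.0: [1, 2, 3, 4, 5]} | {t: [1, 2, 3, 4, 5] for t in (1.0, 2.5)})
        out = compare_repeated(df)
        assert out["friedman_statistic"] == 0.0 and out["friedman_p"] == 1.0
        assert (out["pairwise"]["p_bonferroni"] == 1.0).all()

    def test_perfectly_ordered_ranks_reach_closed_form(self):
        """Strictly increasing values over k=4 time-points give the maximal
        Friedman statistic 3n (rank formula with perfect ordering)."""
        n = 8
        df = pd.DataFrame({t: np.arange(n) * 0.1 + 10 * t for t in (0.0, 1.0, 2.5, 5.0)})
        out = compare_repeated(df)
        assert out["friedman_statistic"] == pytest.approx(3 * n)

    def test_animal_order_invariance(self):
        rng = default_rng(2)
        df = pd.DataFrame(rng.normal(300, 20, size=(10, 4)),
                          columns=[0.0, 1.0, 2.5, 5.0])
        a = compare_repeated(df)
        b = compare_repeated(df.sample(frac=1.0, random_state=3))
        assert a["friedman_statistic"] == pytest.approx(b["friedman_statistic"])
        assert a["pairwise"]["p_raw"].tolist() == pytest.approx(
            b["pairwise"]["p_raw"].tolist())


class TestLogistic:
    def test_saturated_binary_design_equals_cross_product_ratio(self):
        """2x2 design a=8 b=2 c=1 d=7: MLE odds ratio = (8*7)/(2*1) = 28."""
        x = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 7, dtype=float)
        y = np.array([1] * 10 + [0] * 8, dtype=float)
        res = univariate_logistic(y, x)
        assert res.estimate == pytest.approx(28.0, abs=1e-6)

    def test_rescaling_changes_or_not_p(self):
        rng = default_rng(4)
        x = rng.normal(450, 30, 60)
        y = (rng.uniform(size=60) < 1 / (1 + np.exp(-(x - 450) * 0.05))).astype(float)
        res_ms = univariate_logistic(y, x)
        res_s = univariate_logistic(y, x / 1000.0)
        assert np.log(res_s.estimate) == pytest.approx(1000 * np.log(res_ms.estimate),
                                                       rel=1e-6)
        assert res_s.p_value == pytest.approx(res_ms.p_value, rel=1e-6)

    def test_separation_flagged(self):
        x = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        assert univariate_logistic(y, x).flag == "separation"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_logistic(np.ones(10), np.arange(10.0))


class TestLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = univariate_linear(x, x)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-10)

    def test_small_noise_limit(self):
        rng = default_rng(6)
        x = rng.uniform(300, 400, 50)
        y = 0.5 * x + rng.normal(0, 1e-6, 50)
        assert univariate_linear(y, x).estimate == pytest.approx(0.5, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            univariate_linear(np.arange(5.0), np.ones(5))


def _brute_force_auc(events, nonevents):
    wins = 0.0
    for e in events:
        for c in nonevents:
            wins += 1.0 if e > c else 0.5 if e == c else 0.0
    return wins / (len(events) * len(nonevents))


def _brute_force_youden(events, nonevents):
    best = (-np.inf, None)
    for c in sorted(set(list(events) + list(nonevents))):
        sens = np.mean([e > c for e in events])
        spec = np.mean([x <= c for x in nonevents])
        j = sens + spec - 1
        if j > best[0]:
            best = (j, c)
    return best[1]


class TestRoc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        res = roc_analysis(y, x)
        assert res.auc == 1.0
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_constant_covariate_all_ties(self):
        res = roc_analysis(np.array([0, 1, 0, 1.0]), np.ones(4))
        assert res.auc == 0.5

    def test_interleaved_example(self):
        """4 events {10,20,30,40} vs 4 non-events {5,15,25,35}: 10 of 16
        pairs concordant, AUC = 0.625."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        x = np.array([10, 20, 30, 40, 5, 15, 25, 35], dtype=float)
        assert roc_analysis(y, x).auc == 10 / 16

    def test_matches_brute_force_on_random_cohorts(self):
        rng = default_rng(8)
        for _ in range(25):
            n = int(rng.integers(8, 50))
            x = np.round(rng.normal(450, 25, n), 1)
            y = (rng.uniform(size=n) < 0.4).astype(float)
            if y.sum() in (0, n):
                continue
            res = roc_analysis(y, x)
            assert res.auc == _brute_force_auc(x[y == 1], x[y == 0])
            assert res.optimal_cutoff == _brute_force_youden(x[y == 1], x[y == 0])

    def test_youden_tie_takes_lower_cutoff(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        x = np.array([1, 2, 3, 4], dtype=float)
        # J is tied across several cutoffs; the lowest must be reported
        res = roc_analysis(y, x)
        assert res.optimal_cutoff == _brute_force_youden(x[y == 1], x[y == 0])


class TestCox:
    def test_constant_covariate_flagged(self):
        res = cox_univariate([1, 2, 3, 4.0], [1, 1, 0, 0], np.ones(4))
        assert res.flag == "degenerate"

    def test_symmetric_groups_give_unit_hazard(self):
        t = np.array([1, 2, 3, 1, 2, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0.0])
        x = np.array([0, 0, 0, 1, 1, 1.0])
        res = cox_univariate(t, e, x)
        assert res.estimate == pytest.approx(1.0, abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2.0], [0, 0], [1, 2.0])

    def test_recovers_positive_association(self):
        rng = default_rng(12)
        n = 300
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / np.exp(0.4 * x))
        cens = np.quantile(t, 0.8)
        e = (t <= cens).astype(float)
        res = cox_univariate(np.minimum(t, cens), e, x)
        assert res.ci_low <= np.exp(0.4) <= res.ci_high


class TestKaplanMeierLogrank:
    def test_identical_groups_null_statistic(self):
        t = np.array([1, 2, 3, 1, 2, 3.0])
        e = np.array([1, 1, 1, 1, 1, 1.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        fit = km_logrank(t, e, g)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_event_worked_example(self):
        """Events at 1 and 2 min vs two censored animals: O-E = 7/6 and
        V = 17/36, so chi-square = 49/17."""
        t = np.array([1.0, 2.0, 10.0, 10.0])
        e = np.array([1, 1, 0, 0])
        g = np.array(["a", "a", "b", "b"])
        stat, p = logrank_statistic(t, e, g)
        assert stat == pytest.approx(49 / 17, abs=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(49 / 17, 1)), abs=1e-12)

    @staticmethod
    def _oracle_o_minus_e_and_var(t, e, g):
        """Independent per-event-time loop over the O-E / hypergeometric terms."""
        o_minus_e, var = 0.0, 0.0
        for tt in sorted(set(t[e == 1])):
            n = (t >= tt).sum()
            n1 = ((t >= tt) & (g == 1)).sum()
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        return o_minus_e, var

    def test_duplication_doubles_observed_minus_expected(self):
        """Exact duplication of every subject leaves the survival curves
        unchanged and doubles the summed O-E; the statistic follows the
        closed form with the tied-event variance terms."""
        t = np.array([1.0, 2.0, 3.0, 10.0, 10.0, 4.0])
        e = np.array([1, 1, 0, 0, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        t2, e2, g2 = np.tile(t, 2), np.tile(e, 2), np.tile(g, 2)
        oe1, v1 = self._oracle_o_minus_e_and_var(t, e, g)
        oe2, v2 = self._oracle_o_minus_e_and_var(t2, e2, g2)
        assert oe2 == pytest.approx(2 * oe1, rel=1e-12)
        s1, _ = logrank_statistic(t, e, g)
        s2, _ = logrank_statistic(t2, e2, g2)
        assert s1 == pytest.approx(oe1 ** 2 / v1, rel=1e-12)
        assert s2 == pytest.approx(oe2 ** 2 / v2, rel=1e-12)
        f1 = km_logrank(t, e, g)
        f2 = km_logrank(t2, e2, g2)
        for k in f1.curves:
            pd.testing.assert_frame_equal(f1.curves[k], f2.curves[k])

    def test_agrees_with_lifelines(self):
        rng = default_rng(14)
        t = rng.exponential(5, 40)
        e = (rng.uniform(size=40) < 0.7).astype(int)
        g = (rng.uniform(size=40) < 0.5).astype(int)
        ours, _ = logrank_statistic(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_km_without_censoring_is_empirical_survival(self):
        t = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        fit = km_logrank(np.concatenate([t, t + 0.5]),
                         np.ones(10), np.array([0] * 5 + [1] * 5))
        curve = fit.curves["0"].set_index("time")["survival"]
        for tt in t:
            assert curve.loc[tt] == pytest.approx((t > tt).mean())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestSiteChiSquare:
    def test_printed_cohort_table(self):
        """5/9 vs 4/9 VF by occlusion site: chi-square 0.222 (3 s.f.)."""
        site = ["LAD"] * 9 + ["LCX"] * 9
        vf = [True] * 5 + [False] * 4 + [True] * 4 + [False] * 5
        out = site_chisquare(site, vf)
        assert out["chi2"] == pytest.approx(0.222, abs=5e-4)

    def test_balanced_table_is_null(self):
        site = ["LAD"] * 10 + ["LCX"] * 10
        vf = ([True] * 5 + [False] * 5) * 2
        assert site_chisquare(site, vf)["chi2"] == 0.0

    def test_row_swap_symmetric(self):
        site = ["LAD"] * 9 + ["LCX"] * 9
        vf = [True] * 5 + [False] * 4 + [True] * 4 + [False] * 5
        swapped = ["LCX"] * 9 + ["LAD"] * 9
        assert site_chisquare(site, vf)["chi2"] == \
            pytest.approx(site_chisquare(swapped, vf)["chi2"])

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            site_chisquare(["LAD"] * 4, [True, False, True, False])


class TestOutcomeAssociations:
    def test_tidy_screen_over_generated_cohort(self):
        ds = generate_cohort(GeneratorConfig(n_animals=40, seed=55, signals=False))
        # build a minimal summary table from ground truth
        rows = []
        for (animal, t), grp in ds.truth.epi.groupby(["animal", "time_point"]):
            ecg = ds.truth.ecg.query("animal == @animal and time_point == @t")
            rows.append({"animal": animal, "time_point": t,
                         "aric_max": grp["true_aric"].max(),
                         "qtc_max": ecg["true_qtc"].max()})
        summaries = pd.DataFrame(rows)
        out = outcome_associations(summaries, ds.cohort,
                                   covariates=("aric_max", "qtc_max"))
        assert set(out["covariate"]) == {"aric_max", "qtc_max"}
        assert (out["scale"] == "OR").all()
        # the generating model is positive in QTc, so the screen should be too
        assert out.loc[out["covariate"] == "qtc_max", "estimate"].iloc[0] > 1.0

    def test_modes_both_run(self):
        ds = generate_cohort(GeneratorConfig(n_animals=30, seed=56, signals=False))
        rows = [{"animal": a, "time_point": t, "aric_max": g["true_aric"].max()}
                for (a, t), g in ds.truth.epi.groupby(["animal", "time_point"])]
        summaries = pd.DataFrame(rows)
        pooled = outcome_associations(summaries, ds.cohort, covariates=("aric_max",))
        reduced = outcome_associations(summaries, ds.cohort, covariates=("aric_max",),
                                       mode="per_animal_max")
        assert pooled["n"].iloc[0] > reduced["n"].iloc[0] == 30
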