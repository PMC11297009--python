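"""Survival machinery against hand-computed tables and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatsig.survival_stats import (_two_group_logrank_chi2, cox_fit,
                                    km_estimate, logrank, optimal_cutpoint,
                                    time_dependent_auc)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored_flat_curve(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.median is None
        assert km.times.size == 0

    def test_ten_subject_hand_table(self):
        """Product-limit table computed by hand:
        S = 9/10, 4/5, 24/35, 96/175, 72/175, 36/175 at the six event times."""
        times = [2, 3, 3, 5, 7, 8, 10, 12, 14, 15]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        km = km_estimate(times, events)
        np.testing.assert_allclose(
            km.survival,
            [9 / 10, 4 / 5, 24 / 35, 96 / 175, 72 / 175, 36 / 175])
        np.testing.assert_array_equal(km.times, [2, 3, 5, 8, 10, 14])
        np.testing.assert_array_equal(km.at_risk, [10, 9, 7, 5, 4, 2])
        assert km.median == 10.0      # earliest time with S <= 0.5

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 50)
        km = km_estimate(t, np.ones(50, int))
        for q in (0.25, 0.5, 0.75):
            tq = np.quantile(t, q)
            assert km.survival_at(tq) == pytest.approx((t > tq).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        res = logrank([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                      ["A", "A", "A", "B", "B", "B"])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_value(self):
        """Alternating event times 1..6: by hand O_A=3, E_A=67/30,
        V=1091/900, chi2 = (23/30)² / (1091/900) = 529/1091."""
        res = logrank([1, 3, 5, 2, 4, 6], [1] * 6,
                      ["A", "A", "A", "B", "B", "B"])
        assert res.chi_square == pytest.approx(529 / 1091, rel=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(529 / 1091, 1), rel=1e-12)

    def test_relabeling_invariance(self, rng):
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        g = rng.choice(["A", "B"], 40)
        swapped = np.where(g == "A", "B", "A")
        assert logrank(t, e, g).chi_square == pytest.approx(
            logrank(t, e, swapped).chi_square)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], ["A", "A"])

    def test_fast_two_group_matches_lifelines(self, rng):
        """The hand-rolled scan statistic agrees with the library test."""
        for _ in range(5):
            t = rng.exponential(20, 60)
            e = rng.integers(0, 2, 60)
            hi = rng.random(60) > 0.5
            if hi.all() or (~hi).any() is False or e.sum() == 0:
                continue
            mine = _two_group_logrank_chi2(t, e.astype(int), hi)
            ref = logrank(t, e, np.where(hi, "h", "l")).chi_square
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_power_at_planted_hazard_ratio(self):
        """HR 2.5 between groups of 150: detected at alpha=0.05 in >=90% of seeds."""
        detected = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            lam = np.r_[np.full(150, 0.02), np.full(150, 0.05)]
            t = rng.exponential(1 / lam)
            c = np.minimum(rng.exponential(60, 300), 84.0)
            obs = np.minimum(t, c)
            e = (t <= c).astype(int)
            g = np.r_[np.zeros(150), np.ones(150)]
            detected += logrank(obs, e, g).p_value < 0.05
        assert detected >= 0.9 * n_rep


class TestCox:
    def test_tiny_fixture_against_grid_search(self):
        """Log partial likelihood at the lifelines optimum matches a 1-D grid
        search oracle over beta, and the argmax agrees."""
        t = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.3, 7.7, 9.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])

        def loglik(beta):
            # Breslow = Efron here (no tied event times)
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    risk = x[t >= t[i]]
                    ll += beta * x[i] - np.log(np.exp(beta * risk).sum())
            return ll

        grid = np.linspace(-3, 3, 60001)
        lls = np.array([loglik(b) for b in grid])
        b_star = grid[lls.argmax()]
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.log_likelihood == pytest.approx(lls.max(), abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(b_star, abs=1e-3)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            cox_fit(pd.DataFrame({"x": np.ones(30)}),
                    np.arange(1, 31, dtype=float), np.ones(30, int))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0, 0.0]}), [1, 2, 3], [1, 0, 0])

    def test_hazard_ratio_recovery(self):
        """Binary covariate with true HR 2: estimates center on it."""
        hrs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 1000).astype(float)
            lam = 0.02 * 2.0 ** x
            t = rng.exponential(1 / lam)
            fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(1000, int))
            hrs.append(fit.hazard_ratios["x"])
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.1)

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (100, 400, 1600):
            ests = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                x = rng.standard_normal(n)
                t = rng.exponential(1 / (0.02 * np.exp(0.7 * x)))
                ests.append(cox_fit(pd.DataFrame({"x": x}), t,
                                    np.ones(n, int)).coefficients["x"])
            errs[n] = abs(np.mean(ests) - 0.7)
        assert errs[1600] < errs[100] + 0.05
        assert errs[1600] < 0.05


class TestOptimalCutpoint:
    def test_balanced_constraint_forces_median(self):
        rng = np.random.default_rng(2)
        s = np.arange(10, dtype=float)
        res = optimal_cutpoint(s, rng.exponential(10, 10), np.ones(10, int),
                               min_group_frac=0.5)
        assert res.cutoff == pytest.approx(4.5)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(np.ones(30), np.arange(1, 31, dtype=float),
                             np.ones(30, int))

    def test_beats_median_split_by_construction(self, rng):
        s = rng.normal(0, 1, 80)
        t = rng.exponential(1 / (0.03 * np.exp(0.5 * s)))
        e = np.ones(80, int)
        res = optimal_cutpoint(s, t, e)
        chi_median = _two_group_logrank_chi2(t, e, s > np.median(s))
        assert res.chi_square >= chi_median - 1e-12

    def test_hazard_jump_located(self):
        """Scores 1..100 with a hazard jump planted at 60: the cutoff lands
        nearby in >= 90% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = np.arange(1, 101, dtype=float)
            lam = np.where(s > 60, 0.15, 0.01)
            t = rng.exponential(1 / lam)
            res = optimal_cutpoint(s, t, np.ones(100, int))
            hits += 55 <= res.cutoff <= 65
        assert hits >= 18


class TestTimeDependentAUC:
    def test_null_score_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 500
            t = rng.exponential(40, n)
            c = np.minimum(rng.exponential(60, n), 84.0)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            score = rng.normal(0, 1, n)
            aucs.append(time_dependent_auc(score, obs, e, 36.0).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_perfect_ranking_auc_one(self):
        t = np.arange(1, 101, dtype=float)
        assert time_dependent_auc(-t, t, np.ones(100, int), 50.0).auc == 1.0

    def test_reduces_to_static_auc_without_censoring(self, rng):
        """With no censoring the IPCW AUC equals the plain Mann–Whitney AUC of
        cases (events by the horizon) vs survivors past the horizon."""
        n = 200
        t = rng.exponential(30, n)
        e = np.ones(n, int)
        score = -t + rng.normal(0, 10, n)
        horizon = 25.0
        auc = time_dependent_auc(score, t, e, horizon).auc
        cases, ctrl = score[t <= horizon], score[t > horizon]
        wins = sum((x > y) + 0.5 * (x == y) for x in cases for y in ctrl)
        assert auc == pytest.approx(wins / (len(cases) * len(ctrl)), rel=1e-9)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1.0, 2.0], [50.0, 60.0], [1, 1], 10.0)
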