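"""Wilcoxon / Friedman / Holm machinery, EOD mixed model, repeatability ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import shuttlebox as sb
from shuttlebox.errors import DegenerateTestError, InsufficientDataError


def exact_signed_rank_p(values, mu=0.0):
    """Brute-force two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(values, float) - mu
    d = d[d != 0]
    ranks = sst.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(np.dot(signs, ranks))
    dist = np.asarray(dist)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return float(((dist <= lo).sum() + (dist >= hi).sum()) / len(dist))


class TestOneSampleWilcoxon:
    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 9), (3, 10)])
    def test_exact_p_matches_sign_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(55, 10, n), 3)  # continuous -> no ties
        res = sb.one_sample_wilcoxon(vals, 50.0)
        assert res.p == pytest.approx(exact_signed_rank_p(vals, 50.0), abs=1e-12)

    def test_symmetric_values_not_significant(self):
        vals = 50.0 + np.array([-3, -2, -1, 1, 2, 3, -0.5, 0.5])
        assert sb.one_sample_wilcoxon(vals, 50.0).p >= 0.5

    def test_strong_side_preference_is_significant(self):
        # every fish >= 79 % on one side vs the 50 % null
        occ = [100, 100, 100, 100, 100, 100, 100, 100, 100, 100,
               96, 91, 88, 85, 81, 79]
        res = sb.one_sample_wilcoxon(occ, 50.0)
        assert res.p < 0.001

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateTestError):
            sb.one_sample_wilcoxon([50.0] * 8, 50.0)


class TestFriedman:
    def test_identical_columns_give_zero_statistic_p_one(self):
        m = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 6))
        res = sb.friedman_test(m)
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_strictly_ordered_columns_reach_maximal_statistic(self):
        n, k = 16, 17
        rng = np.random.default_rng(0)
        base = np.add.outer(rng.normal(0, 1, n), np.arange(k, dtype=float))
        res = sb.friedman_test(base)
        assert res.statistic == pytest.approx(n * (k - 1))
        assert res.p < 1e-10

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        m = rng.normal(0, 1, (12, 5))
        res = sb.friedman_test(m)
        ref = sst.friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(1, 2, (10, 6))
        a = sb.friedman_test(m).statistic
        b = sb.friedman_test(np.exp(3 * m)).statistic
        assert a == pytest.approx(b)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 4))
        m[0, 0] = np.nan
        with pytest.raises(InsufficientDataError):
            sb.friedman_test(m)


class TestHolm:
    def test_worked_example(self):
        adj = sb.holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 1, 16)
        adj = sb.holm_adjust(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_distributions_stay_non_significant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(50, 5, 16)
        intervals = {f"bin{i:02d}": base + rng.normal(0, 0.5, 16)
                     for i in range(1, 17)}
        results = sb.pairwise_wilcoxon_holm(base, intervals, metric="residence")
        assert len(results) == 16
        sig = [r for r in results if r.p_adjusted is not None
               and r.p_adjusted < 0.05]
        assert not sig

    def test_few_informative_pairs_reported_na(self):
        base = np.full(16, 50.0)
        vals = base.copy()
        vals[:3] += 1.0
        with pytest.warns(UserWarning, match="informative"):
            res = sb.pairwise_wilcoxon_holm(base, {"bin01": vals})
        assert np.isnan(res[0].p)

    def test_familywise_error_controlled_under_global_null(self):
        rng = np.random.default_rng(3)
        reps, family, n = 2000, 4, 12
        false_rejects = 0
        for _ in range(reps):
            raw = [sst.wilcoxon(rng.normal(0, 1, n)).pvalue for _ in range(family)]
            false_rejects += (sb.holm_adjust(raw) < 0.05).any()
        assert false_rejects / reps <= 0.055


class TestEODModel:
    @staticmethod
    def rows(rng, time_slope=-0.005, interaction=0.0, re_sd=0.001,
             resid_sd=0.01, n_fish=16, n_bins=16):
        spec = sb.EODModelSpec()
        slopes = rng.normal(time_slope, re_sd, n_fish)
        out = []
        for i in range(n_fish):
            for t in range(1, n_bins + 1):
                do = max(100.0 - 6.0 * t, 10.0)
                resid_frac = 0.9 if do > 22 else 0.3
                inter = spec.inverted(np.array([do]))[0] * resid_frac
                out.append({
                    "fish_id": f"f{i:02d}", "time": float(t), "do": do,
                    "residence_frac": resid_frac,
                    "pct_change": slopes[i] * t + interaction * inter
                    + rng.normal(0, resid_sd)})
        return pd.DataFrame(out)

    def test_zero_response_gives_zero_estimates(self):
        df = self.rows(np.random.default_rng(0), time_slope=0.0, re_sd=0.0,
                       resid_sd=1e-9)
        fit = sb.fit_eod_lmm(df, compute_df=False)
        for term in fit.terms:
            assert abs(term.estimate) < 1e-6

    def test_interaction_grows_as_do_falls(self):
        spec = sb.EODModelSpec()
        vals = spec.inverted(np.array([80.0, 40.0, 10.0]))
        assert np.all(np.diff(vals) > 0)

    def test_monte_carlo_sign_recovery(self):
        hits = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(seed)
            fit = sb.fit_eod_lmm(self.rows(rng))
            time = fit.term("time")
            inter = fit.term("inverted_do:residence")
            hits += (time.estimate < 0 and time.p < 0.05 and inter.p >= 0.05)
        assert hits / n >= 0.90

    def test_aic_comparison_prefers_true_model(self):
        df = self.rows(np.random.default_rng(5))
        table = sb.compare_eod_models(df)
        assert table.iloc[0]["terms"] in ("time", "time+interaction")

    def test_rank_deficient_design_names_terms(self):
        df = self.rows(np.random.default_rng(0))
        df["residence_frac"] = 0.0  # interaction column collapses to zero
        with pytest.raises(InsufficientDataError, match="collinear"):
            sb.fit_eod_lmm(df)


class TestRepeatabilityANOVA:
    @staticmethod
    def rows(rng, day_shift=0.0, n_fish=5):
        out = []
        for i in range(n_fish):
            for do in (100, 70, 50, 30, 25, 20, 15, 10):
                mu = 90.0 if do > 20 else 30.0
                cell = rng.normal(0, 8)
                for day, shift in ((1, 0.0), (2, day_shift)):
                    out.append({"fish_id": f"f{i}", "do": do, "day": day,
                                "residence": np.clip(mu + cell + shift
                                                     + rng.normal(0, 4), 0, 100)})
        return pd.DataFrame(out)

    def test_identical_days_give_null_result(self):
        df = self.rows(np.random.default_rng(0))
        d1 = df[df.day == 1]
        d2 = d1.copy()
        d2["day"] = 2
        res = sb.rm_anova_repeatability(pd.concat([d1, d2], ignore_index=True))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_permutation_null_approximates_p(self):
        # shuffling day labels within each (fish, DO) cell builds a null F
        # distribution whose exceedance of the observed F approximates p
        rng = np.random.default_rng(1)
        df = self.rows(rng)
        obs = sb.rm_anova_repeatability(df)
        wide = df.pivot_table(index=["fish_id", "do"], columns="day",
                              values="residence").reset_index(drop=True)
        exceed = 0
        reps = 200
        for _ in range(reps):
            flip = rng.random(len(wide)) < 0.5
            perm = wide.copy()
            perm.loc[flip, [1, 2]] = perm.loc[flip, [2, 1]].to_numpy()
            f = sb.rm_anova_repeatability(_relabel(perm, df))
            exceed += f.statistic >= obs.statistic
        assert abs(exceed / reps - obs.p) < 0.2

    def test_unbalanced_design_rejected(self):
        df = self.rows(np.random.default_rng(2)).iloc[:-1]
        with pytest.raises(InsufficientDataError):
            sb.rm_anova_repeatability(df)


def _relabel(wide, template):
    """Rebuild a long balanced frame from a permuted wide table."""
    cells = template[["fish_id", "do"]].drop_duplicates().reset_index(drop=True)
    rows = []
    for i, (_, cell) in enumerate(cells.iterrows()):
        for day in (1, 2):
            rows.append({"fish_id": cell.fish_id, "do": cell.do, "day": day,
                         "residence": wide.iloc[i][day]})
    return pd.DataFrame(rows)
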