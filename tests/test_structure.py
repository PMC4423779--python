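"""RAD construction and fitting, MARS, and the signed-rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trailcam import structure as sx


class TestBuildRad:
    def test_sorts_nonincreasing(self):
        rad = sx.build_rad(pd.Series({"a": 5.0, "b": 1.0, "c": 3.0}))
        assert list(rad.abundances) == [5.0, 3.0, 1.0]
        assert rad.species_ids == ["a", "c", "b"]
        assert list(rad.ranks) == [1, 2, 3]

    def test_singleton(self):
        rad = sx.build_rad(pd.Series({"x": 2.5}))
        assert rad.n == 1 and rad.total == 2.5

    def test_zero_abundance_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-abundance"):
            rad = sx.build_rad(pd.Series({"a": 2.0, "b": 0.0}))
        assert rad.n == 1

    def test_missing_subset_species_raises(self):
        with pytest.raises(ValueError, match="absent"):
            sx.build_rad(pd.Series({"a": 1.0}), species_subset=["a", "zz"])


class TestStructureSubset:
    def test_common_rule_recovers_30_species_community(self, ruaha_long):
        subset = sx.select_structure_species(ruaha_long)
        assert len(subset) == 30
        # species failing the both-placements-every-season detection rule
        for sp in ("african_wild_dog", "ground_pangolin", "klipspringer",
                   "african_buffalo", "caracal", "cheetah"):
            assert sp not in subset
        # detected everywhere but under five events in one season
        assert "grants_gazelle" not in subset    # 2 dry events
        assert "bushbuck" not in subset          # 2 wet events
        for sp in ("impala", "african_elephant", "spotted_hyena", "eland"):
            assert sp in subset

    def test_season_rule(self, ruaha_long):
        dry = sx.select_structure_species(ruaha_long, "dry",
                                          detected_rule="season")
        assert len(dry) == 35
        assert "caracal" not in dry              # 4 events overall

    def test_overall_rule(self, ruaha_long):
        subset = sx.select_structure_species(ruaha_long,
                                             detected_rule="overall")
        assert len(subset) == 37


class TestFitRad:
    def test_broken_stick_exact_data_zero_deviance(self):
        S, J = 6, 30.0
        pred = sx.broken_stick(np.arange(1, S + 1), J, S)
        rad = sx.RAD([f"s{i}" for i in range(S)], pred)
        for scale in ("log", "identity"):
            fit = sx.fit_rad(rad, "null", scale=scale)
            assert fit.deviance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scale", ["log", "identity"])
    def test_preemption_self_consistency(self, scale):
        S, J, alpha = 5, 100.0, 0.5
        obs = sx.preemption_abund(np.arange(1, S + 1), J, S, alpha)
        rad = sx.RAD([f"s{i}" for i in range(S)], obs)
        fit = sx.fit_rad(rad, "preemption", scale=scale)
        assert fit.params["alpha"] == pytest.approx(alpha, abs=1e-4)
        assert fit.deviance < 1e-8

    def test_lognormal_self_consistency(self):
        S = 8
        obs = sx.lognormal_abund(np.arange(1, S + 1), S, mu=1.0, sigma=0.8)
        rad = sx.RAD([f"s{i}" for i in range(S)], obs)
        fit = sx.fit_rad(rad, "lognormal")
        assert fit.params["mu"] == pytest.approx(1.0, abs=1e-4)
        assert fit.params["sigma"] == pytest.approx(0.8, abs=1e-4)
        assert fit.deviance < 1e-8

    def test_zipf_mandelbrot_nests_zipf(self):
        rng = np.random.default_rng(0)
        obs = np.sort(np.exp(rng.normal(1, 1, 12)))[::-1]
        rad = sx.RAD([f"s{i}" for i in range(12)], obs)
        fz = sx.fit_rad(rad, "zipf")
        fzm = sx.fit_rad(rad, "zipf_mandelbrot")
        assert fzm.deviance <= fz.deviance + 1e-6

    def test_predictions_nonincreasing(self):
        rng = np.random.default_rng(1)
        obs = np.sort(np.exp(rng.normal(0, 1.5, 15)))[::-1]
        rad = sx.RAD([f"s{i}" for i in range(15)], obs)
        for fit in sx.fit_all_rad(rad):
            assert fit.success
            assert np.all(np.diff(fit.predicted) <= 1e-9)

    def test_null_and_preemption_sum_to_total(self):
        rng = np.random.default_rng(2)
        obs = np.sort(np.exp(rng.normal(0, 1, 10)))[::-1]
        rad = sx.RAD([f"s{i}" for i in range(10)], obs)
        null = sx.fit_rad(rad, "null")
        assert null.predicted.sum() == pytest.approx(rad.total)
        pre = sx.fit_rad(rad, "preemption", scale="identity")
        assert pre.predicted.sum() == pytest.approx(rad.total, rel=1e-6)

    def test_too_few_species_raises(self):
        rad = sx.RAD(["a", "b"], np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            sx.fit_rad(rad, "zipf_mandelbrot")


class TestSelectRadModel:
    def test_published_deviance_row_selects_lognormal(self):
        fits = [sx.RADFit(m, {}, np.ones(3), d) for m, d in
                zip(sx.RAD_MODELS, (23.8, 4.9, 1.1, 8.0, 4.6))]
        assert sx.select_rad_model(fits).model == "lognormal"

    def test_tie_prefers_fewer_parameters(self):
        fits = [sx.RADFit("lognormal", {}, np.ones(3), 2.0),
                sx.RADFit("preemption", {}, np.ones(3), 2.0)]
        assert sx.select_rad_model(fits).model == "preemption"

    def test_single_fit_and_all_failed(self):
        only = sx.RADFit("zipf", {}, np.ones(3), 5.0)
        assert sx.select_rad_model([only]) is only
        with pytest.raises(ValueError):
            sx.select_rad_model([sx.RADFit("zipf", {}, np.ones(3),
                                           np.inf, success=False)])

    def test_selected_deviance_is_minimal_on_real_data(self, ruaha_long):
        subset = sx.select_structure_species(ruaha_long)
        g = ruaha_long[(ruaha_long.placement == "trail")
                       & (ruaha_long.season == "dry")
                       & ruaha_long.species_id.isin(subset)]
        fits = sx.fit_all_rad(sx.build_rad(g[["species_id", "rai"]]))
        best = sx.select_rad_model(fits)
        assert all(best.deviance <= f.deviance for f in fits if f.success)


class TestMars:
    def test_identical_rankings_zero(self):
        r = pd.Series({"a": 1, "b": 2, "c": 3})
        res = sx.mars(r, r)
        assert res.mars == 0.0 and res.v == 0.0 and res.p_value == 1.0

    def test_single_swap(self):
        a = pd.Series({"x": 1, "y": 2, "z": 3})
        b = pd.Series({"x": 2, "y": 1, "z": 3})
        assert sx.mars(a, b).mars == pytest.approx(2 / 3)

    def test_full_reversal_n4(self):
        a = pd.Series({"p": 1, "q": 2, "r": 3, "s": 4})
        b = pd.Series({"p": 4, "q": 3, "r": 2, "s": 1})
        assert sx.mars(a, b).mars == pytest.approx(2.0)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        sp = [f"s{i}" for i in range(12)]
        a = pd.Series(rng.permutation(12) + 1.0, index=sp)
        b = pd.Series(rng.permutation(12) + 1.0, index=sp)
        m1 = sx.mars(a, b).mars
        assert m1 == sx.mars(b, a).mars
        perm = rng.permutation(sp)
        assert sx.mars(a.loc[perm], b).mars == m1

    def test_mismatched_species_sets(self):
        with pytest.raises(ValueError):
            sx.mars(pd.Series({"a": 1}), pd.Series({"b": 1}))

    def test_v_is_full_rank_sum_of_nonzero_shifts(self):
        # the absolute shifts are nonnegative, so every nonzero shift is
        # positive and V = m(m+1)/2 for m nonzero shifts
        a = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        b = pd.Series({"a": 2, "b": 1, "c": 3, "d": 4})
        res = sx.mars(a, b)
        m = int((res.abs_shifts > 0).sum())
        assert res.v == m * (m + 1) / 2


class TestSignedRankTest:
    def test_all_positive_small_sample(self):
        v, p = sx.signed_rank_test([1.0, 2.0, 3.0])
        assert v == 6.0
        assert p == pytest.approx(0.25)   # 2 * P(W+ >= 6) = 2/8

    def test_symmetric_pair(self):
        _, p = sx.signed_rank_test([-1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        v, p = sx.signed_rank_test([0.0, 0.0, 0.0])
        assert v == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, size=rng.integers(6, 15))
        x = x[x != 0]
        v, p = sx.signed_rank_test(x)
        ref = stats.wilcoxon(x, method="exact")
        assert v == ref.statistic or v == len(x) * (len(x) + 1) / 2 - ref.statistic
        # scipy reports min(V+, V-); two-sided p must agree exactly
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_handles_ties(self):
        # scipy's exact mode cannot rank ties; the convolution here can
        x = np.array([1.0, 1.0, -1.0, 2.0, 2.0])
        v, p = sx.signed_rank_test(x)
        # enumerate all 32 sign patterns directly
        ranks = stats.rankdata(np.abs(x))
        dist = [sum(r for r, s in zip(ranks, signs) if s > 0)
                for signs in itertools.product([1, -1], repeat=5)]
        dist = np.array(dist)
        p_ref = min(1.0, 2 * min((dist <= v).mean(), (dist >= v).mean()))
        assert p == pytest.approx(p_ref)

    def test_approximation_close_to_exact_at_n20(self):
        d = np.array([-0.891, -0.273, -1.817, -1.663, 0.878, -1.234, 1.024,
                      0.325, -0.346, -1.304, -1.128, -0.648, -1.838, -0.556,
                      -1.45, -0.288, -0.523, 0.588, -0.892, -0.956])
        v, p = sx.signed_rank_test(d)           # n=20 -> normal approximation
        assert v == 32.0                        # matches the exact-rank V
        assert p == pytest.approx(0.004859924316, abs=0.01)

    def test_null_distribution_support(self):
        support, pmf = sx.signed_rank_null_distribution(4)
        assert support[0] == 0 and support[-1] == 10
        assert pmf.sum() == pytest.approx(1.0)
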