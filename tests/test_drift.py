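import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import silhouette_score

from a3ge.drift import (
    DegenerateWeightsError,
    DriftConfig,
    DriftModel,
    InsufficientDataError,
    a3ge_score,
    category_analysis,
    compare_groups,
    drift_by_tier,
    fit_young_old_regression,
    group_means,
    paired_t_one_sample,
    pca_overview,
    select_leg_heg,
    size_factors,
    summarize_dispersion,
    welch_t_two_sample,
    wrmsd,
)


def _meta(groups_reps):
    rows = []
    for g, n in groups_reps.items():
        for r in range(1, n + 1):
            rows.append({"sample_id": f"{g}_r{r}", "tissue": "tcell",
                         "genotype": "wt", "age_months": 2.0,
                         "group": g, "replicate": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression and A3GE


class TestRegression:
    def test_identity(self):
        ref = pd.Series(np.exp2(np.linspace(-2, 4, 30)))
        m, b, r2, n = fit_young_old_regression(ref, ref)
        assert m == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert n == 30

    def test_constructed_line(self):
        ref = pd.Series(np.exp2(np.linspace(-3, 5, 40)))
        cmp = np.exp2(0.5 * np.log2(ref) + 1.0)
        m, b, r2, _ = fit_young_old_regression(ref, cmp)
        assert m == pytest.approx(0.5, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_missing_values_excluded_pairwise(self):
        ref = pd.Series([1.0, 2.0, 4.0, np.nan, 8.0])
        cmp = pd.Series([1.0, 2.0, 4.0, 16.0, np.nan])
        _, _, _, n = fit_young_old_regression(ref, cmp)
        assert n == 3

    def test_too_few_features_rejected(self):
        ref = pd.Series([1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_young_old_regression(ref, ref)


class TestA3ge:
    def test_reference_values(self):
        assert a3ge_score(1.0) == 0.0
        assert a3ge_score(0.7071) == pytest.approx(0.50, abs=1e-4)
        assert a3ge_score(0.0) == 1.0
        assert a3ge_score(0.0, "one_minus_m_quantity_squared") == 1.0
        assert a3ge_score(1.0, "one_minus_m_quantity_squared") == 0.0

    @pytest.mark.parametrize("variant", ["one_minus_m_squared",
                                         "one_minus_m_quantity_squared"])
    def test_strictly_decreasing_on_unit_interval(self, variant):
        grid = np.linspace(0, 1, 101)
        vals = [a3ge_score(m, variant) for m in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_clipping_outside_unit_slope(self):
        assert a3ge_score(1.2) == 0.0  # 1 - m^2 < 0 clips to 0
        assert a3ge_score(-2.0, "one_minus_m_quantity_squared") == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            a3ge_score(0.5, "nope")
        with pytest.raises(ValueError):
            a3ge_score(float("nan"))


# ---------------------------------------------------------------------------
# wRMSD


def _reps_with(mean, sd):
    """Two replicates realizing an exact mean and ddof=1 standard deviation."""
    d = sd / math.sqrt(2.0)
    return [mean - d, mean + d]


def brute_force_wrmsd(ref_reps: np.ndarray, cmp: np.ndarray) -> float:
    cvs, means = [], []
    for row in ref_reps:
        means.append(row.mean())
        cvs.append(row.std(ddof=1) / row.mean())
    total = sum(cvs)
    acc = 0.0
    for cv, mean, value in zip(cvs, means, cmp):
        acc += (cv / total) * (mean - value) ** 2
    return math.sqrt(acc)


class TestWrmsd:
    def test_zero_for_self(self):
        reps = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.2, 2.4, 2.8]})
        assert wrmsd(reps, reps.mean(axis=1)) == pytest.approx(0.0, abs=1e-15)

    def test_equal_cvs_collapse_to_plain_rmsd(self):
        reps = pd.DataFrame(
            [_reps_with(1.0, 0.2), _reps_with(2.0, 0.4), _reps_with(4.0, 0.8)],
            columns=["r1", "r2"],
        )
        cmp = pd.Series([1.5, 2.5, 3.5])
        expected = math.sqrt(np.mean((reps.mean(axis=1) - cmp) ** 2))
        assert wrmsd(reps, cmp) == pytest.approx(expected, abs=1e-12)

    def test_hand_worked_example(self):
        # means (1, 2), CVs (0.1, 0.3), cmp (1.1, 1.8)
        # -> w = (0.25, 0.75), wRMSD = sqrt(0.25*0.01 + 0.75*0.04)
        reps = pd.DataFrame(
            [_reps_with(1.0, 0.1), _reps_with(2.0, 0.6)], columns=["r1", "r2"]
        )
        cmp = pd.Series([1.1, 1.8])
        assert wrmsd(reps, cmp) == pytest.approx(
            math.sqrt(0.25 * 0.01 + 0.75 * 0.04), abs=1e-12
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            k = int(rng.integers(2, 6))
            reps = rng.lognormal(0.5, 0.5, size=(n, k))
            cmp = rng.lognormal(0.5, 0.5, size=n)
            got = wrmsd(
                pd.DataFrame(reps), pd.Series(cmp),
                DriftConfig(wrmsd_scale="level"),
            )
            assert got == pytest.approx(brute_force_wrmsd(reps, cmp),
                                        abs=1e-12)

    def test_permutation_invariance(self, rng):
        reps = pd.DataFrame(rng.lognormal(0, 0.4, size=(8, 3)))
        cmp = pd.Series(rng.lognormal(0, 0.4, size=8))
        perm = rng.permutation(8)
        assert wrmsd(reps, cmp) == pytest.approx(
            wrmsd(reps.iloc[perm], cmp.iloc[perm]), abs=1e-14
        )

    def test_degenerate_weights(self):
        reps = pd.DataFrame({"r1": [1.0, 2.0], "r2": [1.0, 2.0]})
        cmp = pd.Series([1.5, 2.5])
        with pytest.raises(DegenerateWeightsError):
            wrmsd(reps, cmp)
        fallback = wrmsd(reps, cmp, DriftConfig(equal_weight_fallback=True))
        assert fallback == pytest.approx(math.sqrt(0.25), abs=1e-12)


# ---------------------------------------------------------------------------
# estimator and contrasts


class TestDriftModel:
    def test_sklearn_protocol(self):
        model = DriftModel(a3ge_variant="one_minus_m_quantity_squared")
        params = model.get_params()
        assert params["a3ge_variant"] == "one_minus_m_quantity_squared"
        cloned = clone(model)
        assert cloned.get_params() == params

    def test_fit_sets_attributes(self, tcell_latent):
        values, meta = tcell_latent.values, tcell_latent.meta
        _, ref = group_means(values, meta, "wy")
        _, cmp = group_means(values, meta, "wo")
        model = DriftModel().fit(ref, cmp)
        assert 0.6 < model.slope_m_ < 0.8
        assert model.a3ge_ == a3ge_score(model.slope_m_)
        assert model.n_features_used_ == len(values)
        assert model.wrmsd_ > 0


class TestCompareGroups:
    def test_self_comparison_is_null(self, tcell_latent):
        rec = compare_groups(
            tcell_latent.values, tcell_latent.meta, "wy", "wy"
        )
        assert rec.slope_m == pytest.approx(1.0, abs=1e-12)
        assert rec.wrmsd == pytest.approx(0.0, abs=1e-12)
        assert rec.a3ge == pytest.approx(0.0, abs=1e-12)

    def test_stronger_compression_gives_larger_drift(self, tcell_latent):
        values, meta = tcell_latent.values, tcell_latent.meta
        wo = compare_groups(values, meta, "wy", "wo")
        ho = compare_groups(values, meta, "wy", "ho")
        assert ho.a3ge > wo.a3ge
        assert ho.wrmsd > wo.wrmsd
        assert ho.r_squared < 1.0

    def test_missing_feature_bookkeeping(self, tcell_latent):
        values = tcell_latent.values.copy()
        before = compare_groups(values, tcell_latent.meta, "wy", "wo")
        values.loc[values.index[0], "wo_r1":"wo_r4"] = np.nan
        after = compare_groups(values, tcell_latent.meta, "wy", "wo")
        assert before.n_features_used - after.n_features_used == 1


class TestCategoryAnalysis:
    @staticmethod
    def _two_category_data(rng):
        n = 40
        base = rng.normal(1.0, 2.0, size=2 * n)
        ids = [f"acet{i:03d}" for i in range(n)] + [
            f"prg{i:03d}" for i in range(n)
        ]
        m = np.r_[np.full(n, 0.95), np.full(n, 0.4)]
        old = 1.0 + m * (base - 1.0)
        values = pd.DataFrame(
            {
                "wy_r1": np.exp2(base), "wy_r2": np.exp2(base + 0.01),
                "old_r1": np.exp2(old), "old_r2": np.exp2(old - 0.01),
            },
            index=ids,
        )
        cats = pd.Series(
            ["acetylation"] * n + ["prg"] * n, index=ids
        )
        return values, _meta({"wy": 2, "old": 2}), cats

    def test_partition_identity(self, tcell_latent, default_panel):
        values, meta = tcell_latent.values, tcell_latent.meta
        one_cat = pd.Series("all", index=values.index)
        recs, skipped = category_analysis(values, meta, "wy", "wo", one_cat)
        assert not skipped
        global_rec = compare_groups(values, meta, "wy", "wo")
        assert recs[0].slope_m == pytest.approx(global_rec.slope_m, abs=1e-12)
        assert recs[0].wrmsd == pytest.approx(global_rec.wrmsd, abs=1e-12)

    def test_category_specific_drift_ordering(self, rng):
        values, meta, cats = self._two_category_data(rng)
        recs, _ = category_analysis(values, meta, "wy", "old", cats)
        by_cat = {r.comparison_label.split("|")[1]: r for r in recs}
        assert by_cat["prg"].a3ge > by_cat["acetylation"].a3ge

    def test_small_category_skipped(self, rng):
        values, meta, cats = self._two_category_data(rng)
        cats.iloc[:2] = "tiny"
        cats.iloc[2:] = "rest"
        recs, skipped = category_analysis(values, meta, "wy", "old", cats,
                                          min_category_features=5)
        assert "tiny" in skipped and "2 features" in skipped["tiny"]
        assert len(recs) == 1


class TestDispersion:
    def test_reference_ratios_are_one(self, tcell_latent):
        disp = summarize_dispersion(
            tcell_latent.values, tcell_latent.meta, ["wy", "wo"], "wy"
        )
        assert disp.at["wy", "median_ratio"] == 1.0
        assert disp.at["wy", "variance_ratio"] == 1.0

    def test_variance_convergence_follows_m_squared(self, tcell_latent):
        disp = summarize_dispersion(
            tcell_latent.values, tcell_latent.meta, ["wy", "wo", "ho"], "wy"
        )
        assert disp.at["wo", "variance_ratio"] == pytest.approx(0.50, abs=0.05)
        assert disp.at["ho", "variance_ratio"] == pytest.approx(0.25, abs=0.05)

    def test_constant_matrix_zero_variance(self):
        values = pd.DataFrame(
            {"g_r1": [2.0] * 5, "g_r2": [2.0] * 5},
            index=[f"f{i}" for i in range(5)],
        )
        disp = summarize_dispersion(values, _meta({"g": 2}), ["g"], "g")
        assert disp.at["g", "variance"] == 0.0


# ---------------------------------------------------------------------------
# LEG / HEG tiers


class TestTierSelection:
    def test_direct_sort(self):
        means = pd.Series(
            [0.1, 0.2, 0.3, 4.0, 5.0, 6.0],
            index=[f"f{i}" for i in range(6)],
        )
        leg, heg = select_leg_heg(means, tier_n=2)
        assert leg == ["f0", "f1"]
        assert heg == ["f4", "f5"]

    def test_zero_level_excluded(self):
        means = pd.Series(
            [0.0, 0.2, 0.3, 4.0, 5.0, 6.0],
            index=[f"f{i}" for i in range(6)],
        )
        leg, heg = select_leg_heg(means, tier_n=2)
        assert "f0" not in leg and "f0" not in heg
        assert leg == ["f1", "f2"]

    def test_boundary_ties_resolve_by_id(self):
        means = pd.Series(
            {"b": 1.0, "a": 1.0, "d": 1.0, "c": 5.0, "e": 6.0, "f": 7.0}
        )
        leg, _ = select_leg_heg(means, tier_n=2)
        assert leg == ["a", "b"]

    def test_insufficient_features_rejected(self):
        with pytest.raises(InsufficientDataError):
            select_leg_heg(pd.Series([1.0, 2.0, 3.0]), tier_n=2)


class TestTierDrift:
    def test_null_contrast(self):
        ref = pd.Series(
            np.exp2(np.linspace(-2, 4, 20)), index=[f"f{i:02d}" for i in range(20)]
        )
        leg, heg = select_leg_heg(ref, tier_n=5)
        leg_res, heg_res, _ = drift_by_tier(ref, ref, leg, heg)
        for res in (leg_res, heg_res):
            assert res.mean_log2_fold_change == 0.0
            assert res.p_value == pytest.approx(1.0)

    def test_textbook_t_example(self):
        # d = {0.5, 1.5, 1.0}: mean 1, sd 0.5, t = 3.4641, p = 0.0742
        d = np.array([0.5, 1.5, 1.0])
        t, p, df = paired_t_one_sample(d)
        assert t == pytest.approx(1.0 / (0.5 / math.sqrt(3)), abs=1e-10)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=5e-5)

    def test_degenerate_zero_sd(self):
        t, p, df = paired_t_one_sample(np.ones(4))
        assert math.isinf(t) and p == 0.0 and df == 3

    def test_t_statistics_match_scipy_oracle(self, rng):
        for _ in range(100):
            d = rng.normal(0.2, 1.0, size=int(rng.integers(3, 30)))
            t, p, _ = paired_t_one_sample(d)
            ref = stats.ttest_1samp(d, 0.0)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)
            a = rng.normal(0, 1, size=int(rng.integers(3, 30)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 30)))
            t2, p2, _ = welch_t_two_sample(a, b)
            ref2 = stats.ttest_ind(a, b, equal_var=False)
            assert t2 == pytest.approx(ref2.statistic, abs=1e-12)
            assert p2 == pytest.approx(ref2.pvalue, abs=1e-12)

    def test_opposite_drift_of_tiers(self, tcell_latent):
        values, meta = tcell_latent.values, tcell_latent.meta
        ref, _ = group_means(values, meta, "wy")
        cmp, _ = group_means(values, meta, "ho")
        leg, heg = select_leg_heg(ref, tier_n=50)
        leg_res, heg_res, between_p = drift_by_tier(ref, cmp, leg, heg)
        assert leg_res.mean_log2_fold_change > 0
        assert heg_res.mean_log2_fold_change < 0
        assert between_p < 1e-10

    def test_nonpositive_feature_named(self):
        ref = pd.Series({"good": 1.0, "bad": 0.0, "ok": 2.0, "ok2": 3.0})
        with pytest.raises(ValueError, match="bad"):
            drift_by_tier(ref, ref, ["good", "bad"], ["ok", "ok2"])

    def test_overlapping_tiers_rejected(self):
        ref = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="disjoint"):
            drift_by_tier(ref, ref, ["a"], ["a", "b"])


# ---------------------------------------------------------------------------
# PCA overview


class TestPca:
    def test_identical_samples_coincide(self, rng):
        col = rng.integers(1, 1000, size=50).astype(float)
        matrix = pd.DataFrame(
            {"s1": col, "s2": col, "s3": col * 2},  # s3 differs only by depth
            index=[f"f{i}" for i in range(50)],
        )
        coords, _ = pca_overview(matrix, top_k_variable=50)
        np.testing.assert_allclose(
            coords.loc["s1"], coords.loc["s2"], atol=1e-9
        )
        # depth-only difference is removed by size-factor normalization
        np.testing.assert_allclose(
            coords.loc["s1"], coords.loc["s3"], atol=1e-9
        )

    def test_explained_variance_properties(self, rng):
        matrix = pd.DataFrame(
            rng.integers(0, 500, size=(60, 8)).astype(float),
            columns=[f"s{i}" for i in range(8)],
        )
        _, explained = pca_overview(matrix, top_k_variable=40, n_components=4)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1.0 + 1e-12

    def test_groups_separate_on_pc1(self, default_panel):
        from a3ge.simulate import (
            DriftParams, GroupSpec, SeqParams, simulate_counts,
            simulate_expression,
        )

        groups = [
            GroupSpec("wy", "tcell", "wt", 2.0, 4, 1.0, 0.0),
            GroupSpec("ho", "tcell", "hd", 19.0, 4, 0.5),
        ]
        latent = simulate_expression(default_panel, groups, DriftParams(),
                                     seed=21)
        counts, _ = simulate_counts(latent, SeqParams(seed=22))
        matrix = counts.pivot(index="amplicon_id", columns="sample_id",
                              values="mouse_reads")
        coords, _ = pca_overview(matrix, top_k_variable=200)
        labels = [s.split("_")[0] for s in coords.index]
        score = silhouette_score(coords[["PC1"]].to_numpy(), labels)
        assert score > 0

    def test_size_factors_track_depth(self, rng):
        col = rng.integers(10, 1000, size=40).astype(float)
        matrix = pd.DataFrame({"a": col, "b": 2.0 * col})
        sf = size_factors(matrix)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)
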