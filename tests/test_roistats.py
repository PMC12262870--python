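"""ROI summaries, outlier handling, ANOVA/GG, BH-FDR, LMM, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinconn.roistats import (brain_behavior_partial_corr, fdr_correct,
                              fit_group_lmm, mixed_anova, replace_outliers,
                              select_top_voxels, summarize_maps)


def bh_bruteforce(p):
    """Definitional BH: adjusted p_(i) = min(1, min_{j>=i} p_(j) * n / j)."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    for rank_i in range(n):
        tail = [p[order[j]] * n / (j + 1) for j in range(rank_i, n)]
        adj_sorted[rank_i] = min(1.0, min(tail))
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


class TestTopVoxels:
    def test_enumerated_example(self):
        values = np.arange(1.0, 11.0)
        sel, mean = select_top_voxels(values, 0.4, values)
        assert sel.tolist() == [6, 7, 8, 9]
        assert mean == 8.5

    def test_ties_select_ceil_fraction_voxels(self):
        values = np.full(10, 3.25)
        sel, mean = select_top_voxels(values, 0.4, values)
        assert sel.size == 4
        assert mean == 3.25

    @given(st.integers(min_value=1, max_value=200),
           st.floats(min_value=0.01, max_value=1.0),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_full_sort_oracle(self, n, fraction, seed):
        rng = np.random.default_rng(seed)
        ranking = rng.normal(size=n)
        values = rng.normal(size=n)
        sel, mean = select_top_voxels(values, fraction, ranking)
        k = int(np.ceil(fraction * n))
        # oracle: full sort on (-ranking, index)
        oracle = sorted(range(n), key=lambda i: (-ranking[i], i))[:k]
        assert sorted(oracle) == sel.tolist()
        assert mean == pytest.approx(values[sorted(oracle)].mean())

    def test_permutation_invariant_selection(self, rng):
        n = 60
        ranking = rng.normal(size=n)
        values = rng.normal(size=n)
        sel, mean = select_top_voxels(values, 0.3, ranking)
        perm = rng.permutation(n)
        sel_p, mean_p = select_top_voxels(values[perm], 0.3, ranking[perm])
        assert mean_p == pytest.approx(mean)
        assert sorted(perm[sel_p]) == sel.tolist()

    def test_cross_condition_ranking_shares_voxel_set(self, rng):
        vals = {"a": rng.normal(size=50), "b": rng.normal(size=50)}
        ranking = (vals["a"] + vals["b"]) / 2
        out = summarize_maps(vals, fraction=0.2)
        sel, _ = select_top_voxels(vals["a"], 0.2, ranking)
        assert out["a"] == pytest.approx(vals["a"][sel].mean())
        assert out["b"] == pytest.approx(vals["b"][sel].mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_top_voxels(np.array([]), 0.4, np.array([]))


class TestOutliers:
    def test_hand_computed_example(self):
        # mean 1.9, sample SD 2.846, median 1: only the 10 exceeds 2 SD
        v = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 10], float)
        cleaned, flags = replace_outliers(v, np.zeros(10))
        assert flags.tolist() == [False] * 9 + [True]
        assert cleaned[-1] == 1.0
        assert np.array_equal(cleaned[:9], v[:9])

    def test_no_outliers_identity(self, rng):
        v = rng.normal(size=20)
        v = np.clip(v, -1.5, 1.5)   # nothing beyond 2 SD of this sample
        cleaned, flags = replace_outliers(v, np.zeros(20))
        if not flags.any():
            assert np.array_equal(cleaned, v)

    def test_constant_group_unchanged(self):
        v = np.full(8, 4.2)
        cleaned, flags = replace_outliers(v, np.zeros(8))
        assert not flags.any()
        assert np.array_equal(cleaned, v)

    def test_only_flagged_entries_change_and_median_is_original(self, rng):
        v = rng.normal(size=30)
        v[3] += 15.0
        groups = np.repeat(["a", "b"], 15)
        cleaned, flags = replace_outliers(v, groups)
        assert np.array_equal(cleaned[~flags], v[~flags])
        for g in ("a", "b"):
            gi = groups == g
            if flags[gi].any():
                assert np.all(cleaned[gi & flags] == np.median(v[gi]))


def _balanced_table(rng, n_per=12, k=3, group_effect=0.0):
    rows = []
    for gi, g in enumerate(("OM", "ONM", "YNM")):
        for s in range(n_per):
            subj_mean = rng.normal(gi * group_effect, 0.4)
            for c in range(k):
                rows.append({"subject_id": f"{g}{s}", "group": g,
                             "condition": f"c{c}",
                             "value": subj_mean + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_level_within_factor_has_unit_epsilon(self, rng):
        df = _balanced_table(rng, k=2)
        res = mixed_anova(df, dv="value", within="condition",
                          subject="subject_id", between="group")
        assert res.gg_epsilon == 1.0
        assert res.sphericity_ok

    def test_group_f_equals_oneway_anova_on_subject_means(self, rng):
        # closed-form oracle: with balanced data, the between-subject F of
        # the mixed ANOVA equals the one-way ANOVA F on subject means
        df = _balanced_table(rng, group_effect=0.5)
        res = mixed_anova(df, dv="value", within="condition",
                          subject="subject_id", between="group")
        means = df.groupby(["subject_id", "group"], as_index=False)["value"].mean()
        from scipy.stats import f_oneway
        f_oracle = f_oneway(*[means.loc[means["group"] == g, "value"]
                              for g in ("OM", "ONM", "YNM")]).statistic
        assert res.effect("group")["F"] == pytest.approx(f_oracle, rel=1e-8)

    def test_missing_cells_rejected_with_subject_names(self, rng):
        df = _balanced_table(rng)
        df = df[~((df["subject_id"] == "OM0") & (df["condition"] == "c2"))]
        with pytest.raises(ValueError, match="OM0"):
            mixed_anova(df, dv="value", within="condition",
                        subject="subject_id", between="group")


class TestFDR:
    def test_definitional_example(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_pvalues_unchanged(self):
        assert fdr_correct([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.1, np.nan])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(fdr_correct(p), bh_bruteforce(p),
                                   atol=1e-12)


def _lmm_table(rng, beta=0.5, subj_sd=0.3, region_sd=0.2, resid_sd=0.3,
               n_per=20, n_regions=6):
    rows = []
    region_fx = rng.normal(0, region_sd, n_regions)
    for g, off in (("YNM", 0.0), ("ONM", beta)):
        for s in range(n_per):
            subj_fx = rng.normal(0, subj_sd)
            for r in range(n_regions):
                rows.append({"group": g, "subject_id": f"{g}{s}",
                             "roi": f"R{r}",
                             "value": off + subj_fx + region_fx[r]
                             + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestGroupLMM:
    def test_no_random_variance_reduces_to_mean_difference(self, rng):
        # OLS oracle: balanced design, zero random effects
        df = _lmm_table(rng, beta=0.7, subj_sd=0.0, region_sd=0.0,
                        resid_sd=0.05, n_per=10, n_regions=4)
        res = fit_group_lmm(df, contrast=("YNM", "ONM"))
        diff = df.loc[df.group == "ONM", "value"].mean() - \
            df.loc[df.group == "YNM", "value"].mean()
        assert res.converged
        assert res.beta_group == pytest.approx(diff, abs=1e-6)

    def test_identical_groups_give_null_contrast(self, rng):
        df = _lmm_table(rng, beta=0.0)
        res = fit_group_lmm(df, contrast=("YNM", "ONM"))
        assert abs(res.beta_group) < 3 * res.se

    def test_robust_mode_matches_plain_fit_on_clean_data(self, rng):
        df = _lmm_table(rng, beta=0.5, n_per=12, n_regions=4)
        plain = fit_group_lmm(df, contrast=("YNM", "ONM"))
        robust = fit_group_lmm(df, contrast=("YNM", "ONM"), robust=True)
        assert robust.robust
        assert robust.beta_group == pytest.approx(plain.beta_group, abs=0.1)

    def test_too_few_regions_rejected(self, rng):
        df = _lmm_table(rng, n_regions=1)
        with pytest.raises(ValueError, match="region"):
            fit_group_lmm(df, contrast=("YNM", "ONM"))


class TestPartialCorr:
    def test_identity_relationship_gives_unit_slope(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=30)
        res = brain_behavior_partial_corr(x, x, {"rsfc": cov})
        assert res.slope == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_covariate_equals_simple_regression(self, rng):
        # two-step residualization oracle
        n = 40
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n) * 0.5
        cov = rng.normal(size=n)
        cov = cov - np.polyval(np.polyfit(x, cov, 1), x)  # orthogonal to x
        res = brain_behavior_partial_corr(x, y, {"c": cov})
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        simple = float(np.linalg.lstsq(
            np.column_stack([np.ones(n), zx]), zy, rcond=None)[0][1])
        assert res.slope == pytest.approx(simple, abs=1e-10)

    def test_null_slope_centred_on_zero(self):
        rng = np.random.default_rng(7)
        slopes = []
        for _ in range(500):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            slopes.append(brain_behavior_partial_corr(x, y).slope)
        slopes = np.array(slopes)
        assert abs(slopes.mean()) < 3 * slopes.std(ddof=1) / np.sqrt(500)

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            brain_behavior_partial_corr(np.ones(10), rng.normal(size=10))
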