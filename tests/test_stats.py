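"""The agreement-statistics battery against brute-force oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ffqval as fv
from ffqval.errors import ConfigurationError, FFQValError
from ffqval.stats import icc_band


class TestCorrelate:
    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = fv.correlate(x, np.exp(x), method="spearman")
        assert res.coefficient == pytest.approx(1.0)

    def test_pearson_affine_invariance(self):
        x = np.arange(10.0)
        res = fv.correlate(x, 2 * x + 3, method="pearson")
        assert res.coefficient == pytest.approx(1.0)

    def test_spearman_hand_ranked_oracle(self):
        # ranks of y: (2,1,4,3,5); sum d^2 = 4; rho = 1 - 6*4/(5*24) = 0.8
        res = fv.correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], method="spearman")
        assert res.coefficient == pytest.approx(0.8, abs=1e-10)

    def test_pairwise_complete_drops_nan(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.5, 2.5, 3.0, np.nan, 5.5])
        res = fv.correlate(x, y, method="pearson")
        assert res.n == 3

    def test_zero_variance_reported_as_undefined(self):
        res = fv.correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(res.coefficient)
        assert "zero variance" in res.note

    def test_too_few_pairs_is_error(self):
        with pytest.raises(FFQValError, match="at least 3"):
            fv.correlate([1.0, 2.0], [2.0, 3.0])


class TestTertileCrossClassification:
    def test_identical_vectors_agree_fully(self):
        v = np.arange(12.0)
        cc = fv.tertile_cross_classify(v, v)
        assert cc.pct_same == 100.0
        assert cc.pct_gross == 0.0

    def test_reversed_ranking_is_pure_gross_for_extremes(self):
        v = np.arange(9.0)
        cc = fv.tertile_cross_classify(v, v[::-1].copy())
        assert cc.pct_gross == pytest.approx(200 / 3)
        assert cc.pct_same == pytest.approx(100 / 3)  # the middle tertile
        assert cc.pct_same_highest == 0.0
        assert cc.pct_same_lowest == 0.0

    def test_single_boundary_swap_hand_oracle(self):
        # n=9; swapping the values of ranks 3 and 4 moves exactly two
        # participants across the first boundary
        ref = np.arange(1.0, 10.0)
        test = ref.copy()
        test[2], test[3] = 4.0, 3.0
        cc = fv.tertile_cross_classify(ref, test)
        assert cc.counts.tolist() == [[2, 1, 0], [1, 2, 0], [0, 0, 3]]
        assert cc.pct_same == pytest.approx(700 / 9)
        assert cc.pct_adjacent == pytest.approx(200 / 9)
        assert cc.pct_gross == 0.0

    def test_percentages_partition_and_counts_sum(self):
        rng = np.random.default_rng(3)
        for n in (9, 10, 11, 50):
            ref, test = rng.normal(size=n), rng.normal(size=n)
            cc = fv.tertile_cross_classify(ref, test)
            assert cc.counts.sum() == n
            assert cc.pct_same + cc.pct_adjacent + cc.pct_gross == pytest.approx(100.0)

    def test_heavy_ties_warn_and_classify_deterministically(self):
        ref = np.array([0.0] * 6 + [1.0, 2.0, 3.0])  # zero-inflated food
        test = np.arange(9.0)
        with pytest.warns(UserWarning, match="tie"):
            cc1 = fv.tertile_cross_classify(ref, test)
        with pytest.warns(UserWarning, match="tie"):
            cc2 = fv.tertile_cross_classify(ref, test)
        assert cc1.counts.tolist() == cc2.counts.tolist()


class TestBlandAltman:
    def test_identical_measurements(self):
        v = np.array([3.0, 5.0, 9.0])
        ba = fv.bland_altman(v, v)
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert ba.n_above == ba.n_below == 0

    def test_constant_shift_gives_zero_width_limits(self):
        v = np.array([3.0, 5.0, 9.0, 11.0])
        ba = fv.bland_altman(v, v + 2.5)
        assert ba.mean_diff == pytest.approx(2.5)
        assert ba.limits == (pytest.approx(2.5), pytest.approx(2.5))

    def test_six_pair_hand_oracle(self):
        ref = np.array([10.0, 12.0, 11.0, 14.0, 9.0, 13.0])
        test = np.array([11.0, 12.0, 13.0, 13.0, 10.0, 15.0])
        ba = fv.bland_altman(ref, test)
        # differences (1,0,2,-1,1,2): mean 5/6, var 41/30
        assert ba.mean_diff == pytest.approx(5 / 6, abs=1e-12)
        assert ba.sd_diff == pytest.approx(np.sqrt(41 / 30), abs=1e-12)
        sd = np.sqrt(41 / 30)
        assert ba.limits[0] == pytest.approx(5 / 6 - 1.96 * sd, abs=1e-12)
        assert ba.limits[1] == pytest.approx(5 / 6 + 1.96 * sd, abs=1e-12)
        # t(0.975, 5) = 2.570581836...
        half = 2.5705818366 * sd / np.sqrt(6)
        assert ba.ci_mean[0] == pytest.approx(5 / 6 - half, abs=1e-8)
        assert ba.ci_mean[1] == pytest.approx(5 / 6 + half, abs=1e-8)

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 1, size=6400)
        small = fv.bland_altman(np.zeros(100), diffs[:100])
        large = fv.bland_altman(np.zeros(6400), diffs)
        w_small = small.ci_mean[1] - small.ci_mean[0]
        w_large = large.ci_mean[1] - large.ci_mean[0]
        assert w_large < w_small / 6  # ~1/8 expected from 64x the n

    def test_excluded_mask_is_carried_to_plot_data(self):
        ref = np.arange(5.0)
        mask = [True, False, False, False, True]
        ba = fv.bland_altman(ref, ref + 1, excluded_mask=mask)
        assert list(ba.points["excluded"]) == mask


class TestICC:
    def test_duplicated_occasions_give_one(self):
        m = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = fv.icc_agreement_average(m)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"
        assert res.ci95 == (1.0, 1.0)

    def test_four_by_two_hand_anova_oracle(self):
        """Two-way ANOVA by hand: MSR=107/24... exact mean squares frozen."""
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 6.0]])
        res = fv.icc_agreement_average(m)
        assert res.msr == pytest.approx(13.375 / 3, abs=1e-12)
        assert res.msc == pytest.approx(3.125, abs=1e-12)
        assert res.mse == pytest.approx(0.125, abs=1e-12)
        # ICC(A,2) = (MSR-MSE)/(MSR+(MSC-MSE)/n) = (13/3)/(125/24) = 104/125
        assert res.icc == pytest.approx(104 / 125, abs=1e-12)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        base = rng.normal(size=25)
        m = np.column_stack([base + rng.normal(0, 0.5, 25),
                             base + rng.normal(0, 0.5, 25)])
        mine = fv.icc_agreement_average(m)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(25), 2),
            "raters": np.tile(["a", "b"], 25),
            "scores": m.ravel(),
        })
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        ci_col = [c for c in ref.columns if c.startswith("CI95")][0]
        row = ref[ref["Type"].isin(["ICC2k", "ICC(A,k)"])].iloc[0]
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-10)
        assert mine.ci95[0] == pytest.approx(row[ci_col][0], abs=0.01)
        assert mine.ci95[1] == pytest.approx(row[ci_col][1], abs=0.01)

    def test_independent_noise_gives_near_zero(self):
        # simulation oracle: no participant signal at all -> ICC ~ 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            m = rng.normal(size=(2000, 2))
            res = fv.icc_agreement_average(m)
            assert abs(res.icc) < 0.1
            assert res.band == "poor"

    def test_icc_decreases_with_added_noise(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=400)
        iccs = []
        for sd in (0.2, 0.6, 1.2):
            m = np.column_stack([base + rng.normal(0, sd, 400),
                                 base + rng.normal(0, sd, 400)])
            iccs.append(fv.icc_agreement_average(m).icc)
        assert iccs[0] > iccs[1] > iccs[2]

    @pytest.mark.parametrize(
        "value,band",
        [(0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"),
         (0.75, "good"), (0.89, "good"), (0.9, "excellent"), (0.97, "excellent")],
    )
    def test_qualitative_bands(self, value, band):
        assert icc_band(value) == band

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [3.0, 4.0]])
        with pytest.raises(FFQValError, match="complete"):
            fv.icc_agreement_average(m)


class TestPCA:
    @staticmethod
    def _positive_frame(n=10, p=4, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 3.0, size=(n, p))
        return pd.DataFrame(x, columns=[f"g{j}" for j in range(p)])

    def test_rank_one_matrix_fully_explained_by_one_component(self):
        # construct data whose log10(x+1) columns are all proportional to one
        # vector, so the preprocessed matrix is exactly rank 1
        rng = np.random.default_rng(1)
        t = rng.uniform(0.1, 1.0, size=10)
        a = rng.uniform(0.5, 1.5, size=4)
        df = pd.DataFrame(10.0 ** np.outer(t, a) - 1.0, columns=list("wxyz"))
        res = fv.pca_patterns(df, k=1)
        assert res.r2[0] == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalue_oracle_on_toy_matrix(self):
        """Component variances must match an independent eigen-decomposition
        of the correlation matrix of the preprocessed data."""
        df = self._positive_frame(seed=2)
        res = fv.pca_patterns(df, k=3)
        x = np.log10(df.to_numpy() + 1.0)
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
        assert np.allclose(res.explained_variance, eig[:3], atol=1e-10)
        assert np.allclose(res.r2, np.cumsum(eig[:3]) / eig.sum(), atol=1e-10)

    def test_row_permutation_leaves_loadings_and_permutes_scores(self):
        df = self._positive_frame(n=12, seed=3)
        perm = np.random.default_rng(0).permutation(12)
        res = fv.pca_patterns(df, k=2)
        res_p = fv.pca_patterns(df.iloc[perm], k=2)
        assert np.allclose(res_p.loadings.to_numpy(), res.loadings.to_numpy(), atol=1e-8)
        assert np.allclose(
            res_p.scores.to_numpy(), res.scores.to_numpy()[perm], atol=1e-8
        )

    def test_q2_bounded_by_r2_and_r2_nondecreasing(self, noisy_dataset, group_mapping):
        freqs = fv.cohort_frequencies_to_daily(
            noisy_dataset.ffq_baseline, noisy_dataset.mapping, noisy_dataset.schema
        )
        fg = fv.aggregate_food_groups(freqs, group_mapping)
        res = fv.pca_patterns(fg, k=3)
        assert np.all(np.diff(res.r2) >= 0)
        assert np.all(res.q2 <= res.r2 + 1e-12)

    def test_structured_data_predicts_well(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=60)
        load = rng.uniform(0.5, 1.5, size=8)
        df = pd.DataFrame(np.exp(np.outer(t, load) * 0.3 + rng.normal(0, 0.1, (60, 8))))
        res = fv.pca_patterns(df, k=2)
        assert res.q2[0] > 0.5

    def test_zero_variance_column_dropped_with_warning(self):
        df = self._positive_frame(seed=7)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fv.pca_patterns(df, k=2)
        assert res.dropped_columns == ("flat",)

    def test_k_beyond_rank_rejected(self):
        df = self._positive_frame(n=5, p=4)
        with pytest.raises(ConfigurationError, match="rank"):
            fv.pca_patterns(df, k=4)

    def test_row_deletion_pattern_also_supported(self):
        df = self._positive_frame(n=21, p=5, seed=8)
        res = fv.pca_patterns(df, k=2, cv_pattern="rows")
        assert res.q2.shape == (2,)
        assert np.all(res.q2 <= 1.0)
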