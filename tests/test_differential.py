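import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from attnomics import differential
from attnomics.preprocess import size_factors_median_of_ratios
from attnomics.synthdata import SynthOmicsParams, generate_transcriptome

from conftest import toy_matrix


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(differential.bh_fdr([0.03]), [0.03])

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(
            differential.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one_and_nan_rejected(self):
        np.testing.assert_allclose(differential.bh_fdr([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            differential.bh_fdr([0.1, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(differential.bh_fdr(ps), expected, atol=1e-12)


class TestVip:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n, p = 20, 5 + 7 * trial
            m = toy_matrix(rng.standard_normal((n, p)),
                           groups=["RA"] * 10 + ["RA_ane"] * 10)
            vip = differential.plsda_vip(m)
            assert abs((vip ** 2).mean() - 1.0) < 1e-8

    def test_identical_copies_all_have_vip_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(16)
        vals = np.tile(x[:, None], (1, 6)) + 1e-9 * rng.standard_normal((16, 6))
        m = toy_matrix(vals, groups=["RA"] * 8 + ["RA_ane"] * 8)
        vip = differential.plsda_vip(m)
        np.testing.assert_allclose(vip, 1.0, atol=1e-3)

    def test_planted_informative_features_exceed_one(self):
        rng = np.random.default_rng(5)
        n = 30
        y = np.r_[np.zeros(n), np.ones(n)]
        vals = rng.standard_normal((2 * n, 20))
        vals[:, 0] += 2.0 * y
        vals[:, 1] -= 2.0 * y
        m = toy_matrix(vals, groups=np.where(y == 1, "RA_ane", "RA"))
        vip = differential.plsda_vip(m)
        assert vip.iloc[0] > 1.0 and vip.iloc[1] > 1.0

    def test_single_class_rejected(self):
        m = toy_matrix(np.random.default_rng(0).standard_normal((8, 4)),
                       groups=["RA"] * 8)
        with pytest.raises(ValueError):
            m.binary_labels()


class TestStudentT:
    def test_matches_scipy_pooled_ttest(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((12, 7))
        m = toy_matrix(vals, groups=["RA"] * 6 + ["RA_ane"] * 6)
        res = differential.student_ttest(m)
        t_ref, p_ref = stats.ttest_ind(vals[6:], vals[:6], equal_var=True)
        np.testing.assert_allclose(res["stat"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_hand_worked_three_vs_three(self):
        # textbook pooled t: g1 = (1,2,3), g2 = (4,5,6); diff=3, sp2=1, se=sqrt(2/3)
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        m = toy_matrix(vals, groups=["RA"] * 3 + ["RA_ane"] * 3)
        res = differential.student_ttest(m)
        expected_t = 3.0 / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(res["stat"].iloc[0], expected_t, rtol=1e-12)
        np.testing.assert_allclose(res["p"].iloc[0], 2 * stats.t.sf(expected_t, 4), rtol=1e-12)

    def test_degenerate_feature_flagged_p_one(self):
        vals = np.ones((8, 1))
        m = toy_matrix(vals, groups=["RA"] * 4 + ["RA_ane"] * 4)
        res = differential.student_ttest(m)
        assert res["p"].iloc[0] == 1.0 and res["stat"].iloc[0] == 0.0
        assert bool(res["degenerate"].iloc[0])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((40, 1000))
        m = toy_matrix(vals, groups=["RA"] * 20 + ["RA_ane"] * 20)
        res = differential.student_ttest(m)
        rate = (res["p"] < 0.05).mean()
        # 3 binomial SDs around 0.05 at n=1000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestSelectionRules:
    def test_vip_exactly_one_excluded(self):
        res = pd.DataFrame({"vip": [1.0, 1.01], "p": [0.01, 0.01]},
                           index=["a", "b"])
        assert differential.select_differential_metabolites(res) == {"b"}

    def test_toy_table(self):
        res = pd.DataFrame({
            "vip": [1.2, 0.8, 1.5, 1.1],
            "p": [0.01, 0.01, 0.2, 0.04],
        }, index=["f1", "f2", "f3", "f4"])
        assert differential.select_differential_metabolites(res) == {"f1", "f4"}

    def test_empty_result_allowed(self):
        res = pd.DataFrame({"vip": [0.5], "p": [0.9]}, index=["a"])
        assert differential.select_differential_metabolites(res) == set()


class TestFoldChangeFilter:
    def test_fc_exactly_threshold_is_significant(self):
        # group means exactly 10 and 12 -> FC = 1.2, tiny within-group spread
        g1 = [9.99, 10.01] * 5
        g2 = [11.99, 12.01] * 5
        vals = np.array(g1 + g2)[:, None]
        m = toy_matrix(vals, groups=["RA"] * 10 + ["RA_ane"] * 10)
        res = differential.fold_change_filter(m)
        assert res["fc"].iloc[0] == 1.2
        assert res["p"].iloc[0] < 0.05
        assert bool(res["significant"].iloc[0])  # inclusive >= at the boundary

    def test_large_fc_with_large_p_not_significant(self):
        vals = np.array([[1.0], [100.0], [1.0], [100.0]])
        m = toy_matrix(vals, groups=["RA", "RA", "RA_ane", "RA_ane"])
        res = differential.fold_change_filter(m)
        assert not bool(res["significant"].iloc[0])

    def test_unit_fc_everywhere_empty(self):
        rng = np.random.default_rng(9)
        noise = rng.lognormal(sigma=0.01, size=(20, 5))
        vals = np.vstack([noise, noise])
        m = toy_matrix(vals, groups=["RA"] * 20 + ["RA_ane"] * 20)
        res = differential.fold_change_filter(m)
        assert not res["significant"].any()

    def test_rejects_nonpositive_values(self):
        m = toy_matrix([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0], [1.0, 2.0]],
                       groups=["RA", "RA", "RA_ane", "RA_ane"])
        with pytest.raises(ValueError):
            differential.fold_change_filter(m)


@pytest.fixture(scope="module")
def planted_de():
    params = SynthOmicsParams(n_per_group=20, n_features=400, n_planted=12,
                              effect_log2fc=2.0, seed=12)
    return generate_transcriptome(params)


class TestNbWaldDe:

    def test_label_swap_negates_log2fc_keeps_p(self, planted_de):
        from attnomics.preprocess import preprocess_transcriptome
        m, _ = planted_de
        proc, sf, _ = preprocess_transcriptome(m)
        res = differential.nb_wald_de(proc, size_factors=sf)
        flipped = proc.group_labels.map({"RA": "RA_ane", "RA_ane": "RA"})
        res2 = differential.nb_wald_de(proc, labels=flipped, size_factors=sf)
        np.testing.assert_allclose(res2["log2_fc"], -res["log2_fc"], atol=1e-6)
        np.testing.assert_allclose(res2["p"], res["p"], atol=1e-8)

    def test_planted_genes_recovered(self, planted_de):
        from attnomics.preprocess import preprocess_transcriptome
        m, truth = planted_de
        proc, sf, _ = preprocess_transcriptome(m)
        res = differential.nb_wald_de(proc, size_factors=sf)
        sig = set(res.index[res["significant"]])
        planted = set(truth.planted_feature_ids) & set(proc.feature_ids)
        assert len(sig & planted) / len(planted) >= 0.8

    def test_identical_groups_give_zero_log2fc(self):
        vals = np.tile([10, 50, 5, 100], (8, 1))
        m = toy_matrix(vals, "transcriptome", groups=["RA"] * 4 + ["RA_ane"] * 4)
        sf = size_factors_median_of_ratios(m)
        res = differential.nb_wald_de(m, size_factors=sf)
        np.testing.assert_allclose(res["log2_fc"], 0.0, atol=1e-10)
        assert not res["significant"].any()
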