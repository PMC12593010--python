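"""Inference, effect sizes, multiplicity, discriminant and reliability."""

import numpy as np
import pandas as pd
import pytest

import emgfpca as ef
from emgfpca.exceptions import DataError, UndefinedEffectError


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _long_table(data):
    """data: {group: {subject: [trial values]}} -> long DataFrame."""
    rows = []
    for group, subjects in data.items():
        for subj, vals in subjects.items():
            for t, v in enumerate(vals, start=1):
                rows.append({"subject": subj, "group": group, "trial": t,
                             "value": v})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_groups_null_result(self):
        tab = _long_table({
            "elite": {"a": [1, 2], "b": [3, 4]},
            "sub_elite": {"c": [1, 2], "d": [3, 4]},
        })
        res = ef.rm_anova_iemg(tab)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.partial_eta_sq == pytest.approx(0.0)

    def test_toy_design_matches_hand_anova(self):
        # 2 groups x 3 subjects x 2 trials; oracle: explicit subject-level
        # one-way ANOVA on subject means, F scaled by trials
        data = {
            "elite": {"a": [4, 6], "b": [5, 7], "c": [8, 8]},
            "sub_elite": {"d": [2, 2], "e": [3, 5], "f": [1, 3]},
        }
        tab = _long_table(data)
        subj_means = np.array([5, 6, 8, 2, 4, 2], float)
        k = 2
        g1, g2 = subj_means[:3], subj_means[3:]
        grand = subj_means.mean()
        ss_group = k * (3 * (g1.mean() - grand) ** 2 + 3 * (g2.mean() - grand) ** 2)
        ss_subj = k * (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum())
        F_expected = (ss_group / 1) / (ss_subj / 4)
        res = ef.rm_anova_iemg(tab)
        assert res.F == pytest.approx(F_expected, rel=1e-12)
        assert res.df == (1, 4)

    def test_partial_eta_identity(self):
        rng = np.random.default_rng(21)
        data = {
            "elite": {f"a{i}": list(rng.normal(1, 1, 4)) for i in range(6)},
            "sub_elite": {f"b{i}": list(rng.normal(0, 1, 4)) for i in range(6)},
        }
        res = ef.rm_anova_iemg(_long_table(data))
        df1, df2 = res.df
        identity = res.F * df1 / (res.F * df1 + df2)
        assert res.partial_eta_sq == pytest.approx(identity, rel=1e-9)
        assert res.eta_ci[0] <= res.partial_eta_sq <= res.eta_ci[1]

    def test_unbalanced_design_rejected(self):
        tab = _long_table({
            "elite": {"a": [1, 2, 3], "b": [3, 4]},
            "sub_elite": {"c": [1, 2], "d": [3, 4]},
        })
        with pytest.raises(DataError, match="mixed"):
            ef.rm_anova_iemg(tab)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

class TestHedgesG:
    def test_equal_means_zero(self):
        es = ef.hedges_g([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert es.value == pytest.approx(0.0)

    def test_hand_computed_example(self):
        es = ef.hedges_g([1, 2, 3], [2, 3, 4])
        assert es.J == pytest.approx(0.8)
        assert es.value == pytest.approx(-0.8)
        assert es.ci[0] < es.value < es.ci[1]

    def test_moderate_label(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.64, 1.0, 4000)
        y = rng.normal(0.0, 1.0, 4000)
        es = ef.hedges_g(x, y)
        assert es.label == "moderate"

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(UndefinedEffectError):
            ef.hedges_g([1.0, 1.0], [2.0, 2.0])

    def test_welch_variant_close_to_pooled_for_equal_variances(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1, 1, 30)
        y = rng.normal(0, 1, 30)
        a = ef.hedges_g(x, y, welch=False)
        b = ef.hedges_g(x, y, welch=True)
        assert a.value == pytest.approx(b.value, abs=0.02)

    def test_ci_coverage_near_nominal(self):
        # true standardized difference 0.5 at n=50/group
        rng = np.random.default_rng(42)
        true_d = 0.5
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(true_d, 1.0, 50)
            y = rng.normal(0.0, 1.0, 50)
            es = ef.hedges_g(x, y)
            if es.ci[0] <= true_d <= es.ci[1]:
                hits += 1
        assert abs(hits / n_rep - 0.95) < 0.04


class TestCohenDz:
    def test_zero_mean_differences(self):
        assert ef.cohen_dz([-1.0, 1.0, -2.0, 2.0]).value == pytest.approx(0.0)

    def test_constant_differences_rejected(self):
        with pytest.raises(UndefinedEffectError):
            ef.cohen_dz([1.0, 1.0, 1.0, 1.0])

    def test_hand_computed_example(self):
        assert ef.cohen_dz([0.0, 1.0, 2.0]).value == pytest.approx(1.0)


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.19, "trivial"), (0.20, "small"), (0.59, "small"),
        (0.60, "moderate"), (0.64, "moderate"), (1.19, "moderate"),
        (1.20, "large"), (2.00, "very_large"), (3.99, "very_large"),
        (4.00, "extremely_large"), (-0.8, "moderate"),
    ],
)
def test_effect_labels(value, expected):
    assert ef.label_effect(value) == expected


# ---------------------------------------------------------------------------
# PC-score comparison and FDR
# ---------------------------------------------------------------------------

def _score_frame(x, y, pc=1):
    rows = [{"subject": f"e{i}", "group": "elite", "pc": pc, "score": v}
            for i, v in enumerate(x)]
    rows += [{"subject": f"s{i}", "group": "sub_elite", "pc": pc, "score": v}
             for i, v in enumerate(y)]
    return pd.DataFrame(rows)


class TestComparePcScores:
    def test_identical_distributions_null(self):
        df = _score_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        row = ef.compare_pc_scores(df).iloc[0]
        assert row["p"] > 0.99
        assert row["hedges_g"] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(17)
        x = rng.normal(2.0, 1.0, 10)
        y = rng.normal(0.0, 1.0, 10)
        row = ef.compare_pc_scores(_score_frame(x, y)).iloc[0]
        assert row["p"] < 0.01
        assert 1.0 <= row["hedges_g"] <= 3.0
        assert row["diff_ci_low"] < row["mean_diff"] < row["diff_ci_high"]

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(18)
        x = rng.normal(1.0, 1.0, 8)
        y = rng.normal(0.0, 1.0, 8)
        a = ef.compare_pc_scores(_score_frame(x, y)).iloc[0]
        b = ef.compare_pc_scores(_score_frame(y, x)).iloc[0]
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)
        assert a["hedges_g"] == pytest.approx(-b["hedges_g"], rel=1e-9)
        assert a["mean_diff"] == pytest.approx(-b["mean_diff"], rel=1e-9)


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(
            ef.adjust_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ef.adjust_fdr([0.37]), [0.37])

    def test_tied_pvalues_unchanged(self):
        np.testing.assert_allclose(ef.adjust_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(0, 1, 25)
        adj = ef.adjust_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ef.adjust_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# stepwise discriminant
# ---------------------------------------------------------------------------

class TestStepwiseDiscriminant:
    def _toy(self, seed=23, n=30):
        rng = np.random.default_rng(seed)
        labels = np.array(["elite"] * n + ["sub_elite"] * n)
        signal = np.concatenate([rng.normal(3, 1, n), rng.normal(0, 1, n)])
        noise1 = rng.normal(0, 1, 2 * n)
        noise2 = rng.normal(0, 1, 2 * n)
        X = pd.DataFrame({"signal": signal, "noise1": noise1, "noise2": noise2})
        return X, labels

    def test_separating_feature_selected_first(self):
        X, labels = self._toy()
        selected, trace = ef.stepwise_discriminant(X, labels)
        assert selected[0] == "signal"
        assert trace[0]["action"] == "enter"

    def test_no_group_difference_empty_selection(self):
        X = pd.DataFrame({"a": np.tile([1.0, 2.0, 3.0], 4),
                          "b": np.tile([4.0, 5.0, 6.0], 4)})
        labels = np.array(["elite"] * 6 + ["sub_elite"] * 6)
        selected, _ = ef.stepwise_discriminant(X, labels)
        assert selected == []

    def test_selection_invariant_to_feature_scaling(self):
        X, labels = self._toy(seed=29)
        a, _ = ef.stepwise_discriminant(X, labels)
        Xs = X * np.array([100.0, 0.01, 7.0])
        b, _ = ef.stepwise_discriminant(Xs, labels)
        assert a == b


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _trial_frame(rng, n_subj, k, subject_sd, resid_sd, delta=0.0):
    rows = []
    for g, tag, shift in (("elite", "e", delta), ("sub_elite", "s", 0.0)):
        for i in range(n_subj):
            b = rng.normal(0, subject_sd)
            for t in range(k):
                rows.append({"subject": f"{tag}{i}", "group": g, "trial": t + 1,
                             "score": shift + b + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_zero_subject_variance_recovered(self):
        rng = np.random.default_rng(31)
        df = _trial_frame(rng, 100, 6, subject_sd=0.0, resid_sd=1.0)
        res = ef.mixed_model_scores(df)
        assert res.subject_var < 0.05
        assert res.residual_var == pytest.approx(1.0, rel=0.1)

    def test_variance_ratio_recovered_at_large_n(self):
        rng = np.random.default_rng(32)
        df = _trial_frame(rng, 100, 6, subject_sd=1.0, resid_sd=1.0)
        res = ef.mixed_model_scores(df)
        icc_true = 1.0 / 2.0
        icc_est = res.subject_var / (res.subject_var + res.residual_var)
        assert icc_est == pytest.approx(icc_true, rel=0.10)

    def test_group_effect_equals_subject_mean_t_test(self):
        rng = np.random.default_rng(33)
        df = _trial_frame(rng, 8, 4, subject_sd=0.5, resid_sd=0.5, delta=1.0)
        res = ef.mixed_model_scores(df)
        subj = df.groupby(["group", "subject"])["score"].mean()
        from scipy import stats as sst
        t, p = sst.ttest_ind(subj.loc["elite"], subj.loc["sub_elite"],
                             equal_var=True)
        assert res.group_t == pytest.approx(t, rel=1e-9)
        assert res.group_p == pytest.approx(p, rel=1e-9)

    def test_unbalanced_rejected(self):
        df = pd.DataFrame({
            "subject": ["a", "a", "b"], "group": ["elite"] * 3,
            "trial": [1, 2, 1], "score": [0.1, 0.2, 0.3],
        })
        with pytest.raises(DataError):
            ef.mixed_model_scores(df)


# ---------------------------------------------------------------------------
# ICC(3,k)
# ---------------------------------------------------------------------------

def _icc_oracle(Y):
    """Independent two-way-ANOVA-table computation of ICC(3,k)."""
    n, k = Y.shape
    grand = Y.mean()
    ss_rows = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((Y - grand) ** 2).sum() - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / ms_rows


TOY_5X3 = np.array([
    [9.0, 10.0, 11.0],
    [5.5, 6.0, 6.5],
    [3.0, 2.0, 4.0],
    [7.5, 8.5, 7.0],
    [1.0, 1.5, 0.5],
])


class TestIcc3k:
    def test_toy_matrix_matches_anova_oracle(self):
        res = ef.icc_3k(TOY_5X3)
        assert res.icc == pytest.approx(_icc_oracle(TOY_5X3), abs=1e-10)
        assert res.ci[0] < res.icc < res.ci[1]

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        n, k = TOY_5X3.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": TOY_5X3.ravel(),
        })
        icc = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        ref = icc.loc[icc["Type"] == "ICC(C,k)", "ICC"].iloc[0]
        assert ef.icc_3k(TOY_5X3).icc == pytest.approx(ref, abs=1e-9)

    def test_perfect_consistency(self):
        Y = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        res = ef.icc_3k(Y)
        assert res.icc == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_equal_row_means_nonpositive(self):
        rng = np.random.default_rng(35)
        Y = rng.normal(0, 1, (6, 3))
        Y = Y - Y.mean(axis=1, keepdims=True) + 5.0   # force equal row means
        res = ef.icc_3k(Y)
        assert res.icc <= 0.0
        assert res.negative or res.icc == 0.0

    def test_missing_cells_rejected(self):
        Y = TOY_5X3.copy()
        Y[2, 1] = np.nan
        with pytest.raises(DataError):
            ef.icc_3k(Y)

    def test_sem_cv_definitions(self):
        res = ef.icc_3k(TOY_5X3)
        sd = TOY_5X3.mean(axis=1).std(ddof=1)
        assert res.sem == pytest.approx(sd * np.sqrt(1 - res.icc), rel=1e-9)
        assert res.cv == pytest.approx(100 * res.sem / TOY_5X3.mean(), rel=1e-9)
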