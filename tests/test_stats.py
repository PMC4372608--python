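"""CAP ordination, permutation ANOVA, cluster data and LDA error estimation."""

import numpy as np
import pandas as pd
import pytest

import otoshape as ot


def planted(seed=0, n=(30, 30, 30), shift=0.0, n_coef=5, axis=0):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g, ng in enumerate(n):
        block = rng.normal(0, 1, size=(ng, n_coef))
        block[:, axis] += g * shift
        blocks.append(block)
        labels.extend([f"G{g + 1}"] * ng)
    return np.vstack(blocks), np.array(labels)


class TestCap:
    def test_three_groups_give_two_axes_and_unit_ratio_sum(self):
        y, labels = planted(1, shift=1.0)
        res = ot.cap(y, labels)
        assert res.eigenvalues.shape == (2,)
        assert res.eig_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues >= 0).all()

    def test_matches_brute_force_projection_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(10, 4))
        labels = np.array(["a"] * 4 + ["b"] * 3 + ["c"] * 3)
        # oracle: regress each column on group dummies, eigendecompose fitted
        g = pd.get_dummies(labels).to_numpy(float)
        yc = y - y.mean(0)
        hat = g @ np.linalg.pinv(g)
        yfit = hat @ yc
        eig_oracle = np.sort(np.linalg.eigvalsh(yfit.T @ yfit))[::-1][:2] / (len(y) - 1)
        res = ot.cap(y, labels)
        np.testing.assert_allclose(res.eigenvalues, eig_oracle, atol=1e-9)
        # site scores are projections of centered data on the fitted axes
        np.testing.assert_allclose(np.abs(res.site_scores), np.abs(yc @ (np.linalg.svd(yfit)[2][:2].T)), atol=1e-9)

    def test_separated_groups_separate_on_axis1(self):
        y, labels = planted(3, n=(40, 40), shift=8.0)
        res = ot.cap(y, labels)
        s1 = res.site_scores[labels == "G1", 0]
        s2 = res.site_scores[labels == "G2", 0]
        assert s1.max() < s2.min() or s2.max() < s1.min()  # no overlap

    def test_label_permutation_drops_constrained_variance(self):
        y, labels = planted(5, shift=2.0)
        observed = ot.cap(y, labels).eigenvalues.sum()
        rng = np.random.default_rng(11)
        for _ in range(20):
            perm = rng.permutation(labels)
            assert ot.cap(y, perm).eigenvalues.sum() < observed

    def test_more_coefficients_than_fish_rejected(self):
        y, labels = planted(1, n=(3, 3), n_coef=10)
        with pytest.raises(ValueError, match="larger than the number of coefficients"):
            ot.cap(y, labels)

    def test_single_group_rejected(self):
        y = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            ot.cap(y, ["a"] * 10)


class TestPermanova:
    def test_df_for_160_fish_in_3_groups(self):
        y, labels = planted(2, n=(65, 65, 30), shift=0.5)
        table = ot.permutation_anova(y, labels, permutations=99, seed=1)
        assert table.model_df == 2
        assert table.residual_df == 157

    def test_strong_separation_reaches_minimum_p(self):
        y, labels = planted(4, shift=6.0)
        table = ot.permutation_anova(y, labels, permutations=1000, seed=2)
        assert table.p == pytest.approx(1 / 1001)
        assert round(table.p, 3) == 0.001

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 100
        for i in range(reps):
            y = rng.normal(size=(30, 3))
            labels = np.repeat(["a", "b", "c"], 10)
            t = ot.permutation_anova(y, labels, permutations=99, seed=i)
            rejections += t.p <= 0.05
        # binomial 99% envelope around 0.05 with 100 replicates
        assert rejections <= 12

    def test_p_invariant_to_group_relabeling(self):
        y, labels = planted(6, shift=1.0)
        t1 = ot.permutation_anova(y, labels, permutations=199, seed=3)
        renamed = np.char.replace(labels.astype(str), "G", "pop_")
        t2 = ot.permutation_anova(y, renamed, permutations=199, seed=3)
        assert t1.p == t2.p
        assert t1.pseudo_f == pytest.approx(t2.pseudo_f, rel=1e-12)

    def test_variance_decomposition_is_consistent(self):
        y, labels = planted(8, shift=1.5)
        t = ot.permutation_anova(y, labels, permutations=9, seed=0)
        yc = y - y.mean(0)
        total = np.sum(yc**2) / (len(y) - 1)
        assert t.model_var + t.residual_var == pytest.approx(total, rel=1e-12)


class TestClusterData:
    def test_single_fish_groups_have_zero_se(self):
        y, labels = planted(1, n=(1, 1, 1), n_coef=2, shift=3.0)
        res = ot.cap(y, labels)
        data = ot.cluster_plot_data(res, labels)
        assert (data[["se1", "se2"]].to_numpy() == 0).all()

    def test_duplicating_data_halves_se_by_sqrt2(self):
        y, labels = planted(9, n=(20, 20), shift=2.0, n_coef=3)
        res1 = ot.cap(y, labels)
        d1 = ot.cluster_plot_data(res1, labels)
        y2 = np.vstack([y, y])
        labels2 = np.concatenate([labels, labels])
        res2 = ot.cap(y2, labels2)
        d2 = ot.cluster_plot_data(res2, labels2)
        np.testing.assert_allclose(
            np.abs(d2["mean1"].to_numpy()), np.abs(d1["mean1"].to_numpy()), atol=1e-9
        )
        np.testing.assert_allclose(
            d2["se1"].to_numpy(), d1["se1"].to_numpy() / np.sqrt(2), atol=1e-9
        )

    def test_axis_labels_carry_percentages(self):
        y, labels = planted(1, shift=1.0)
        data = ot.cluster_plot_data(ot.cap(y, labels), labels)
        assert data.attrs["axis_labels"][0].startswith("CAP1 (")


class TestLdaError:
    def test_separable_groups_have_zero_cv_error(self):
        y, labels = planted(12, n=(30, 30), shift=10.0)
        err = ot.lda_error(y, labels, "cv", 10, seed=0)
        assert err.error_rate == 0.0

    def test_identical_groups_error_near_half(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=(100, 4))
        labels = np.repeat(["a", "b"], 50)
        err = ot.lda_error(y, labels, "cv", 10, seed=5)
        assert err.error_rate == pytest.approx(0.5, abs=0.1)

    def test_cv_with_n_folds_is_exactly_leave_one_out(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        y, labels = planted(14, n=(15, 15), shift=1.2, n_coef=3)
        n = len(y)
        err = ot.lda_error(y, labels, "cv", n, seed=9)
        wrong = 0
        for i in range(n):  # explicit LOO oracle
            train = np.setdiff1d(np.arange(n), [i])
            model = LinearDiscriminantAnalysis().fit(y[train], labels[train])
            wrong += model.predict(y[[i]])[0] != labels[i]
        assert err.error_rate == pytest.approx(wrong / n, abs=1e-12)

    def test_bootstrap_estimators_track_cv_on_moderate_effect(self):
        y, labels = planted(15, n=(60, 60), shift=1.6, n_coef=4)
        boot = ot.lda_error(y, labels, "boot", 100, seed=3)
        b632 = ot.lda_error(y, labels, "boot632", 100, seed=3)
        assert 0.05 < boot.error_rate < 0.5
        assert 0.0 < b632.error_rate <= boot.error_rate + 1e-9

    def test_too_many_coefficients_rejected(self):
        y, labels = planted(16, n=(4, 4), n_coef=10)
        with pytest.raises(ValueError, match="fewer"):
            ot.lda_error(y, labels, "cv", 2, seed=0)
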