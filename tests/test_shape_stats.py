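"""Procrustes ANOVA, allometry, PCA, CVA and distance-test checks."""

import numpy as np
import pytest

from opermorph import (
    allometry_regress,
    cva,
    group_distance_tests,
    pca,
    procrustes_anova,
    shape_along_axis,
)


class TestProcrustesAnova:
    def test_hand_decomposition_two_specimens(self, rng):
        # 2 specimens x 2 sides, sides identical within specimen,
        # ||shapeA - shapeB|| = 1: the 4 observations sit at +-(a-b)/2
        # from the grand mean, so SS(individual) = 1, SS(side) = 0
        a = rng.normal(size=12)
        diff = rng.normal(size=12)
        b = a - diff / np.linalg.norm(diff)
        data = np.stack([a, a, b, b])
        table = procrustes_anova(
            data, ["s1", "s1", "s2", "s2"], ["l", "r", "l", "r"]
        )
        assert table["between-specimen"][1] == pytest.approx(1.0, abs=1e-12)
        assert table["within-specimen"][1] == pytest.approx(0.0, abs=1e-12)
        assert table["residual"][1] == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_observations(self, rng):
        row = rng.normal(size=10)
        data = np.tile(row, (4, 1))
        table = procrustes_anova(data, ["a", "a", "b", "b"], ["l", "r", "l", "r"])
        assert all(r[1] == 0.0 for r in table.rows)

    def test_ss_additivity_unbalanced(self, rng):
        # random unbalanced design: sum of effect + residual SS = total SS
        n_spec = 9
        rows, ind, side = [], [], []
        for s in range(n_spec):
            sides = ["l", "r"] if s % 3 else ["l"]
            for sd in sides:
                rows.append(rng.normal(size=16))
                ind.append(f"s{s}")
                side.append(sd)
        data = np.stack(rows)
        table = procrustes_anova(data, ind, side)
        ss_total = table["total"][1]
        parts = (
            table["between-specimen"][1]
            + table["within-specimen"][1]
            + table["residual"][1]
        )
        assert parts == pytest.approx(ss_total, rel=1e-10)
        grand = data.mean(axis=0)
        assert ss_total == pytest.approx(np.sum((data - grand) ** 2), rel=1e-12)

    def test_df_scaling(self, rng):
        k = 8  # 16 coordinates -> shape dim 2k-4 = 12
        data = rng.normal(size=(6, 2 * k))
        table = procrustes_anova(
            data, ["a", "a", "b", "b", "c", "c"], ["l", "r"] * 3
        )
        assert table["between-specimen"][2] == 2 * (2 * k - 4)
        assert table["within-specimen"][2] == 1 * (2 * k - 4)
        assert table["total"][2] == 5 * (2 * k - 4)

    def test_single_level_factor_omitted(self, rng):
        data = rng.normal(size=(4, 10))
        with pytest.warns(UserWarning, match="one level"):
            table = procrustes_anova(data, ["a", "a", "b", "b"], ["l"] * 4)
        assert all(r[0] != "within-specimen" for r in table.rows)


class TestAllometry:
    def test_exact_recovery_noise_free(self, rng):
        # shapes constructed exactly as mean_g + 0.1 (s - s_bar_g) v
        v = rng.normal(size=20)
        v /= np.linalg.norm(v)
        groups, sizes, shapes = [], [], []
        for g, mean in enumerate(rng.normal(size=(3, 20))):
            s = rng.uniform(1, 5, size=6)
            for si in s:
                shapes.append(mean + 0.1 * (si - s.mean()) * v)
                sizes.append(si)
                groups.append(f"g{g}")
        model = allometry_regress(np.stack(shapes), sizes, groups)
        np.testing.assert_allclose(model.slope, 0.1 * v, atol=1e-10)
        assert model.percent_predicted == pytest.approx(100.0, abs=1e-8)

    def test_degenerate_group_excluded(self, rng):
        shapes = rng.normal(size=(7, 8))
        sizes = [1.0, 2.0, 3.0, 2.0, 2.0, 2.0, 5.0]
        groups = ["a", "a", "a", "b", "b", "b", "c"]  # b: no size var, c: n=1
        with pytest.warns(UserWarning, match="excluded"):
            model = allometry_regress(shapes, sizes, groups)
        assert set(model.excluded_groups) == {"b", "c"}
        sel = np.array(groups) == "a"
        s = np.asarray(sizes)[sel] - np.mean(np.asarray(sizes)[sel])
        y = shapes[sel] - shapes[sel].mean(axis=0)
        expected = (s @ y) / np.sum(s**2)
        np.testing.assert_allclose(model.slope, expected, atol=1e-12)

    def test_pooled_slope_vs_two_group_closed_form(self, rng):
        # two groups, identical within-group slope but different means:
        # the pooled estimate recovers the common slope; a regression
        # ignoring groups is pulled away by the mean difference
        v = rng.normal(size=10)
        v /= np.linalg.norm(v)
        slope = 0.07
        shapes, sizes, groups = [], [], []
        means = {"a": rng.normal(size=10), "b": rng.normal(size=10) + 3}
        size_means = {"a": 2.0, "b": 8.0}
        for g in ("a", "b"):
            s = size_means[g] + rng.uniform(-1, 1, 8)
            for si in s:
                shapes.append(means[g] + slope * (si - s.mean()) * v)
                sizes.append(si)
                groups.append(g)
        shapes = np.stack(shapes)
        sizes = np.asarray(sizes)
        groups = np.asarray(groups)
        model = allometry_regress(shapes, sizes, groups)
        # closed-form pooled slope: sum over both groups of centered products
        num = np.zeros(10)
        den = 0.0
        for g in ("a", "b"):
            sel = groups == g
            sc = sizes[sel] - sizes[sel].mean()
            yc = shapes[sel] - shapes[sel].mean(axis=0)
            num += sc @ yc
            den += np.sum(sc**2)
        np.testing.assert_allclose(model.slope, num / den, atol=1e-12)
        np.testing.assert_allclose(model.slope, slope * v, atol=1e-10)
        naive = ((sizes - sizes.mean()) @ (shapes - shapes.mean(axis=0))) / np.sum(
            (sizes - sizes.mean()) ** 2
        )
        assert np.linalg.norm(naive - slope * v) > 1e-3

    def test_residuals_uncorrelated_with_centered_size(self, rng):
        shapes = rng.normal(size=(20, 12))
        sizes = rng.uniform(1, 4, 20)
        groups = np.repeat(["a", "b"], 10)
        model = allometry_regress(shapes, sizes, groups)
        s_cent = sizes.copy()
        resid_cent = model.residuals.copy()
        for g in ("a", "b"):
            sel = groups == g
            s_cent[sel] -= sizes[sel].mean()
            resid_cent[sel] -= model.residuals[sel].mean(axis=0)
        cov = s_cent @ resid_cent / len(sizes)
        assert np.abs(cov).max() <= 1e-10

    def test_percent_invariant_to_group_mean_shifts(self, rng):
        shapes = rng.normal(size=(16, 6))
        sizes = rng.uniform(1, 3, 16)
        groups = np.repeat(["a", "b"], 8)
        m1 = allometry_regress(shapes, sizes, groups)
        shifted = shapes.copy()
        shifted[np.asarray(groups) == "b"] += rng.normal(size=6) * 5
        m2 = allometry_regress(shifted, sizes, groups)
        assert m1.percent_predicted == pytest.approx(
            m2.percent_predicted, abs=1e-10
        )

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError, match="size variance"):
            allometry_regress(np.eye(4), [2, 2, 2, 2], ["a", "a", "b", "b"])


class TestPca:
    def test_single_line_one_axis(self, rng):
        direction = rng.normal(size=8)
        t = rng.normal(size=20)
        data = np.outer(t, direction) + rng.normal(size=8)
        ord_ = pca(data)
        assert len(ord_.eigenvalues) == 1
        np.testing.assert_allclose(ord_.percent_variance, [100.0])

    def test_percent_variance_sums_to_100(self, rng):
        ord_ = pca(rng.normal(size=(15, 9)))
        assert ord_.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_axes_orthonormal_scores_centered(self, rng):
        ord_ = pca(rng.normal(size=(25, 10)))
        gram = ord_.axes @ ord_.axes.T
        np.testing.assert_allclose(gram, np.eye(len(ord_.axes)), atol=1e-9)
        assert np.abs(ord_.scores.mean(axis=0)).max() <= 1e-10

    def test_eigenvalues_match_direct_oracle(self, rng):
        data = rng.normal(size=(10, 6))
        ord_ = pca(data)
        C = np.cov(data, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(C))[::-1][: len(ord_.eigenvalues)]
        np.testing.assert_allclose(ord_.eigenvalues, expected, atol=1e-10)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 4)))


class TestShapeAlongAxis:
    def test_scale_zero_is_mean(self, rng):
        ord_ = pca(rng.normal(size=(12, 8)))
        np.testing.assert_allclose(
            shape_along_axis(ord_, 0, 0.0).ravel(order="F"), ord_.mean
        )

    def test_plus_minus_reflect_through_mean(self, rng):
        ord_ = pca(rng.normal(size=(12, 8)))
        plus = shape_along_axis(ord_, 1, 0.3)
        minus = shape_along_axis(ord_, 1, -0.3)
        mean = ord_.mean
        np.testing.assert_allclose(
            plus.ravel(order="F") - mean, -(minus.ravel(order="F") - mean),
            atol=1e-12,
        )

    def test_procrustes_distance_equals_scale(self, rng):
        ord_ = pca(rng.normal(size=(12, 8)))
        shape = shape_along_axis(ord_, 1, 0.1)
        assert np.linalg.norm(shape.ravel(order="F") - ord_.mean) == pytest.approx(
            0.1, abs=1e-12
        )

    def test_axis_out_of_range(self, rng):
        ord_ = pca(rng.normal(size=(5, 6)))
        with pytest.raises(IndexError):
            shape_along_axis(ord_, 99, 0.1)


def blobs(rng, centers, n=20, scale=0.3):
    data, labels = [], []
    for i, c in enumerate(centers):
        data.append(np.asarray(c) + scale * rng.standard_normal((n, len(c))))
        labels += [f"g{i}"] * n
    return np.vstack(data), np.asarray(labels)


class TestCva:
    def test_three_groups_two_cvs_full_variance(self, rng):
        data, labels = blobs(rng, [(0, 0, 0, 0), (4, 0, 0, 0), (0, 4, 0, 0)])
        res = cva(data, labels)
        assert res.cv_eigenvalues.size == 2
        assert res.percent_between_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_groups_one_cv(self, rng):
        data, labels = blobs(rng, [(0, 0, 0), (3, 0, 0)])
        res = cva(data, labels)
        assert res.cv_eigenvalues.size == 1

    def test_within_group_score_variance_is_one(self, rng):
        data, labels = blobs(rng, [(0, 0, 0, 0, 0), (3, 1, 0, 0, 0), (0, 0, 3, 0, 0)])
        res = cva(data, labels)
        n, g = data.shape[0], 3
        pooled = np.zeros((res.scores.shape[1], res.scores.shape[1]))
        for lev in res.group_names:
            sub = res.scores[labels == lev]
            d = sub - sub.mean(axis=0)
            pooled += d.T @ d
        pooled /= n - g
        np.testing.assert_allclose(pooled, np.eye(res.scores.shape[1]), atol=1e-8)

    def test_group_of_one_rejected(self, rng):
        data = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="size 1"):
            cva(data, ["a", "a", "b", "b", "c"])

    def test_rank_deficient_data_handled(self, rng):
        # embed 2D blobs in 10D via a fixed linear map: CVA still works
        base, labels = blobs(rng, [(0, 0), (3, 0), (0, 3)], n=10)
        embed = rng.normal(size=(2, 10))
        res = cva(base @ embed, labels)
        assert res.cv_eigenvalues.size == 2


class TestGroupDistances:
    def test_identity_w_hand_value(self, rng):
        # two tight blobs with means 2 apart and pooled W ~ I would give
        # D ~ 2; construct data with exactly unit pooled covariance
        n = 40
        base = rng.standard_normal((n, 2))
        # zero each group's mean, then whiten so pooled W is exactly identity
        base[: n // 2] -= base[: n // 2].mean(axis=0)
        base[n // 2 :] -= base[n // 2 :].mean(axis=0)
        W = (base.T @ base) / (n - 2)
        white = base @ np.linalg.inv(np.linalg.cholesky(W)).T
        data = white.copy()
        data[n // 2 :] += [2.0, 0.0]
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        maha, proc, *_ = group_distance_tests(data, labels, n_perm=10, seed=1)
        assert maha[0, 1] == pytest.approx(2.0, rel=1e-6)

    def test_diagonal_w_hand_value(self, rng):
        # means differing by (2, 0) with W = diag(4, 1): D = 2/sqrt(4) = 1
        n = 60
        z = rng.standard_normal((n, 2))
        half = n // 2
        z[:half] -= z[:half].mean(axis=0)
        z[half:] -= z[half:].mean(axis=0)
        W = (z.T @ z) / (n - 2)
        white = z @ np.linalg.inv(np.linalg.cholesky(W)).T
        data = white * np.array([2.0, 1.0])  # now pooled W = diag(4, 1)
        data[half:] += [2.0, 0.0]
        labels = ["a"] * half + ["b"] * half
        maha, proc, *_ = group_distance_tests(data, labels, n_perm=10, seed=1)
        assert maha[0, 1] == pytest.approx(1.0, rel=1e-6)
        assert proc[0, 1] == pytest.approx(2.0, rel=1e-6)

    def test_mahalanobis_affine_invariant_procrustes_not(self, rng):
        data, labels = blobs(rng, [(0, 0, 0), (2, 1, 0), (0, 0, 2)], n=15)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        maha1, proc1, *_ = group_distance_tests(data, labels, n_perm=5, seed=0)
        maha2, proc2, *_ = group_distance_tests(data @ A.T, labels, n_perm=5, seed=0)
        np.testing.assert_allclose(maha1, maha2, atol=1e-6)
        assert np.abs(proc1 - proc2).max() > 1e-3

    def test_p_values_in_range_and_separated_groups_significant(self, rng):
        data, labels = blobs(rng, [(0, 0), (6, 0), (0, 6)], n=15, scale=0.2)
        maha, proc, p_m, p_p, levels = group_distance_tests(
            data, labels, n_perm=200, seed=3
        )
        off = ~np.eye(3, dtype=bool)
        assert (p_m[off] >= 1 / 200).all() and (p_m[off] <= 1).all()
        assert (p_m[off] == 1 / 200).all()
        assert (p_p[off] == 1 / 200).all()

    def test_permuted_labels_inside_null_support(self, rng):
        data, labels = blobs(rng, [(0, 0), (0.5, 0)], n=12)
        shuffled = rng.permutation(labels)
        maha, _, p_m, _, _ = group_distance_tests(
            data, shuffled, n_perm=100, seed=5
        )
        assert 1 / 100 <= p_m[0, 1] <= 1.0
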