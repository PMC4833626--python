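import numpy as np
import pandas as pd
import pytest
from selflines import morpho

from oracles import arc_length_fourier_first_harmonic


def circle(n=512, r=1.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def ellipse(n=512, a=2.0, b=1.0, angle=0.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack(
        [center[0] + ca * x - sa * y, center[1] + sa * x + ca * y]
    )


def blob(seed, n=256):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1 + sum(
        rng.normal(0, 0.08 / k) * np.cos(k * t + rng.uniform(0, 2 * np.pi))
        for k in range(2, 7)
    )
    return np.column_stack([1.4 * r * np.cos(t), r * np.sin(t)])


def norm_coeffs(pts, n_harmonics=10, **kw):
    return morpho.normalize_efa(morpho.elliptic_fourier(pts, n_harmonics), **kw)


class TestEllipticFourier:
    def test_circle_closed_form(self):
        efa = morpho.elliptic_fourier(circle(n=2048, r=3.0), 8)
        a1, b1, c1, d1 = efa.coeffs[0]
        assert np.hypot(a1, c1) == pytest.approx(3.0, rel=1e-5)
        assert np.hypot(b1, d1) == pytest.approx(3.0, rel=1e-5)
        higher = np.abs(efa.coeffs[1:]).max()
        assert higher < 1e-6 * 3.0

    def test_ellipse_matches_direct_integral_oracle(self):
        pts = ellipse(n=4096)
        efa = morpho.elliptic_fourier(pts, 6)
        oa1, od1 = arc_length_fourier_first_harmonic(pts)
        assert efa.coeffs[0][0] == pytest.approx(oa1, rel=1e-6)
        assert efa.coeffs[0][3] == pytest.approx(od1, rel=1e-6)
        assert abs(efa.coeffs[0][1]) < 1e-9 and abs(efa.coeffs[0][2]) < 1e-9

    def test_offsets_recover_centroid(self):
        efa = morpho.elliptic_fourier(circle(center=(5.0, -2.0)), 4)
        assert efa.A0 == pytest.approx(5.0, abs=1e-6)
        assert efa.C0 == pytest.approx(-2.0, abs=1e-6)

    def test_reversed_traversal_same_normalized_shape(self):
        pts = blob(1)
        f = norm_coeffs(pts)
        r = norm_coeffs(pts[::-1])
        np.testing.assert_allclose(f.coeffs, r.coeffs, atol=1e-8)

    def test_nyquist_cap_warns(self):
        with pytest.warns(UserWarning, match="harmonics"):
            efa = morpho.elliptic_fourier(circle(n=64), 399)
        assert efa.n_harmonics == 32

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValueError):
            morpho.elliptic_fourier(np.zeros((40, 2)), 4)


class TestNormalization:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_scale_invariance(self, seed):
        pts = blob(seed)
        a = norm_coeffs(pts)
        b = norm_coeffs(pts * 3.0)
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-8)

    @pytest.mark.parametrize("angle", [0.3, 0.7, 2.4])
    def test_rotation_invariance(self, angle):
        pts = blob(4)
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        a = norm_coeffs(pts)
        b = norm_coeffs(pts @ R.T)
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-8)

    def test_translation_invariance(self):
        pts = blob(5)
        a = norm_coeffs(pts)
        b = norm_coeffs(pts + np.array([11.0, -4.0]))
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-8)

    @pytest.mark.parametrize("shift", [1, 17, 100])
    def test_start_point_invariance(self, shift):
        pts = blob(6)
        a = norm_coeffs(pts)
        b = norm_coeffs(np.roll(pts, shift, axis=0))
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-8)

    def test_standard_orientation(self):
        n = norm_coeffs(blob(7), scale=False)
        a1, b1, c1, d1 = n.coeffs[0]
        assert a1 > 0
        assert abs(b1) < 1e-9 and abs(c1) < 1e-9
        assert d1 >= 0

    def test_different_shapes_differ(self):
        a = norm_coeffs(ellipse(a=2.0))
        b = norm_coeffs(ellipse(a=1.2))
        assert np.abs(a.coeffs - b.coeffs).max() > 1e-3

    def test_zero_first_harmonic_rejected(self):
        efa = morpho.EFACoefficients(
            coeffs=np.zeros((3, 4)), A0=0.0, C0=0.0
        )
        with pytest.raises(ValueError):
            morpho.normalize_efa(efa)


class TestInverse:
    def test_full_rank_reconstruction_accuracy(self):
        pts = blob(8, n=128)
        efa = morpho.elliptic_fourier(pts, 64)
        rec = morpho.inverse_efa(efa, n_points=2000)
        diam = np.ptp(pts, axis=0).max()
        # nearest-neighbour deviation of source points from the curve
        d = np.min(
            np.linalg.norm(pts[:, None, :] - rec.points[None, :, :], axis=2), axis=1
        )
        assert d.mean() < 1e-3 * diam

    def test_one_harmonic_is_ellipse(self):
        efa = morpho.elliptic_fourier(blob(9), 1)
        rec = morpho.inverse_efa(efa, n_points=200)
        # points of a one-harmonic reconstruction lie exactly on the conic
        # (x, y) = offset + M (cos t, sin t):  |M^-1 (p - offset)| = 1
        M = efa.coeffs[0].reshape(2, 2)
        rel = rec.points - np.array([efa.A0, efa.C0])
        radii = np.linalg.norm(np.linalg.solve(M, rel.T), axis=0)
        np.testing.assert_allclose(radii, 1.0, atol=1e-9)

    def test_reconstruction_idempotent(self):
        efa = morpho.elliptic_fourier(blob(10), 20)
        r1 = morpho.inverse_efa(efa, n_points=400)
        efa2 = morpho.elliptic_fourier(r1.points, 20)
        r2 = morpho.inverse_efa(efa2, n_points=400)
        assert np.abs(r1.points - r2.points).max() < 1e-3

    def test_error_decreases_with_harmonics(self):
        pts = blob(11, n=256)
        diam = np.ptp(pts, axis=0).max()
        errs = []
        for nh in (1, 4, 16, 64):
            rec = morpho.inverse_efa(morpho.elliptic_fourier(pts, nh), 1024)
            d = np.min(
                np.linalg.norm(pts[:, None, :] - rec.points[None, :, :], axis=2),
                axis=1,
            )
            errs.append(d.mean() / diam)
        # non-strict decrease up to the sampling floor of the comparison
        # (the point-to-curve distance is itself discretized at ~1e-6)
        assert all(e2 <= e1 * (1 + 1e-3) + 1e-6 for e1, e2 in zip(errs, errs[1:]))

    def test_harmonic_power_convergence(self):
        efa = morpho.elliptic_fourier(blob(12), 50)
        power = morpho.harmonic_power(efa)
        cum = np.cumsum(power)
        assert (np.diff(cum) >= 0).all()
        assert cum[10] / cum[-1] > 0.99


class TestEfaPca:
    def test_identical_outlines_zero_variance(self):
        efas = [norm_coeffs(blob(13))] * 4
        scores, var = morpho.efa_pca(efas, n_components=2)
        assert np.abs(scores).max() < 1e-9

    def test_aspect_families_separate_on_pc1(self):
        fam1 = [norm_coeffs(ellipse(a=2.0 + 0.02 * i, n=256)) for i in range(5)]
        fam2 = [norm_coeffs(ellipse(a=1.1 + 0.02 * i, n=256)) for i in range(5)]
        scores, _ = morpho.efa_pca(fam1 + fam2, n_components=2)
        pc1 = scores[:, 0]
        assert (pc1[:5].max() < pc1[5:].min()) or (pc1[:5].min() > pc1[5:].max())

    def test_scores_orthogonal(self):
        efas = [norm_coeffs(blob(s)) for s in range(3, 12)]
        scores, _ = morpho.efa_pca(efas, n_components=3)
        g = scores.T @ scores
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(g)).max()

    def test_too_few_outlines_rejected(self):
        with pytest.raises(ValueError):
            morpho.efa_pca([norm_coeffs(blob(1))] * 2)


class TestTraitAnova:
    def test_two_group_f_equals_t_squared(self):
        # textbook worked example: F for two groups equals Student's t^2
        g1 = np.array([4.0, 5.0, 6.0, 7.0])
        g2 = np.array([6.0, 7.0, 8.0, 9.0])
        df = pd.DataFrame({"y": np.concatenate([g1, g2])})
        labels = ["a"] * 4 + ["b"] * 4
        out = morpho.trait_anova(df, labels, trait_cols=["y"])
        from scipy import stats as ss

        t, p = ss.ttest_ind(g1, g2)
        assert out.loc["y", "F"] == pytest.approx(t**2, rel=1e-10)
        assert out.loc["y", "p"] == pytest.approx(p, rel=1e-10)
        # hand-computed between-group mean square: n/2 * (mean diff)^2 * ...
        grand = df["y"].mean()
        ms = 4 * ((g1.mean() - grand) ** 2 + (g2.mean() - grand) ** 2) / 1
        assert out.loc["y", "MS"] == pytest.approx(ms, rel=1e-12)

    def test_identical_means_large_p(self, rng):
        y = np.concatenate([rng.normal(5, 1, 30), rng.normal(5, 1, 30)])
        df = pd.DataFrame({"y": y})
        out = morpho.trait_anova(df, ["a"] * 30 + ["b"] * 30, trait_cols=["y"])
        assert out.loc["y", "p"] > 0.01

    def test_zero_within_variance_flagged(self):
        df = pd.DataFrame({"y": [1.0, 1.0, 2.0, 2.0]})
        out = morpho.trait_anova(df, ["a", "a", "b", "b"], trait_cols=["y"])
        assert np.isnan(out.loc["y", "F"])
        assert "zero" in out.loc["y", "flag"]

    def test_wellseparated_lineage_traits_all_significant(self):
        from selflines.synthetic import TABLE_TRAITS, simulate_trait_table

        tt = simulate_trait_table(
            TABLE_TRAITS, {"G1": 25, "G2": 26, "G3": 25}, seed=6
        )
        out = morpho.trait_anova(tt, tt["lineage"])
        assert (out["p"] < 0.001).all()
        # tukey letters: term_dim separates G1 from G2/G3 (shared letter)
        td = out.loc["term_dim"]
        assert td["letter_G1"] != td["letter_G2"]


class TestLdaLoocv:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))]
        )
        rep = morpho.lda_loocv(X, ["a"] * 10 + ["b"] * 10)
        assert rep.success_rate == 100.0
        assert rep.confusion.loc["a", "a"] == 10

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 4))
        labels = np.array(["a", "b", "c"] * 40)
        rates = []
        for _ in range(5):
            rng.shuffle(labels)
            rates.append(morpho.lda_loocv(X, labels.copy()).success_rate)
        assert abs(np.mean(rates) - 100 / 3) < 15

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 4))
        labels = ["a"] * 15 + ["b"] * 15
        r1 = morpho.lda_loocv(X, labels)
        r2 = morpho.lda_loocv(X, labels)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_singleton_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            morpho.lda_loocv(X, ["a", "a", "a", "b"])

    def test_confusion_rows_sum_to_class_sizes(self, rng):
        X = rng.normal(size=(40, 3))
        X[:20] += 1.0
        labels = ["a"] * 20 + ["b"] * 20
        rep = morpho.lda_loocv(X, labels)
        assert rep.confusion.sum(axis=1).tolist() == [20, 20]
        trace = sum(rep.confusion.loc[c, c] for c in ("a", "b"))
        assert rep.success_rate == pytest.approx(100 * trace / 40)
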