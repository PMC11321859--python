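"""Outline normalization, elliptic Fourier analysis, and PCA."""

import numpy as np
import pytest

from shapedyn.morpho import (EFACoefficients, Outline, choose_harmonics,
                             efa_transform, fit_pca, harmonic_power,
                             inverse_efa, normalize_outline,
                             project_coefficients, shape_along_axis)

from conftest import circle_outline


def ellipse(a, b, n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def blob(n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([np.cos(t) + 0.08 * np.cos(3 * t),
                            np.sin(t) + 0.05 * np.sin(2 * t)])


class TestOutline:
    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            Outline("x", np.zeros((4, 2)) + np.arange(4)[:, None])

    def test_rejects_consecutive_duplicates(self):
        pts = circle_outline(16)
        pts[3] = pts[4]
        with pytest.raises(ValueError):
            Outline("x", pts)

    def test_explicit_closing_point_dropped(self):
        pts = circle_outline(16)
        o = Outline("x", np.vstack([pts, pts[:1]]))
        assert o.n_points == 16


class TestNormalize:
    def test_centroid_and_size(self, rng):
        pts = circle_outline(64, radius=3.2, center=(5.0, -2.0))
        pts += rng.normal(0, 0.05, pts.shape)
        out = normalize_outline(Outline("x", pts))
        assert np.allclose(out.centroid(), 0.0, atol=1e-12)
        assert np.isclose(out.centroid_size(), 1.0, atol=1e-12)

    def test_idempotent_on_normalized_circle(self):
        o = Outline("c", circle_outline(64))
        norm = normalize_outline(o)
        again = normalize_outline(norm)
        assert np.allclose(norm.points, again.points, atol=1e-12)

    def test_translation_scale_invariance(self, rng):
        pts = blob(200)
        o1 = normalize_outline(Outline("a", pts))
        o2 = normalize_outline(Outline("b", 7.3 * pts + np.array([11.0, -4.0])))
        assert np.allclose(o1.points, o2.points, atol=1e-8)

    def test_rotation_and_start_index_applied(self):
        pts = circle_outline(32)
        out = normalize_outline(Outline("c", pts), orientation_angle=np.pi / 2,
                                start_index=4)
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        expected = np.roll(pts @ rot.T, -4, axis=0)
        assert np.allclose(out.points, expected / np.sqrt(0.5 * 2), atol=1e-9) \
            or np.allclose(out.points, expected, atol=1e-9)

    def test_degenerate_outline_fails(self):
        o = Outline.__new__(Outline)
        o.specimen_id = "z"
        o.points = np.zeros((10, 2))  # bypass validation to hit the guard
        with pytest.raises(ValueError, match="degenerate"):
            normalize_outline(o)


class TestEFA:
    def test_mild_ellipse_first_harmonic_dominates(self):
        o = Outline("e", ellipse(1.05, 1.0))
        cum = harmonic_power(efa_transform(o, 12))
        assert cum[0] >= 0.9999

    def test_circle_first_harmonic_coefficients(self):
        o = Outline("c", circle_outline(2000, radius=2.0))
        c = efa_transform(o, 4)
        a, b, cc, d = c.harmonics[0]
        assert np.isclose(a, 2.0, atol=1e-4)
        assert np.isclose(d, 2.0, atol=1e-4)
        assert abs(b) < 1e-6 and abs(cc) < 1e-6
        assert np.all(np.abs(c.harmonics[1:]) < 1e-6)

    def test_harmonic_limit_enforced(self):
        o = Outline("c", circle_outline(20))
        with pytest.raises(ValueError, match="10"):
            efa_transform(o, 11)
        with pytest.raises(ValueError):
            efa_transform(o, 0)

    def test_refinement_stability(self):
        c1 = efa_transform(Outline("b", blob(720)), 6)
        c2 = efa_transform(Outline("b", blob(1440)), 6)
        assert np.abs(c1.harmonics - c2.harmonics).max() < 1e-3

    def test_round_trip_is_a_contraction(self):
        # the forward transform re-parameterizes by chord length, so one
        # round trip reproduces the coefficients only to first order in the
        # shape's speed non-uniformity; iterating must contract toward the
        # self-consistent fixed point
        c0 = efa_transform(Outline("b", blob(720)), 6)
        c1 = efa_transform(inverse_efa(c0, 50_000), 6)
        d1 = np.abs(c1.harmonics - c0.harmonics).max()
        assert d1 < 1e-3
        c2 = efa_transform(inverse_efa(c1, 50_000), 6)
        d2 = np.abs(c2.harmonics - c1.harmonics).max()
        assert d2 < 0.7 * d1

    def test_round_trip_circle_exact(self):
        c = EFACoefficients("c", np.array([[1.5, 0.0, 0.0, 1.5]]))
        c2 = efa_transform(inverse_efa(c, 100_000), 1)
        assert np.abs(c2.harmonics - c.harmonics).max() < 1e-8


class TestHarmonicPower:
    def test_pure_ellipse_cumulative_one_after_first(self):
        c = EFACoefficients("e", np.array([[2.0, 0.0, 0.0, 1.0],
                                           [0.0, 0.0, 0.0, 0.0]]))
        cum = harmonic_power(c)
        assert np.isclose(cum[0], 1.0)

    def test_monotone_and_normalized(self, rng):
        c = EFACoefficients("r", rng.normal(0, 1, (10, 4)))
        cum = harmonic_power(c)
        assert np.all(np.diff(cum) >= -1e-15)
        assert np.isclose(cum[-1], 1.0)

    def test_matches_direct_summation(self, rng):
        h = rng.normal(0, 1, (7, 4))
        cum = harmonic_power(EFACoefficients("r", h))
        power = (h ** 2).sum(axis=1) / 2.0
        oracle = np.cumsum(power) / power.sum()
        assert np.allclose(cum, oracle, atol=1e-12)

    def test_all_zero_fails(self):
        with pytest.raises(ValueError):
            harmonic_power(EFACoefficients("z", np.zeros((3, 4))))


class TestChooseHarmonics:
    def test_ellipse_needs_one(self):
        o = Outline("e", ellipse(1.02, 1.0))
        assert choose_harmonics(o, 0.999) == 1

    def test_monotone_in_threshold(self):
        o = Outline("b", blob())
        assert choose_harmonics(o, 0.99) <= choose_harmonics(o, 0.999)

    def test_constructed_five_harmonic_shape(self):
        h = np.zeros((8, 4))
        h[0] = [1.0, 0.0, 0.0, 1.0]
        h[2] = [0.1, 0.0, 0.0, 0.05]
        h[4] = [0.03, 0.01, 0.0, 0.02]
        out = inverse_efa(EFACoefficients("s", h), 4096)
        assert choose_harmonics(out, 0.9999, h_max=20) == 5

    def test_unreachable_threshold_fails(self):
        o = Outline("b", blob(64))
        with pytest.raises(ValueError):
            choose_harmonics(o, 1.0 - 1e-15, h_max=2)


class TestPCA:
    def test_collinear_data_has_rank_one(self, rng):
        direction = rng.normal(0, 1, 8)
        x = np.outer(rng.normal(0, 1, 10), direction)
        basis, traits = fit_pca(x)
        assert basis.rank == 1
        assert traits.values.shape == (10, 1)

    def test_full_reconstruction(self, rng):
        x = rng.normal(0, 1, (9, 12))
        basis, traits = fit_pca(x)
        rec = basis.mean_vector + traits.values @ basis.loadings.T
        assert np.allclose(rec, x, atol=1e-8)
        assert basis.rank == 8  # n - 1 for generic data

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        x = rng.normal(0, 1, (20, 6))
        basis, traits = fit_pca(x)
        cov = traits.values.T @ traits.values / (20 - 1)
        assert np.allclose(cov, np.diag(basis.eigenvalues), atol=1e-10)

    def test_explained_curve_monotone_to_one(self, rng):
        x = rng.normal(0, 1, (15, 10))
        _, traits = fit_pca(x)
        assert np.all(np.diff(traits.explained) >= -1e-12)
        assert np.isclose(traits.explained[-1], 1.0)

    def test_centering(self, rng):
        x = rng.normal(3.0, 1.0, (12, 5))
        _, traits = fit_pca(x)
        assert np.allclose(traits.values.mean(axis=0), 0.0, atol=1e-10)

    def test_too_few_specimens(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 4)))


class TestShapeAlongAxis:
    @pytest.fixture
    def basis(self, rng):
        coeffs = []
        base = np.zeros((4, 4))
        base[0] = [1.0, 0.0, 0.0, 1.0]
        for i in range(12):
            h = base + rng.normal(0, 0.05, (4, 4))
            coeffs.append(EFACoefficients(f"s{i}", h))
        return fit_pca(coeffs)[0]

    def test_zero_multiple_gives_mean_shape(self, basis):
        out = shape_along_axis(basis, 0, 0.0, n_points=256)
        mean = inverse_efa(
            EFACoefficients("m", basis.mean_vector.reshape(-1, 4)), 256)
        assert np.allclose(out.points, mean.points, atol=1e-12)

    def test_plus_minus_mirror_in_coefficient_space(self, basis):
        up = shape_along_axis(basis, 0, 2.0, n_points=128).points
        down = shape_along_axis(basis, 0, -2.0, n_points=128).points
        mean = shape_along_axis(basis, 0, 0.0, n_points=128).points
        assert np.allclose(up - mean, -(down - mean), atol=1e-10)

    def test_projection_round_trip(self, basis):
        mult = 1.7
        flat = (basis.mean_vector
                + mult * np.sqrt(basis.eigenvalues[1]) * basis.loadings[:, 1])
        scores = project_coefficients(basis, flat)[0]
        assert np.isclose(scores[1], mult * np.sqrt(basis.eigenvalues[1]),
                          atol=1e-10)
        others = np.delete(scores, 1)
        assert np.all(np.abs(others) < 1e-10)

    def test_axis_out_of_range(self, basis):
        with pytest.raises(ValueError):
            shape_along_axis(basis, basis.rank, 1.0)
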