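"""Elliptic Fourier analysis, Procrustes superimposition, shape PCA."""

import numpy as np
import pytest

from divsel.morpho import (efa_reconstruct, efa_transform, gpa_align,
                           leaf_area, perimeter, petal_length,
                           procrustes_distance, resample_outline, shape_pca)
from divsel.simulate import gen_flower_landmarks, gen_leaf_outlines


def ellipse(a=2.5, b=1.0, n=256, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


class TestResample:
    def test_square_resampled_to_corners_and_midpoints(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        res = resample_outline(square, 8)
        expected = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5],
                             [1, 1], [0.5, 1], [0, 1], [0, 0.5]])
        assert np.allclose(res, expected, atol=1e-12)

    def test_circle_perimeter_preserved(self):
        res = resample_outline(ellipse(1, 1, 64), 256)
        assert abs(perimeter(res) - 2 * np.pi) / (2 * np.pi) < 1e-3

    def test_idempotent_on_uniform_outline(self):
        circ = ellipse(1, 1, 128)
        once = resample_outline(circ, 128)
        twice = resample_outline(once, 128)
        assert np.allclose(once, twice, atol=1e-10)

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValueError):
            resample_outline(np.zeros((10, 2)), 16)


class TestEFA:
    def test_ellipse_is_pure_first_harmonic(self):
        for a in (1.0, 2.0, 4.0):
            ef = efa_transform(ellipse(a=a), 15, parameterization="uniform")
            power = ef.harmonic_power()
            assert power[1:].sum() / power.sum() < 1e-9

    def test_circle_normalized_coefficients_closed_form(self):
        """A circle's normalized first harmonic is the identity ellipse."""
        ef = efa_transform(ellipse(1, 1), 15, parameterization="uniform")
        a1, b1, c1, d1 = ef.coeffs[0]
        assert a1 == pytest.approx(1.0, abs=1e-9)
        assert b1 == pytest.approx(0.0, abs=1e-9)
        assert c1 == pytest.approx(0.0, abs=1e-9)
        assert abs(d1) == pytest.approx(1.0, abs=1e-9)
        assert ef.scale == pytest.approx(1.0, rel=1e-4)

    def test_normalization_record_invariants(self):
        outlines = gen_leaf_outlines(1, {"p": 2.3}, lobing=0.15, seed=5)
        ef = efa_transform(outlines[0][1], 10)
        a1, b1, c1, d1 = ef.coeffs[0]
        # semi-major axis 1, orientation angle 0 after normalization
        theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1),
                                 a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
        assert np.hypot(a1, c1) == pytest.approx(1.0, abs=1e-9)
        assert np.arctan2(c1, a1) == pytest.approx(0.0, abs=1e-9)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_cumulative_power_non_decreasing_reaching_one(self):
        outlines = gen_leaf_outlines(1, {"p": 2.0}, lobing=0.2, n_points=128,
                                     seed=6)
        ef = efa_transform(outlines[0][1], 64)
        cp = ef.cumulative_power()
        assert (np.diff(cp) >= -1e-15).all()
        assert cp[-1] == pytest.approx(1.0)

    def test_nyquist_limit_enforced(self):
        with pytest.raises(ValueError, match="Nyquist"):
            efa_transform(ellipse(n=64), 33)

    def test_lobed_leaf_reaches_99_percent_at_15_harmonics(self):
        outlines = gen_leaf_outlines(5, {"p": 2.5}, lobing=0.2, n_lobes=9,
                                     n_points=512, seed=7)
        for _, xy in outlines:
            ef = efa_transform(resample_outline(xy, 512), 256)
            assert ef.cumulative_power()[14] >= 0.99


class TestReconstruct:
    def test_single_harmonic_round_trip(self):
        ell = ellipse(2.5, 1.0, 4096)
        rec = efa_reconstruct(
            efa_transform(ell, 1, parameterization="uniform"), 4096)
        assert np.abs(rec - ell).max() < 1e-6

    def test_error_decreases_with_harmonics(self):
        outlines = gen_leaf_outlines(1, {"p": 2.5}, lobing=0.25, n_lobes=9,
                                     n_points=512, seed=8)
        xy = resample_outline(outlines[0][1], 512)
        ef = efa_transform(xy, 20)

        def max_err(h):
            rec = efa_reconstruct(ef, 512, n_harmonics=h)
            from scipy.spatial.distance import cdist
            d = cdist(rec, xy)
            return max(d.min(axis=0).max(), d.min(axis=1).max())

        assert max_err(15) <= max_err(5)

    def test_round_trip_preserves_normalized_shape(self):
        """Synthesis at uniform parameter, re-analysed in the same
        parameterization, returns the identical normalized coefficients."""
        outlines = gen_leaf_outlines(1, {"p": 2.0}, lobing=0.1, seed=9)
        ef = efa_transform(outlines[0][1], 12)
        rec = efa_reconstruct(ef, 512, normalized=True)
        ef2 = efa_transform(rec, 12, parameterization="uniform")
        assert np.allclose(ef.coeffs, ef2.coeffs, atol=1e-4)


class TestGPA:
    def test_similarity_transforms_are_removed(self):
        configs = gen_flower_landmarks(2, ["a"], seed=10)
        base = configs[0][1]
        th = np.radians(37.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        copy = 3.0 * base @ rot.T + np.array([4.0, -1.0])
        aligned, _ = gpa_align([base, copy, configs[1][1]])
        assert np.abs(aligned[0] - aligned[1]).max() < 1e-8

    def test_right_triangles_have_zero_procrustes_distance(self):
        """(0,0)(1,0)(0,1) and (0,0)(0,2)(-2,0) are similar triangles:
        rotation by 90 degrees and scale 2, so the distance is zero."""
        t1 = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        t2 = np.array([[0.0, 0.0], [0.0, 2.0], [-2.0, 0.0]])
        assert procrustes_distance(t1, t2) == pytest.approx(0.0, abs=1e-12)

    def test_distance_matches_closed_form_single_pair(self):
        """Closed-form 2-D Procrustes: d^2 = 2(1 - |<z1, z2>|) for unit
        complex configuration vectors."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))

        def unit_complex(c):
            z = (c[:, 0] - c[:, 0].mean()) + 1j * (c[:, 1] - c[:, 1].mean())
            return z / np.sqrt(np.sum(np.abs(z) ** 2))

        z1, z2 = unit_complex(a), unit_complex(b)
        d_closed = np.sqrt(max(2 * (1 - np.abs(np.vdot(z1, z2))), 0.0))
        # partial Procrustes (no reflection): same value when the optimal
        # rotation has positive determinant
        assert procrustes_distance(a, b) == pytest.approx(d_closed, abs=1e-8)

    def test_consensus_of_two_is_their_aligned_average(self):
        configs = gen_flower_landmarks(2, ["a"], landmark_noise=0.3, seed=11)
        aligned, consensus = gpa_align([configs[0][1], configs[1][1]])
        avg = (aligned[0] + aligned[1]) / 2
        avg = avg / np.sqrt((avg ** 2).sum())
        assert np.allclose(consensus, avg, atol=1e-8)

    def test_result_invariant_to_input_order(self):
        configs = [c for _, c in gen_flower_landmarks(4, ["a"], seed=12)]
        a1, c1 = gpa_align(configs)
        a2, c2 = gpa_align(configs[::-1])
        assert np.allclose(c1, c2, atol=1e-8)
        assert np.allclose(a1[0], a2[-1], atol=1e-8)

    def test_zero_size_configuration_rejected(self):
        with pytest.raises(ValueError):
            gpa_align([np.zeros((37, 2)), np.ones((37, 2))])


class TestShapePCA:
    def test_identical_shapes_have_zero_scores(self):
        rows = np.tile(np.arange(8.0), (5, 1))
        scores, _, pct = shape_pca(rows, 2)
        assert np.allclose(scores, 0.0)

    def test_two_distinct_shapes_need_one_axis(self, caplog):
        rows = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        scores, load, pct = shape_pca(rows, 3)
        assert scores.shape[1] == 1
        assert pct[0] == pytest.approx(100.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(13)
        rows = rng.normal(size=(5, 4))
        xc = rows - rows.mean(0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T))
        order = np.argsort(evals)[::-1]
        scores, load, _ = shape_pca(rows, 3)
        for j in range(3):
            ref = xc @ evecs[:, order[j]]
            assert np.allclose(np.abs(scores[:, j]), np.abs(ref), atol=1e-8)


class TestScalars:
    def test_unit_square_area(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert leaf_area(sq) == pytest.approx(1.0)
        assert leaf_area(sq, scale=2.0) == pytest.approx(4.0)

    def test_circle_area_converges_to_pi(self):
        circ = ellipse(1, 1, 256)
        assert abs(leaf_area(circ) - np.pi) / np.pi < 1e-3

    def test_petal_length_from_tips(self):
        config = np.zeros((37, 2))
        config[1] = [5.0, 0.0]
        config[2] = [0.0, 5.0]
        config[3] = [-5.0, 0.0]
        config[4] = [0.0, -5.0]
        assert petal_length(config) == pytest.approx(5.0)
        assert petal_length(config, scale=2.0) == pytest.approx(10.0)
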