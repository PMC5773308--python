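"""GAMOVA, Mantel, trait-climate regression and the scenario classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divsel.datatypes import DistMatrix, PopulationMap
from divsel.inference import (classify_scenario, gamova, geo_distance_matrix,
                              mantel, trait_env_regression)


def dist(labels, values, kind="phi_pt"):
    return DistMatrix(labels=list(labels), values=np.asarray(values, float),
                      kind=kind)


class TestGeoDistance:
    def test_quarter_circumference(self):
        pm = PopulationMap(pd.DataFrame({
            "population_id": ["a", "b"], "latitude": [0.0, 0.0],
            "longitude": [0.0, 90.0], "n_individuals": [5, 5]}))
        d = geo_distance_matrix(pm)
        assert d.values[0, 1] == pytest.approx(10_007.5, abs=1.0)

    def test_coincident_points_and_symmetry(self):
        pm = PopulationMap(pd.DataFrame({
            "population_id": ["a", "b", "c"],
            "latitude": [33.5, 33.5, 34.0],
            "longitude": [9.0, 9.0, 10.0], "n_individuals": [5, 5, 5]}))
        d = geo_distance_matrix(pm)
        assert d.values[0, 1] == 0.0
        assert np.array_equal(d.values, d.values.T)


class TestGamova:
    def test_equals_classical_regression_f_on_euclidean_distances(self):
        """On |y_i - y_j| distances the pseudo-F is the OLS F of y on x."""
        rng = np.random.default_rng(6)
        for trial in range(3):
            y = rng.normal(size=6)
            x = rng.normal(size=6)
            labels = [f"p{i}" for i in range(6)]
            d = dist(labels, np.abs(y[:, None] - y[None, :]))
            res = gamova(d, dict(zip(labels, x)), n_perm=9, seed=0)
            # classical F from the normal equations
            xc = x - x.mean()
            yc = y - y.mean()
            beta = (xc @ yc) / (xc @ xc)
            ss_model = beta ** 2 * (xc @ xc)
            ss_res = ((yc - beta * xc) ** 2).sum()
            f_classical = ss_model / (ss_res / (6 - 2))
            assert res.pseudo_f == pytest.approx(f_classical, abs=1e-8)

    def test_null_rejection_rate_calibrated(self):
        """Independent noise traits reject at ~alpha."""
        rng = np.random.default_rng(7)
        labels = [f"p{i}" for i in range(8)]
        y = rng.normal(size=8)
        d = dist(labels, np.abs(y[:, None] - y[None, :]))
        rejections = 0
        runs = 500
        for r in range(runs):
            x = rng.normal(size=8)
            res = gamova(d, dict(zip(labels, x)), n_perm=199, seed=r)
            rejections += res.p_value <= 0.05
        assert abs(rejections / runs - 0.05) < 0.02

    def test_constant_trait_and_tiny_designs_rejected(self):
        labels = list("abcd")
        d = dist(labels, 1 - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            gamova(d, dict.fromkeys(labels, 1.0), n_perm=9)
        d3 = dist(list("abc"), 1 - np.eye(3))
        with pytest.raises(ValueError, match="4 populations"):
            gamova(d3, {"a": 1.0, "b": 2.0, "c": 3.0}, n_perm=9)

    def test_negative_pseudo_f_possible_on_non_euclidean_matrix(self):
        # a matrix violating the triangle inequality strongly enough to give
        # a negative residual/model trace split for a poorly aligned trait
        labels = list("abcde")
        v = np.array([
            [0, 5.0, 0.1, 0.1, 0.1],
            [5.0, 0, 0.1, 0.1, 0.1],
            [0.1, 0.1, 0, 0.1, 0.1],
            [0.1, 0.1, 0.1, 0, 0.1],
            [0.1, 0.1, 0.1, 0.1, 0]])
        d = dist(labels, v)
        res = gamova(d, {"a": 0.1, "b": 0.2, "c": 5.0, "d": -3.0, "e": 2.0},
                     n_perm=99, seed=1)
        assert res.pseudo_f < 0
        assert res.p_value > 0.5


def brute_force_mantel(m1, m2, alternative="greater"):
    """Exhaustive relabeling oracle, written independently."""
    n = m1.shape[0]
    idx = np.tril_indices(n, k=-1)
    r_obs = np.corrcoef(m1[idx], m2[idx])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(m1[idx], m2[p[:, None], p[None, :]][idx])[0, 1]
        total += 1
        if alternative == "greater":
            count += r >= r_obs
        else:
            count += abs(r) >= abs(r_obs)
    return r_obs, count / total


class TestMantel:
    def test_matrix_against_itself_and_affine_image(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=5)
        v = np.abs(y[:, None] - y[None, :])
        d1 = dist(list("abcde"), v)
        d2 = dist(list("abcde"), 3.0 * v + 7.0 * (1 - np.eye(5)))
        assert mantel(d1, d1, n_perm=99, seed=0).r == pytest.approx(1.0)
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_p_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.random((4, 4))
        b = rng.random((4, 4))
        m1 = (a + a.T) / 2
        m2 = (b + b.T) / 2
        np.fill_diagonal(m1, 0)
        np.fill_diagonal(m2, 0)
        labels = list("abcd")
        res = mantel(dist(labels, m1), dist(labels, m2), exhaustive=True)
        r_ref, p_ref = brute_force_mantel(m1, m2)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_sampler_converges_to_exhaustive_p(self):
        rng = np.random.default_rng(10)
        a = rng.random((4, 4))
        b = rng.random((4, 4))
        m1, m2 = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(m1, 0)
        np.fill_diagonal(m2, 0)
        labels = list("abcd")
        _, p_ref = brute_force_mantel(m1, m2)
        res = mantel(dist(labels, m1), dist(labels, m2), n_perm=9_999, seed=3)
        assert abs(res.p_value - p_ref) < 0.02

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        y = rng.normal(size=6)
        z = y + 0.3 * rng.normal(size=6)
        m1 = np.abs(y[:, None] - y[None, :])
        m2 = np.abs(z[:, None] - z[None, :])
        labels = [f"p{i}" for i in range(6)]
        ours = mantel(dist(labels, m1), dist(labels, m2), n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(m1), skbio.DistanceMatrix(m2),
            permutations=999, alternative="greater")
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(ours.p_value - p_ref) < 0.05

    def test_constant_triangle_rejected(self):
        d1 = dist(list("abc"), 1 - np.eye(3))
        with pytest.raises(ValueError, match="constant"):
            mantel(d1, d1, n_perm=9)


class TestTraitEnvRegression:
    def test_collinear_points_have_unit_r2(self):
        tm = {"a": 1.0, "b": 2.0, "c": 3.0}
        env = {"a": 10.0, "b": 20.0, "c": 30.0}
        slope, icept, r2 = trait_env_regression(tm, env)
        assert slope == pytest.approx(0.1)
        assert r2 == pytest.approx(1.0)

    def test_five_point_normal_equations_oracle(self):
        x = np.array([100.0, 130.0, 155.0, 180.0, 200.0])
        y = np.array([0.21, 0.05, -0.02, -0.11, -0.19])
        pops = list("abcde")
        slope, icept, r2 = trait_env_regression(dict(zip(pops, y)),
                                                dict(zip(pops, x)))
        xc = x - x.mean()
        b = (xc @ (y - y.mean())) / (xc @ xc)
        a = y.mean() - b * x.mean()
        resid = y - (a + b * x)
        r2_ref = 1 - (resid @ resid) / (((y - y.mean()) ** 2).sum())
        assert slope == pytest.approx(b, abs=1e-12)
        assert icept == pytest.approx(a, abs=1e-12)
        assert r2 == pytest.approx(r2_ref, abs=1e-12)

    def test_drop_list_and_minimum_points(self):
        tm = dict(zip("abcd", [1.0, 2.0, 3.0, -5.0]))
        env = dict(zip("abcd", [1.0, 2.0, 3.0, 4.0]))
        _, _, r2_full = trait_env_regression(tm, env)
        _, _, r2_drop = trait_env_regression(tm, env, drop=["d"])
        assert r2_drop > r2_full
        with pytest.raises(ValueError):
            trait_env_regression(tm, env, drop=["c", "d"])


class TestScenarioClassifier:
    @pytest.mark.parametrize("flags,expected", [
        ((True, False, True, True), "1.1"),
        ((True, False, True, False), "1.1"),
        ((True, False, False, True), "1.2"),
        ((True, True, True, True), "2"),
        ((True, True, False, False), "2"),
        ((False, True, False, True), "3.1"),
        ((False, True, True, False), "3.2"),
        ((False, False, False, False), "no_signal"),
    ])
    def test_decision_table(self, flags, expected):
        call = classify_scenario(*flags)
        assert call.scenario == expected

    def test_total_deterministic_function(self):
        seen = set()
        for flags in itertools.product([True, False], repeat=4):
            call = classify_scenario(*flags)
            assert call.scenario in {"1.1", "1.2", "2", "3.1", "3.2",
                                     "no_signal"}
            assert call.interpretation
            again = classify_scenario(*flags)
            assert again.scenario == call.scenario
            seen.add((flags, call.scenario))
        assert len(seen) == 16
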