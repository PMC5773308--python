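"""Dominant-marker statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import integrate

from divsel.datatypes import MarkerMatrix
from divsel.popgen import (bray_curtis_matrix, bray_curtis_pcoa,
                           compute_locus_stats, estimate_band_allele_freq,
                           locus_fst_he, pairwise_phi_pt, phi_pt,
                           replicate_error_rate)
from divsel.simulate import gen_aflp


def quad_posterior_mean(m, n, a=1.0, b=1.0):
    """Independent quadrature oracle for the band-absence frequency."""
    def post(q):
        return q ** (a - 1) * (1 - q) ** (b - 1) * (q * q) ** m * (1 - q * q) ** (n - m)
    z, _ = integrate.quad(post, 0, 1, epsabs=0, epsrel=1e-12, limit=300)
    num, _ = integrate.quad(lambda q: q * post(q), 0, 1,
                            epsabs=0, epsrel=1e-12, limit=300)
    return num / z


class TestBandFrequency:
    @pytest.mark.parametrize("m,n", [(5, 10), (0, 10), (10, 10), (50, 50),
                                     (3, 17), (0, 1)])
    def test_matches_quadrature_oracle(self, m, n):
        assert estimate_band_allele_freq(m, n) == pytest.approx(
            quad_posterior_mean(m, n), abs=1e-6)

    def test_posterior_equals_prior_without_data(self):
        assert estimate_band_allele_freq(0, 0) == pytest.approx(0.5)
        assert estimate_band_allele_freq(0, 0, prior=(2.0, 6.0)) == \
            pytest.approx(0.25)

    def test_all_absent_stays_inside_unit_interval(self):
        q = estimate_band_allele_freq(50, 50)
        assert 0.95 < q < 1.0
        assert q == pytest.approx(quad_posterior_mean(50, 50), abs=1e-6)

    def test_beta_prior_shifts_estimate(self):
        flat = estimate_band_allele_freq(5, 10)
        skewed = estimate_band_allele_freq(5, 10, prior=(1.0, 5.0))
        assert skewed < flat
        assert skewed == pytest.approx(quad_posterior_mean(5, 10, 1, 5),
                                       abs=1e-6)


class TestEmpiricalPrior:
    def test_moments_match_observed_distribution(self, neutral_matrix):
        from divsel.popgen import band_freq_from_counts, fit_empirical_prior
        matrix, _ = neutral_matrix
        a, b = fit_empirical_prior(matrix)
        assert a > 0 and b > 0
        q = band_freq_from_counts((matrix.bands == 0).sum(axis=0),
                                  matrix.n_individuals)
        assert a / (a + b) == pytest.approx(q.mean(), abs=1e-9)

    def test_prior_pulls_estimates_toward_its_mean(self):
        # skewed prior favouring low q: estimates drop relative to uniform
        flat = estimate_band_allele_freq(5, 10, prior=(1.0, 1.0))
        low = estimate_band_allele_freq(5, 10, prior=(2.0, 8.0))
        assert low < flat


class TestLocusFst:
    def test_no_differentiation_is_exactly_zero(self):
        fst, he = locus_fst_he(np.array([0.3, 0.3, 0.3]), np.array([20, 20, 20]))
        assert fst == 0.0
        assert he == pytest.approx(2 * 0.3 * 0.7)

    def test_fixation_reaches_one(self):
        fst, _ = locus_fst_he(np.array([0.0, 1.0]), np.array([1000, 1000]))
        assert fst == pytest.approx(1.0)

    def test_three_population_variance_components_oracle(self):
        p = np.array([0.2, 0.4, 0.6])
        w = np.array([20.0, 20.0, 20.0])
        # independent evaluation of the variance-ratio definition
        wn = w / w.sum()
        pbar = wn @ p
        s2 = (wn @ (p - pbar) ** 2) * 3 / 2
        expected = s2 / (pbar * (1 - pbar) + s2 / 3)
        fst, he = locus_fst_he(p, w)
        assert fst == pytest.approx(expected, abs=1e-12)
        assert he == pytest.approx(2 * pbar * (1 - pbar))

    def test_oracle_grid_of_rational_frequencies(self):
        for p in itertools.combinations([0.1, 0.25, 0.5, 0.75, 0.9], 3):
            p = np.array(p)
            w = np.full(3, 15.0)
            pbar = p.mean()
            s2 = ((p - pbar) ** 2).mean() * 1.5
            expected = s2 / (pbar * (1 - pbar) + s2 / 3)
            assert locus_fst_he(p, w)[0] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_locus_is_undefined(self):
        fst, _ = locus_fst_he(np.array([0.0, 0.0]), np.array([10, 10]))
        assert np.isnan(fst)


def brute_force_phi(bands, groups):
    """Independent AMOVA oracle: explicit sums of squares over pairs."""
    n = bands.shape[0]
    d2 = np.array([[np.sum((bands[i] - bands[j]) ** 2) for j in range(n)]
                   for i in range(n)], dtype=float)
    labels = sorted(set(groups))
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    sizes = []
    for g in labels:
        rows = [i for i in range(n) if groups[i] == g]
        sizes.append(len(rows))
        ss_within += sum(d2[i, j] for i in rows for j in rows if i < j) / len(rows)
    k = len(labels)
    ms_a = (ss_total - ss_within) / (k - 1)
    ms_w = ss_within / (n - k)
    n0 = (n - sum(s * s for s in sizes) / n) / (k - 1)
    va = (ms_a - ms_w) / n0
    if va + ms_w <= 0:
        return 0.0
    return va / (va + ms_w)


class TestPhiPT:
    def test_toy_matrix_matches_brute_force_oracle(self, toy_matrix):
        groups = [toy_matrix.pop_of[i] for i in toy_matrix.individual_ids]
        expected = brute_force_phi(toy_matrix.bands.astype(float), groups)
        phi, _ = phi_pt(toy_matrix)
        assert phi == pytest.approx(expected, abs=1e-12)

    def test_permutation_p_converges_to_exhaustive(self, toy_matrix):
        """All 20 balanced 3|3 splits enumerate the exact permutation null."""
        bands = toy_matrix.bands.astype(float)
        groups = [toy_matrix.pop_of[i] for i in toy_matrix.individual_ids]
        phi_obs = brute_force_phi(bands, groups)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            g = ["A" if i in combo else "B" for i in range(6)]
            total += 1
            if brute_force_phi(bands, g) >= phi_obs - 1e-12:
                count += 1
        p_exact = count / total
        _, p_perm = phi_pt(toy_matrix, n_perm=4999, seed=11)
        assert abs(p_perm - p_exact) < 0.05

    def test_identical_populations_give_phi_one_when_fixed(self):
        bands = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
        ids = list("wxyz")
        m = MarkerMatrix(ids, ["l1", "l2"], bands,
                         {"w": "A", "x": "A", "y": "B", "z": "B"})
        phi, _ = phi_pt(m)
        assert phi == pytest.approx(1.0)

    def test_all_identical_individuals_degenerate_to_zero(self):
        bands = np.ones((4, 3), dtype=np.int8)
        ids = list("wxyz")
        m = MarkerMatrix(ids, ["a", "b", "c"], bands,
                         {"w": "A", "x": "A", "y": "B", "z": "B"})
        with pytest.warns(UserWarning, match="identical"):
            phi, _ = phi_pt(m)
        assert phi == 0.0

    def test_singleton_population_is_an_error(self):
        bands = np.zeros((3, 2), dtype=np.int8)
        m = MarkerMatrix(["a", "b", "c"], ["l1", "l2"], bands,
                         {"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError, match="B"):
            phi_pt(m)

    def test_pairwise_matrix_shape_and_order_invariance(self, toy_matrix, meta12):
        matrix, _ = gen_aflp(meta12, n_neutral=40, n_selected=0, n_ind=5,
                             fst_background=0.05, n_replicates=0, seed=9)
        dm = pairwise_phi_pt(matrix)
        k = len(matrix.populations)
        assert dm.values.shape == (k, k)
        assert np.allclose(dm.values, dm.values.T, atol=1e-12)
        # shuffle individuals and loci; Phi_PT must not change
        rng = np.random.default_rng(0)
        iorder = rng.permutation(matrix.n_individuals)
        lorder = rng.permutation(matrix.n_loci)
        shuffled = MarkerMatrix(
            [matrix.individual_ids[i] for i in iorder],
            [matrix.locus_ids[j] for j in lorder],
            matrix.bands[np.ix_(iorder, lorder)],
            matrix.pop_of)
        dm2 = pairwise_phi_pt(shuffled).reorder(dm.labels)
        assert np.allclose(dm.values, dm2.values, atol=1e-12)


class TestBrayCurtisPcoa:
    def test_hand_formula_for_single_pair(self):
        bands = np.array([[1, 1, 0], [0, 1, 1]], dtype=np.int8)
        bc = bray_curtis_matrix(bands)
        assert bc[0, 1] == pytest.approx(1 - 2 * 1 / (2 + 2))

    def test_identical_individuals_have_zero_coordinates(self):
        bands = np.tile(np.array([1, 0, 1, 1], dtype=np.int8), (4, 1))
        ids = list("abcd")
        m = MarkerMatrix(ids, ["l1", "l2", "l3", "l4"], bands,
                         {i: "A" for i in ids})
        coords, evals, _ = bray_curtis_pcoa(m)
        assert np.allclose(coords, 0.0, atol=1e-9)

    def test_equidistant_triple_gives_two_equal_eigenvalues(self):
        bands = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
        ids = list("abc")
        m = MarkerMatrix(ids, ["l1", "l2", "l3"], bands, {i: "A" for i in ids})
        _, evals, pct = bray_curtis_pcoa(m)
        pos = evals[evals > 1e-12]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1])
        assert pct[:2].sum() == pytest.approx(100.0)

    def test_matches_skbio_ordination(self, toy_matrix):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(toy_matrix.bands.astype(float), "braycurtis"))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        coords, evals, _ = bray_curtis_pcoa(toy_matrix, n_axes=2)
        ref_e = np.sort(ref.eigvals.to_numpy())[::-1]
        assert np.allclose(np.sort(evals)[::-1][:3], ref_e[:3], atol=1e-8)
        assert np.allclose(np.abs(coords[:, 0]),
                           np.abs(ref.samples.iloc[:, 0].to_numpy()), atol=1e-8)


class TestReplicateError:
    def test_direct_mismatch_count(self):
        bands = np.zeros((2, 100), dtype=np.int8)
        bands[1, :9] = 1
        m = MarkerMatrix(["a", "a_rep"], [f"L{i}" for i in range(100)], bands,
                         {"a": "A", "a_rep": "A"},
                         replicate_pairs=[("a", "a_rep")])
        assert replicate_error_rate(m) == pytest.approx(0.09)

    def test_identical_pair_is_zero_and_no_pairs_errors(self):
        bands = np.zeros((2, 10), dtype=np.int8)
        m = MarkerMatrix(["a", "b"], [f"L{i}" for i in range(10)], bands,
                         {"a": "A", "b": "A"}, replicate_pairs=[("a", "b")])
        assert replicate_error_rate(m) == 0.0
        m.replicate_pairs = []
        with pytest.raises(ValueError):
            replicate_error_rate(m)

    def test_generator_rate_recovered_within_binomial_ci(self, meta12):
        matrix, _ = gen_aflp(meta12, n_neutral=732, n_selected=0,
                             fst_background=0.02, error_rate=0.09,
                             n_replicates=24, seed=5)
        rate = replicate_error_rate(matrix)
        n_eff = 732 * 24
        se = np.sqrt(0.09 * 0.91 / n_eff)
        assert abs(rate - 0.09) < 4 * se


class TestRealizedFst:
    def test_neutral_background_recovered(self, neutral_matrix):
        """Mean estimated F_ST over 700 neutral loci tracks the target."""
        matrix, truth = neutral_matrix
        stats = compute_locus_stats(matrix)
        assert abs(np.nanmean(stats.table["fst"]) - truth.fst_background) < 0.005

    def test_phi_pt_monotone_in_background_fst(self, meta12):
        means = []
        for f in (0.01, 0.05, 0.2):
            matrix, _ = gen_aflp(meta12, n_neutral=500, n_selected=0, n_ind=8,
                                 fst_background=f, n_replicates=0, ibd=False,
                                 seed=21)
            dm = pairwise_phi_pt(matrix)
            means.append(dm.lower_triangle().mean())
        assert means[0] < means[1] < means[2]
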