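"""Allele-frequency and differentiation statistics for dominant 0/1 markers.

Dominant fingerprints (AFLP-like) observe only band presence (genotypes AA
or Aa) versus absence (aa); allele frequencies must be inferred, not counted.
Under Hardy-Weinberg, the count ``m`` of band-absent individuals among ``n``
is Binomial(n, q^2) in the band-absence allele frequency q.  We estimate q by
its Bayesian posterior mean under a Beta prior (Zhivotovsky-style), and build
locus-wise F_ST from the among-population variance of the estimated
band-presence frequencies p = 1 - q, with a correction for the sampling
variance of the estimator itself.

Population differentiation on the raw band phenotypes uses AMOVA variance
components from pairwise squared Euclidean distances (Phi_PT), which requires
no allele-frequency inference and tolerates departure from Hardy-Weinberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gammaln

from .datatypes import MISSING, DistMatrix, MarkerMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Band-absence allele frequency (Zhivotovsky posterior mean)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def estimate_band_allele_freq(m_absent: int, n: int,
                              prior: tuple[float, float] = (1.0, 1.0)) -> float:
    """Posterior mean of the band-absence allele frequency q.

    Likelihood is ``(q^2)^m (1-q^2)^(n-m)`` for ``m`` band-absent individuals
    among ``n`` (dominant marker, Hardy-Weinberg); the prior on q is
    Beta(a, b), uniform by default.  Computed by adaptive quadrature; the
    estimate is strictly inside (0, 1).

    Returns q-hat; the band-presence frequency is ``p = 1 - q``.
    """
    if not (0 <= m_absent <= n):
        raise ValueError(f"need 0 <= m_absent <= n, got m={m_absent}, n={n}")
    a, b = prior
    if n == 0:
        if a <= 0 or b <= 0:
            raise ValueError("n = 0 requires a proper Beta prior")
        return a / (a + b)

    # log-space integrand for numerical stability at large n
    def logpost(q: float) -> float:
        if q <= 0.0 or q >= 1.0:
            return -np.inf
        return (2 * m_absent + a - 1) * np.log(q) + (b - 1) * np.log1p(-q) \
            + (n - m_absent) * np.log1p(-q * q)

    # normalize at the mode to avoid under/overflow
    qs = np.linspace(1e-6, 1 - 1e-6, 512)
    ref = max(logpost(q) for q in qs)

    def dens(q: float) -> float:
        return np.exp(logpost(q) - ref)

    z, _ = integrate.quad(dens, 0.0, 1.0, epsabs=0.0, epsrel=1e-10, limit=200)
    num, _ = integrate.quad(lambda q: q * dens(q), 0.0, 1.0,
                            epsabs=0.0, epsrel=1e-10, limit=200)
    return float(num / z)


@lru_cache(maxsize=512)
def _qhat_table(n: int, prior: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """q-hat for every possible absence count m = 0..n at sample size n."""
    return np.array([estimate_band_allele_freq(m, n, prior) for m in range(n + 1)])


def band_freq_from_counts(m_absent: np.ndarray, n: int,
                          prior: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Vectorized q-hat lookup for an array of absence counts at fixed n."""
    return _qhat_table(n, prior)[np.asarray(m_absent, dtype=int)]


def fit_empirical_prior(matrix: MarkerMatrix) -> tuple[float, float]:
    """Beta prior fitted by moments to the across-loci q distribution.

    First-pass band-absence frequencies are estimated per locus under the
    uniform prior (pooled over individuals), then a Beta(a, b) is matched to
    their mean and variance.  Using the result as the estimation prior
    borrows strength across loci; the uniform default remains the
    conservative choice.
    """
    if np.any(matrix.bands == MISSING):
        raise ValueError("missing band scores present; resolve them first")
    n = matrix.n_individuals
    m_absent = (matrix.bands == 0).sum(axis=0)
    q = band_freq_from_counts(m_absent, n)
    mean, var = float(q.mean()), float(q.var())
    cap = mean * (1.0 - mean)
    if var <= 0 or var >= cap:
        return 1.0, 1.0
    conc = cap / var - 1.0
    return mean * conc, (1.0 - mean) * conc


@lru_cache(maxsize=256)
def _estimator_curves(n: int, prior: tuple[float, float] = (1.0, 1.0),
                      ngrid: int = 2001):
    """Exact sampling curves of the q estimator at sample size n.

    Returns (q grid, E[q-hat | q], Var[q-hat | q], d/dq E[q-hat | q]) with
    m ~ Binomial(n, q^2), evaluated by summing over all n+1 outcomes.  The
    variance is the noise the estimator adds to the among-population spread;
    the derivative is the attenuation slope of the Bayesian shrinkage (the
    posterior mean compresses extreme frequencies toward the prior mean,
    deflating the among-population variance by roughly the squared slope).
    Both enter the F_ST correction, evaluated at the de-shrunk locus-mean
    frequency.
    """
    table = _qhat_table(n, prior)
    grid = np.linspace(1e-4, 1.0 - 1e-4, ngrid)
    m = np.arange(n + 1)
    logc = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    q2 = grid * grid
    logpmf = logc[:, None] + m[:, None] * np.log(q2)[None, :] \
        + (n - m)[:, None] * np.log1p(-q2)[None, :]
    pmf = np.exp(logpmf)
    gmean = pmf.T @ table
    var = np.maximum(pmf.T @ (table * table) - gmean ** 2, 0.0)
    # d(pmf)/dq = pmf * (2m/q - 2q(n-m)/(1-q^2))
    fac = 2.0 * m[:, None] / grid[None, :] \
        - 2.0 * grid[None, :] * (n - m)[:, None] / (1.0 - q2)[None, :]
    dmean = (pmf * fac).T @ table
    return grid, gmean, var, dmean


def _center_corrections(qbar: np.ndarray, n: int,
                        prior: tuple[float, float] = (1.0, 1.0)
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sampling variance and attenuation slope at the de-shrunk center.

    ``qbar`` is the across-population mean of estimated band-absence
    frequencies for each locus; it is mapped back through the estimator's
    expectation curve to the underlying frequency before the exact moments
    are read off, which keeps the correction stable where shrinkage is
    strong.
    """
    grid, gmean, var, dmean = _estimator_curves(n, prior)
    q0 = np.interp(qbar, gmean, grid)
    return np.interp(q0, grid, var), np.interp(q0, grid, dmean)


# ---------------------------------------------------------------------------
# Locus-wise F_ST and expected heterozygosity
# ---------------------------------------------------------------------------

def locus_fst_he(freqs: np.ndarray, weights: np.ndarray,
                 sampling_var: np.ndarray | None = None,
                 attenuation: np.ndarray | None = None) -> tuple[float, float]:
    """F_ST and expected heterozygosity from per-population frequencies.

    ``freqs`` are estimated band-presence frequencies p-hat_j, ``weights`` the
    per-population sample sizes.  F_ST is the sample-size-weighted
    among-population variance of p-hat (with a K/(K-1) small-sample factor),
    minus the mean sampling variance of the estimates if given, rescaled by
    the mean squared attenuation slope if given, divided by the total
    variance pbar(1-pbar) + s2/K.  A monomorphic locus (pbar(1-pbar) = 0)
    returns NaN; all frequencies identical returns exactly 0.
    """
    p = np.asarray(freqs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.size < 2:
        raise ValueError("need frequencies for at least two populations")
    w = w / w.sum()
    pbar = float(w @ p)
    he = 2.0 * pbar * (1.0 - pbar)
    denom = pbar * (1.0 - pbar)
    if denom <= 0.0:
        return np.nan, he
    if np.ptp(p) == 0.0:
        return 0.0, he
    k = p.size
    s2 = float(w @ (p - pbar) ** 2) * k / (k - 1)
    if sampling_var is not None:
        s2 -= float(w @ np.asarray(sampling_var, dtype=float))
    if attenuation is not None:
        a2 = float(w @ np.asarray(attenuation, dtype=float) ** 2)
        s2 /= max(a2, 1e-3)
    # total variance in the denominator includes the among-population share
    # (s2/K), so complete fixation (p = 0 vs 1) yields exactly 1
    return s2 / (denom + max(s2, 0.0) / k), he


@dataclass
class LocusStats:
    """Per-locus summaries assembled across pipeline stages."""

    table: pd.DataFrame  # index locus_id
    pop_freqs: pd.DataFrame  # loci x populations band-presence frequencies

    @property
    def locus_ids(self) -> list[str]:
        return self.table.index.tolist()


def compute_locus_stats(matrix: MarkerMatrix,
                        prior: tuple[float, float] = (1.0, 1.0),
                        correction: str = "dominant_exact") -> LocusStats:
    """Estimate per-population band frequencies plus F_ST/He for every locus.

    ``correction`` selects how estimator noise is removed before forming the
    frequency-variance ratio: ``dominant_exact`` (default) subtracts the
    exact sampling variance of the tabulated Bayesian estimator and rescales
    by its shrinkage-attenuation slope, ``binomial`` subtracts p(1-p)/(2n),
    ``none`` subtracts nothing.  Loci monomorphic in band phenotype get
    F_ST = NaN and are excluded from outlier scans downstream.
    """
    if np.any(matrix.bands == MISSING):
        raise ValueError("missing band scores present; apply a missing-data "
                         "policy before computing locus statistics")
    pops = matrix.populations
    idx = matrix.pop_indices()
    freqs = np.empty((matrix.n_loci, len(pops)))
    svars = np.zeros_like(freqs)
    atten = np.ones_like(freqs)
    sizes = np.array([idx[p].size for p in pops], dtype=float)
    for j, pop in enumerate(pops):
        sub = matrix.bands[idx[pop]]
        n = sub.shape[0]
        m_absent = (sub == 0).sum(axis=0)
        freqs[:, j] = 1.0 - band_freq_from_counts(m_absent, n, prior)
    w = sizes / sizes.sum()
    qbar = 1.0 - freqs @ w
    if correction == "dominant_exact":
        for j, pop in enumerate(pops):
            v0, a0 = _center_corrections(qbar, int(sizes[j]), prior)
            svars[:, j] = v0
            atten[:, j] = a0
    elif correction == "binomial":
        svars = freqs * (1.0 - freqs) / (2.0 * sizes[None, :])
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    fst = np.empty(matrix.n_loci)
    he = np.empty(matrix.n_loci)
    mono = set(matrix.zero_variance_loci())
    for i, locus in enumerate(matrix.locus_ids):
        if locus in mono:
            fst[i], he[i] = np.nan, np.nan
            continue
        fst[i], he[i] = locus_fst_he(freqs[i], sizes, svars[i], atten[i])
    table = pd.DataFrame({"fst": fst, "he": he}, index=pd.Index(matrix.locus_ids, name="locus"))
    pop_freqs = pd.DataFrame(freqs, index=table.index, columns=pops)
    return LocusStats(table=table, pop_freqs=pop_freqs)


# ---------------------------------------------------------------------------
# AMOVA Phi_PT on band phenotypes
# ---------------------------------------------------------------------------

def _squared_distances(bands: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between binary band rows."""
    x = bands.astype(float)
    s = x @ x.T
    n1 = np.diag(s)
    d2 = n1[:, None] + n1[None, :] - 2.0 * s
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_phi(d2: np.ndarray, groups: np.ndarray, k: int) -> float:
    """Phi_PT from a squared-distance matrix and integer group labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    sizes = np.zeros(k)
    for g in range(k):
        rows = np.flatnonzero(groups == g)
        sizes[g] = rows.size
        ss_within += d2[np.ix_(rows, rows)].sum() / (2.0 * rows.size)
    ss_among = ss_total - ss_within
    df_a, df_w = k - 1, n - k
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    n0 = (n - (sizes ** 2).sum() / n) / df_a
    var_a = (ms_a - ms_w) / n0
    var_w = ms_w
    tot = var_a + var_w
    if tot <= 0.0:
        return 0.0
    return var_a / tot


def phi_pt(matrix: MarkerMatrix, pops: list[str] | None = None,
           n_perm: int = 0, seed: int | None = None) -> tuple[float, float | None]:
    """AMOVA Phi_PT over the given populations, with optional permutation p.

    Variance components come from pairwise squared Euclidean distances
    between band phenotypes.  The p-value permutes individuals among
    populations: p = (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm).  Negative
    Phi estimates are retained.  Pass ``n_perm=0`` to skip the test.
    """
    if pops is not None:
        matrix = matrix.subset_pops(pops)
    sizes = matrix.pop_sizes()
    for p, s in sizes.items():
        if s < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    pop_list = matrix.populations
    pop_index = {p: g for g, p in enumerate(pop_list)}
    groups = np.array([pop_index[matrix.pop_of[i]] for i in matrix.individual_ids])
    d2 = _squared_distances(matrix.bands)
    if d2.sum() == 0.0:
        warnings.warn("all individuals identical; Phi_PT defined as 0")
        return 0.0, (1.0 if n_perm else None)
    phi_obs = _amova_phi(d2, groups, len(pop_list))
    if n_perm <= 0:
        return phi_obs, None
    rng = np.random.default_rng(seed)
    count = 0
    g = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(g)
        if _amova_phi(d2, g, len(pop_list)) >= phi_obs:
            count += 1
    return phi_obs, (1 + count) / (1 + n_perm)


def pairwise_phi_pt(matrix: MarkerMatrix, n_perm: int = 0,
                    seed: int | None = None) -> DistMatrix:
    """Phi_PT for every population pair, assembled into a symmetric matrix."""
    pops = matrix.populations
    k = len(pops)
    out = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            sub_seed = int(rng.integers(2 ** 31)) if n_perm else None
            phi, _ = phi_pt(matrix, [pops[a], pops[b]], n_perm=n_perm, seed=sub_seed)
            out[a, b] = out[b, a] = phi
    return DistMatrix(labels=pops, values=out, kind="phi_pt")


# ---------------------------------------------------------------------------
# Bray-Curtis PCoA and replicate error
# ---------------------------------------------------------------------------

def bray_curtis_matrix(bands: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between binary band rows.

    For 0/1 data BC = 1 - 2W/(A+B) with W the number of shared bands.  A pair
    of all-zero individuals has an undefined BC; it is defined as 0 here with
    a warning.
    """
    x = bands.astype(float)
    w = x @ x.T
    tot = x.sum(axis=1)
    denom = tot[:, None] + tot[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = 1.0 - 2.0 * w / denom
    if np.isnan(bc).any():
        warnings.warn("all-zero individuals present; their mutual Bray-Curtis "
                      "distance is defined as 0")
        bc = np.nan_to_num(bc, nan=0.0)
    np.fill_diagonal(bc, 0.0)
    return bc


def bray_curtis_pcoa(matrix: MarkerMatrix, n_axes: int = 2):
    """Classical scaling (PCoA) of Bray-Curtis distances among individuals.

    Returns (coordinates, eigenvalues, percent variance).  Negative
    eigenvalues are reported as-is (no correction); percent variance is
    relative to the sum of positive eigenvalues.
    """
    if matrix.n_individuals < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    d = bray_curtis_matrix(matrix.bands)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.maximum(evals, 0.0)
    coords = evecs[:, :n_axes] * np.sqrt(pos[:n_axes])[None, :]
    pct = np.where(evals > 0, 100.0 * evals / max(pos.sum(), 1e-300), 0.0)
    return coords, evals, pct


def replicate_error_rate(matrix: MarkerMatrix) -> float:
    """Mean per-pair fraction of mismatching loci over replicate pairs."""
    if not matrix.replicate_pairs:
        raise ValueError("no replicate pairs recorded in this matrix")
    pos = {ind: i for i, ind in enumerate(matrix.individual_ids)}
    rates = []
    for a, b in matrix.replicate_pairs:
        xa, xb = matrix.bands[pos[a]], matrix.bands[pos[b]]
        ok = (xa != MISSING) & (xb != MISSING)
        rates.append(float(np.mean(xa[ok] != xb[ok])))
    return float(np.mean(rates))
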