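"""Hierarchical Bayesian F-model for dominant markers (BayeScan-style).

Band-absence counts are m_jl ~ Binomial(n_j, (1 - p_jl)^2) where p_jl is the
band-presence allele frequency of locus l in population j (dominant marker,
Hardy-Weinberg).  Population frequencies are tied to an ancestral frequency
p_l through the Beta island model

    p_jl ~ Beta(theta_jl * p_l, theta_jl * (1 - p_l)),
    theta_jl = (1 - F_jl) / F_jl,
    logit(F_jl) = alpha_l * delta_l + beta_j,

so every locus-population pair has its own differentiation F_jl decomposed
into a population effect beta_j (shared demography) and a locus effect
alpha_l that is only active when the selection indicator delta_l is on.  The
posterior probability of selection for a locus is the posterior mean of
delta_l.

Sampling is Metropolis-within-Gibbs with elementwise random-walk proposals,
adapted during pilot runs to acceptance rates of 0.25-0.45.  The indicator
delta is flipped by a variable-selection move that uses per-locus
pseudo-priors for alpha fitted from the pilot runs (run with all deltas on),
an equivalent but simpler alternative to full reversible jump.  Priors:
alpha ~ N(0, 1.8), beta ~ N(-1, 1.8), p_l ~ Uniform(0, 1), prior odds
neutral:selected of 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .config import MCMCSchedule
from .datatypes import MISSING, MarkerMatrix

log = logging.getLogger(__name__)

_ALPHA_SD = 1.8
_BETA_MEAN, _BETA_SD = -1.0, 1.8
_F_CLIP = (1e-4, 1.0 - 1e-4)


@dataclass
class FModelResult:
    """Posterior summaries and chain diagnostics of the F-model fit."""

    table: pd.DataFrame  # index locus: posterior_prob, alpha_mean, fst_mean
    beta_mean: np.ndarray
    acceptance: dict[str, float]
    n_samples: int
    delta_samples: np.ndarray | None = None


class _State:
    def __init__(self, m: np.ndarray, n: np.ndarray, rng: np.random.Generator):
        self.m = m  # (K, L) absence counts
        self.n = n  # (K,) sample sizes
        K, L = m.shape
        self.rng = rng
        with np.errstate(divide="ignore"):
            p_obs = 1.0 - np.sqrt((m + 0.5) / (n[:, None] + 1.0))
        self.p_pop = np.clip(p_obs, 0.02, 0.98)
        self.p_anc = np.clip(self.p_pop.mean(axis=0), 0.05, 0.95)
        self.alpha = np.zeros(L)
        self.beta = np.full(K, logit(0.05))
        self.delta = np.zeros(L, dtype=bool)
        # proposal scales (log-space random walks)
        self.s_pop = np.full((K, L), 0.8)
        self.s_anc = np.full(L, 0.4)
        self.s_alpha = np.full(L, 0.6)
        self.s_beta = np.full(K, 0.15)
        self.acc = {k: [0, 0] for k in ("p_pop", "p_anc", "alpha", "beta", "delta")}

    # -- likelihood pieces -------------------------------------------------
    def loglik_data(self, p_pop: np.ndarray) -> np.ndarray:
        q = 1.0 - p_pop
        return 2.0 * self.m * np.log(q) + \
            (self.n[:, None] - self.m) * np.log1p(-q * q)

    def theta(self, delta=None, alpha=None, beta=None) -> np.ndarray:
        d = self.delta if delta is None else delta
        a = self.alpha if alpha is None else alpha
        b = self.beta if beta is None else beta
        f = expit(a[None, :] * d[None, :] + b[:, None])
        f = np.clip(f, *_F_CLIP)
        return (1.0 - f) / f

    def log_beta_prior(self, p_pop: np.ndarray, theta: np.ndarray,
                       p_anc: np.ndarray, normalized: bool = True) -> np.ndarray:
        a = theta * p_anc[None, :]
        b = theta * (1.0 - p_anc[None, :])
        out = (a - 1.0) * np.log(p_pop) + (b - 1.0) * np.log1p(-p_pop)
        if normalized:
            out = out - betaln(a, b)
        return out


def _logit_rw(x: np.ndarray, scale: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random walk on logit scale; returns (proposal, log Jacobian ratio)."""
    z = logit(np.clip(x, 1e-9, 1 - 1e-9))
    znew = z + scale * rng.standard_normal(z.shape)
    xnew = expit(znew)
    xnew = np.clip(xnew, 1e-9, 1 - 1e-9)
    jac = np.log(xnew) + np.log1p(-xnew) - np.log(x) - np.log1p(-x)
    return xnew, jac


def _sweep(st: _State, pseudo_mean: np.ndarray, pseudo_sd: np.ndarray,
           prior_odds: float, update_delta: bool) -> None:
    rng = st.rng
    K, L = st.m.shape
    theta_cur = st.theta()

    # population-locus frequencies
    prop, jac = _logit_rw(st.p_pop, st.s_pop, rng)
    delta_ll = st.loglik_data(prop) - st.loglik_data(st.p_pop) \
        + st.log_beta_prior(prop, theta_cur, st.p_anc, normalized=False) \
        - st.log_beta_prior(st.p_pop, theta_cur, st.p_anc, normalized=False) \
        + jac
    accept = np.log(rng.random((K, L))) < delta_ll
    st.p_pop = np.where(accept, prop, st.p_pop)
    st.acc["p_pop"][0] += int(accept.sum())
    st.acc["p_pop"][1] += accept.size

    # ancestral frequencies (uniform prior; normalization terms matter)
    prop_anc, jac = _logit_rw(st.p_anc, st.s_anc, rng)
    ll_new = st.log_beta_prior(st.p_pop, theta_cur, prop_anc).sum(axis=0)
    ll_old = st.log_beta_prior(st.p_pop, theta_cur, st.p_anc).sum(axis=0)
    accept = np.log(rng.random(L)) < ll_new - ll_old + jac
    st.p_anc = np.where(accept, prop_anc, st.p_anc)
    st.acc["p_anc"][0] += int(accept.sum())
    st.acc["p_anc"][1] += accept.size

    # locus effects: random walk where delta is on, pseudo-prior refresh off
    theta_cur = st.theta()
    on = st.delta
    prop_alpha = st.alpha + st.s_alpha * rng.standard_normal(L)
    theta_prop = st.theta(alpha=prop_alpha)
    ll_new = st.log_beta_prior(st.p_pop, theta_prop, st.p_anc).sum(axis=0)
    ll_old = st.log_beta_prior(st.p_pop, theta_cur, st.p_anc).sum(axis=0)
    dprior = -0.5 * (prop_alpha ** 2 - st.alpha ** 2) / _ALPHA_SD ** 2
    accept = on & (np.log(rng.random(L)) < ll_new - ll_old + dprior)
    st.alpha = np.where(accept, prop_alpha, st.alpha)
    if on.any():
        st.acc["alpha"][0] += int(accept[on].sum())
        st.acc["alpha"][1] += int(on.sum())
    off = ~on
    if off.any():  # Gibbs refresh from the pseudo-prior
        st.alpha[off] = pseudo_mean[off] + \
            pseudo_sd[off] * rng.standard_normal(int(off.sum()))

    # population effects (all rows proposed at once; rows are independent)
    theta_cur = st.theta()
    prop_beta = st.beta + st.s_beta * rng.standard_normal(K)
    theta_prop = st.theta(beta=prop_beta)
    ll_new = st.log_beta_prior(st.p_pop, theta_prop, st.p_anc).sum(axis=1)
    ll_old = st.log_beta_prior(st.p_pop, theta_cur, st.p_anc).sum(axis=1)
    dprior = -0.5 * ((prop_beta - _BETA_MEAN) ** 2
                     - (st.beta - _BETA_MEAN) ** 2) / _BETA_SD ** 2
    accept = np.log(rng.random(K)) < ll_new - ll_old + dprior
    st.beta = np.where(accept, prop_beta, st.beta)
    st.acc["beta"][0] += int(accept.sum())
    st.acc["beta"][1] += accept.size

    if not update_delta:
        return

    # selection indicators: toggle with pseudo-prior correction
    theta_on = st.theta(delta=np.ones(L, dtype=bool))
    theta_off = st.theta(delta=np.zeros(L, dtype=bool))
    ll_on = st.log_beta_prior(st.p_pop, theta_on, st.p_anc).sum(axis=0)
    ll_off = st.log_beta_prior(st.p_pop, theta_off, st.p_anc).sum(axis=0)
    log_prior_on = np.log(1.0 / (1.0 + prior_odds))
    log_prior_off = np.log(prior_odds / (1.0 + prior_odds))
    log_n = -0.5 * (st.alpha ** 2) / _ALPHA_SD ** 2 \
        - np.log(_ALPHA_SD * np.sqrt(2 * np.pi))
    log_g = -0.5 * ((st.alpha - pseudo_mean) ** 2) / pseudo_sd ** 2 \
        - np.log(pseudo_sd * np.sqrt(2 * np.pi))
    log_r_on = (ll_on - ll_off) + (log_prior_on - log_prior_off) + (log_n - log_g)
    flip_to_on = ~st.delta & (np.log(rng.random(L)) < log_r_on)
    flip_to_off = st.delta & (np.log(rng.random(L)) < -log_r_on)
    st.delta = st.delta ^ (flip_to_on | flip_to_off)
    st.acc["delta"][0] += int((flip_to_on | flip_to_off).sum())
    st.acc["delta"][1] += L


def _adapt(rates: dict[str, float], st: _State) -> None:
    for name, scale in (("p_pop", st.s_pop), ("p_anc", st.s_anc),
                        ("alpha", st.s_alpha), ("beta", st.s_beta)):
        r = rates.get(name)
        if r is None:
            continue
        if r > 0.45:
            scale *= 1.4
        elif r < 0.25:
            scale /= 1.4


def fit_bayes_fmodel(matrix: MarkerMatrix, schedule: MCMCSchedule | None = None,
                     prior_odds: float = 10.0, seed: int | None = None,
                     keep_delta_samples: bool = False) -> FModelResult:
    """Fit the F-model by MCMC; posterior selection probability per locus.

    Monomorphic loci are excluded (their posterior probability is reported
    as NaN).  Pilot runs execute with all selection indicators on, adapting
    the proposal scales and fitting the per-locus pseudo-priors used by the
    indicator move; the main run then samples delta.  A chain whose updates
    all collapse below 5% acceptance after the pilots aborts with a
    diagnostic.
    """
    schedule = schedule or MCMCSchedule()
    if np.any(matrix.bands == MISSING):
        raise ValueError("missing band scores present; resolve them first")
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx = matrix.pop_indices()
    mono = set(matrix.zero_variance_loci())
    poly = [l for l in matrix.locus_ids if l not in mono]
    sub = matrix.subset_loci(poly)
    K, L = len(pops), len(poly)
    m = np.empty((K, L))
    n = np.empty(K, dtype=int)
    for j, pop in enumerate(pops):
        rows = sub.bands[idx[pop]]
        m[j] = (rows == 0).sum(axis=0)
        n[j] = rows.shape[0]

    rng = np.random.default_rng(seed)
    st = _State(m, n, rng)
    pseudo_mean = np.zeros(L)
    pseudo_sd = np.full(L, 1.0)

    # pilot runs: delta forced on, adapt scales, collect alpha for pseudo-priors
    st.delta[:] = True
    alpha_hist = []
    for pilot in range(schedule.n_pilot):
        st.acc = {k: [0, 0] for k in st.acc}
        for _ in range(schedule.pilot_length):
            _sweep(st, pseudo_mean, pseudo_sd, prior_odds, update_delta=False)
        rates = {k: (a / t if t else 1.0) for k, (a, t) in st.acc.items()}
        _adapt(rates, st)
        if pilot >= schedule.n_pilot // 2:
            alpha_hist.append(st.alpha.copy())
    if alpha_hist:
        hist = np.asarray(alpha_hist)
        pseudo_mean = hist.mean(axis=0)
        pseudo_sd = np.maximum(hist.std(axis=0), 0.3)
    rates = {k: (a / t if t else 1.0) for k, (a, t) in st.acc.items()}
    if all(r < 0.05 for k, r in rates.items() if k != "delta"):
        raise RuntimeError(f"chain is not mixing after pilots: {rates}")

    # main run
    st.delta[:] = False
    st.acc = {k: [0, 0] for k in st.acc}
    delta_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    fst_sum = np.zeros(L)
    samples = []
    n_samples = 0
    for it in range(schedule.iterations):
        _sweep(st, pseudo_mean, pseudo_sd, prior_odds, update_delta=True)
        if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thinning == 0:
            delta_sum += st.delta
            alpha_sum += np.where(st.delta, st.alpha, 0.0)
            f = expit(st.alpha[None, :] * st.delta[None, :] + st.beta[:, None])
            fst_sum += f.mean(axis=0)
            if keep_delta_samples:
                samples.append(st.delta.copy())
            n_samples += 1
    rates = {k: (a / t if t else 0.0) for k, (a, t) in st.acc.items()}
    log.info("F-model acceptance rates: %s",
             {k: round(v, 3) for k, v in rates.items()})

    pp = pd.Series(delta_sum / n_samples, index=poly)
    table = pd.DataFrame({
        "posterior_prob": pp,
        "alpha_mean": pd.Series(
            np.divide(alpha_sum, np.maximum(delta_sum, 1)), index=poly),
        "fst_mean": pd.Series(fst_sum / n_samples, index=poly),
    }).reindex(matrix.locus_ids)
    return FModelResult(table=table, beta_mean=st.beta.copy(),
                        acceptance=rates, n_samples=n_samples,
                        delta_samples=np.asarray(samples) if keep_delta_samples else None)
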