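"""F_ST-outlier detection against a simulated neutral envelope.

The detector follows the Dfdist/fdist logic: simulate a large number of
dominant loci under a neutral Beta island model at a target background F_ST,
re-estimate (He, F_ST) for each simulated locus with exactly the estimators
used on the observed data, and judge each observed locus against the
simulated loci in its heterozygosity neighbourhood.  The background F_ST is
itself estimated iteratively as a "trimmed mean": loci outside the current
confidence envelope are excluded and the envelope is rebuilt at the mean of
the remainder, so a handful of strongly differentiated loci cannot inflate
the neutral baseline.

Empirical p-values are corrected by Benjamini-Hochberg; a locus is called a
divergent-selection outlier when it is rejected at the chosen FDR *and* lies
above the upper envelope curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import LocusStats, _center_corrections, band_freq_from_counts

log = logging.getLogger(__name__)


@dataclass
class NeutralEnvelope:
    """Simulated (He, F_ST) pairs under neutrality, sorted by He."""

    he: np.ndarray
    fst: np.ndarray
    target_fst: float
    pop_sizes: tuple[int, ...]
    ci: float = 0.95
    he_window: int = 2_000
    trimmed_mean: float | None = None

    @property
    def n_sims(self) -> int:
        return self.he.size

    def _window(self, he_value: float) -> slice:
        w = min(self.he_window, self.n_sims)
        i = int(np.searchsorted(self.he, he_value))
        lo = max(0, min(i - w // 2, self.n_sims - w))
        return slice(lo, lo + w)

    def quantile_curve(self, he_values: np.ndarray, q: float) -> np.ndarray:
        """Conditional F_ST quantile at each He, from the sliding window."""
        out = np.empty(len(he_values))
        for i, he in enumerate(np.asarray(he_values, dtype=float)):
            out[i] = np.quantile(self.fst[self._window(he)], q)
        return out

    def _grid_bounds(self, n_grid: int = 200) -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray]:
        """CI curves on an He grid, for cheap interpolation at many points."""
        grid = np.linspace(self.he[0], self.he[-1], n_grid)
        lo_q = (1.0 - self.ci) / 2.0
        return grid, self.quantile_curve(grid, lo_q), \
            self.quantile_curve(grid, 1.0 - lo_q)

    def self_trimmed_mean(self) -> float:
        """Mean F_ST of the simulated loci inside their own CI band.

        Trimming is not mean-preserving (the F_ST distribution is right
        skewed), so the trimmed mean of perfectly neutral loci sits below
        the simulation target; this quantity measures that offset.
        """
        grid, lo, hi = self._grid_bounds()
        lo_i = np.interp(self.he, grid, lo)
        hi_i = np.interp(self.he, grid, hi)
        inside = (self.fst >= lo_i) & (self.fst <= hi_i)
        return float(self.fst[inside].mean())

    def empirical_p(self, he_value: float, fst_value: float) -> float:
        """Upper-tail empirical p within the He neighbourhood."""
        win = self.fst[self._window(he_value)]
        return (1.0 + np.sum(win >= fst_value)) / (1.0 + win.size)

    def ci_bounds(self, he_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo_q = (1.0 - self.ci) / 2.0
        return (self.quantile_curve(he_values, lo_q),
                self.quantile_curve(he_values, 1.0 - lo_q))


def simulate_neutral_envelope(target_fst: float, pop_sizes: list[int],
                              n_sims: int = 1_000_000, ci: float = 0.95,
                              seed: int | None = None,
                              he_window: int = 2_000,
                              prior: tuple[float, float] = (1.0, 1.0),
                              min_sims: int = 10_000,
                              correction: str = "dominant_exact"
                              ) -> NeutralEnvelope:
    """Simulate neutral dominant loci and their re-estimated (He, F_ST).

    Each simulated locus draws an ancestral band-allele frequency from
    Uniform(0.01, 0.99), population frequencies from
    Beta(p(1-F)/F, (1-p)(1-F)/F), and dominant band phenotypes at the
    observed sample sizes; frequencies are then re-estimated from the counts
    with the same Bayesian estimator and variance correction used on real
    data, so the envelope and the observations are directly comparable.
    """
    if not (0.0 < target_fst < 0.99):
        raise ValueError("target_fst must be in (0, 0.99)")
    if n_sims < min_sims:
        raise ValueError(f"n_sims below the floor of {min_sims}")
    rng = np.random.default_rng(seed)
    sizes = np.asarray(pop_sizes, dtype=int)
    k = sizes.size
    p_anc = rng.uniform(0.01, 0.99, n_sims)
    a = p_anc * (1.0 - target_fst) / target_fst
    b = (1.0 - p_anc) * (1.0 - target_fst) / target_fst
    p_pop = rng.beta(a[:, None], b[:, None], size=(n_sims, k))

    phat = np.empty_like(p_pop)
    svar = np.zeros_like(p_pop)
    atten = np.ones_like(p_pop)
    for j in range(k):
        n_j = int(sizes[j])
        absent_prob = (1.0 - p_pop[:, j]) ** 2
        m_absent = rng.binomial(n_j, absent_prob)
        phat[:, j] = 1.0 - band_freq_from_counts(m_absent, n_j, prior)
    w = sizes / sizes.sum()
    pbar = phat @ w
    qbar = 1.0 - pbar
    if correction == "dominant_exact":
        for j in range(k):
            svar[:, j], atten[:, j] = _center_corrections(qbar, int(sizes[j]),
                                                          prior)
    elif correction == "binomial":
        svar = phat * (1.0 - phat) / (2.0 * sizes[None, :])
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    he = 2.0 * pbar * (1.0 - pbar)
    denom = pbar * (1.0 - pbar)
    s2 = (((phat - pbar[:, None]) ** 2 @ w) * k / (k - 1) - svar @ w) \
        / np.maximum((atten ** 2) @ w, 1e-3)
    total = denom + np.maximum(s2, 0.0) / k
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, s2 / np.where(denom > 0, total, 1.0), np.nan)
    ok = np.isfinite(fst)
    he, fst = he[ok], fst[ok]
    order = np.argsort(he, kind="stable")
    return NeutralEnvelope(he=he[order], fst=fst[order],
                           target_fst=target_fst,
                           pop_sizes=tuple(int(s) for s in sizes),
                           ci=ci, he_window=he_window)


def trimmed_mean_fst(locus_stats: LocusStats, pop_sizes: list[int],
                     n_sims: int = 50_000, ci: float = 0.95,
                     max_iter: int = 5, tol: float = 5e-4,
                     seed: int | None = None, he_window: int = 2_000,
                     prior: tuple[float, float] = (1.0, 1.0)
                     ) -> tuple[float, NeutralEnvelope]:
    """Iterated trimmed mean F_ST and the envelope built at it.

    Starting from the plain mean locus F_ST, an envelope is simulated at the
    current target, loci outside its confidence band are trimmed, and the
    target is updated by the gap between the data's trimmed mean and the
    simulated loci's own trimmed mean at the same target.  Because trimming
    a right-skewed F_ST distribution pulls the mean down even under pure
    neutrality, matching *trimmed* means (rather than forcing the target to
    the data's trimmed mean) keeps the envelope calibrated.  Iteration stops
    when the two trimmed means agree within ``tol`` or after ``max_iter``
    rounds; the returned value is the data's trimmed mean.
    """
    stats = locus_stats.table.dropna(subset=["fst"])
    fst = stats["fst"].to_numpy(float)
    he = stats["he"].to_numpy(float)
    if fst.size == 0:
        raise ValueError("no loci with a defined F_ST")
    rng = np.random.default_rng(seed)
    target = float(np.clip(fst.mean(), 1e-4, 0.9))
    envelope = None
    trimmed = target
    for it in range(max_iter):
        envelope = simulate_neutral_envelope(
            target, pop_sizes, n_sims=n_sims, ci=ci,
            seed=int(rng.integers(2 ** 31)), he_window=he_window,
            prior=prior, min_sims=min(n_sims, 10_000))
        lo, hi = envelope.ci_bounds(he)
        inside = (fst >= lo) & (fst <= hi)
        if not inside.any():
            raise ValueError("all loci trimmed; envelope cannot be anchored")
        trimmed = float(fst[inside].mean())
        sim_trimmed = envelope.self_trimmed_mean()
        gap = trimmed - sim_trimmed
        log.info("trim iteration %d: target %.4f, data trimmed mean %.4f, "
                 "simulated trimmed mean %.4f (%d/%d loci retained)",
                 it + 1, target, trimmed, sim_trimmed,
                 int(inside.sum()), fst.size)
        if abs(gap) < tol:
            break
        target = float(np.clip(target + gap, 1e-4, 0.9))
    envelope.trimmed_mean = trimmed
    return trimmed, envelope


def benjamini_hochberg(pvals: np.ndarray, fdr: float) -> np.ndarray:
    """Boolean rejection mask at the given FDR (step-up procedure)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = fdr * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        reject[order[:kmax + 1]] = True
    return reject


def fdist_classify(locus_stats: LocusStats, envelope: NeutralEnvelope,
                   fdr: float = 0.05) -> pd.DataFrame:
    """Per-locus empirical p, envelope position and FDR outlier flag.

    Returns a frame indexed by locus with columns ``empirical_p``,
    ``above_upper``, ``below_lower``, ``outside_ci`` and ``outlier``
    (Benjamini-Hochberg rejected and above the upper envelope curve).  Loci
    with undefined F_ST are excluded.
    """
    stats = locus_stats.table
    usable = stats.dropna(subset=["fst"])
    dropped = stats.index.difference(usable.index)
    if len(dropped):
        log.info("excluding %d loci with undefined F_ST from the scan",
                 len(dropped))
    he = usable["he"].to_numpy(float)
    fst = usable["fst"].to_numpy(float)
    pvals = np.array([envelope.empirical_p(h, f) for h, f in zip(he, fst)])
    lo, hi = envelope.ci_bounds(he)
    above = fst > hi
    below = fst < lo
    reject = benjamini_hochberg(pvals, fdr)
    out = pd.DataFrame({
        "empirical_p": pvals,
        "above_upper": above,
        "below_lower": below,
        "outside_ci": above | below,
        "fdr_reject": reject,
        "outlier": reject & above,
    }, index=usable.index)
    out = out.reindex(stats.index)
    for col in ("above_upper", "below_lower", "outside_ci", "fdr_reject",
                "outlier"):
        out[col] = out[col].astype("boolean").fillna(False).astype(bool)
    return out


def bayes_qvalues(posteriors: np.ndarray) -> np.ndarray:
    """q-values from posterior selection probabilities.

    Loci are ranked by posterior probability (PP) descending; the q-value of
    a locus is the mean of (1 - PP) over all loci with PP at least as large —
    the expected false-discovery proportion if everything down to that locus
    is called selected.
    """
    pp = np.asarray(posteriors, dtype=float)
    if np.any((pp < 0) | (pp > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-pp, kind="stable")
    cummean = np.cumsum(1.0 - pp[order]) / np.arange(1, pp.size + 1)
    # ties share the q of the last member of their tie group
    q_sorted = cummean.copy()
    i = pp.size - 1
    while i > 0:
        if pp[order[i]] == pp[order[i - 1]]:
            q_sorted[i - 1] = q_sorted[i]
        i -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class LocusPartition:
    """Selected/neutral split of the scanned loci under one consensus rule."""

    rule: str
    selected: list[str]
    neutral: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.selected) & set(self.neutral)
        if overlap:
            raise ValueError(f"loci in both sets: {sorted(overlap)[:5]}")


def consensus_partition(flags: dict[str, set[str]], all_loci: list[str],
                        rule: tuple[str, ...]) -> LocusPartition:
    """Intersect per-method outlier sets into a selected/neutral partition.

    ``flags`` maps a method name (e.g. "fdist", "bayes", "scan") to the set
    of locus ids it flagged; ``rule`` names the methods to intersect.
    """
    for method in rule:
        if method not in flags:
            raise ValueError(f"unknown method {method!r} in rule; "
                             f"have {sorted(flags)}")
    selected: set[str] = set(all_loci)
    for method in rule:
        selected &= set(flags[method])
    if not selected:
        log.warning("consensus rule %s selected no loci; downstream tests on "
                    "the selected set will be skipped", "&".join(rule))
    neutral = [l for l in all_loci if l not in selected]
    sel_sorted = [l for l in all_loci if l in selected]
    return LocusPartition(rule="&".join(rule), selected=sel_sorted,
                          neutral=neutral)
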