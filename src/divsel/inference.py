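"""Distance-matrix inference: GAMOVA, Mantel tests, scenario classification.

GAMOVA (a.k.a. multivariate distance-matrix regression, MDMR) regresses a
population differentiation matrix on a quantitative trait: the squared
distance matrix is Gower-centered, G = -1/2 J (D o D) J, and the pseudo-F is
tr(GH) / tr(G(I-H)) * (n - 2) for the hat matrix H of the design [1, trait].
Significance comes from permuting trait values across populations.  Because
Phi_PT matrices need not be Euclidean, G can have negative eigenvalues and
the pseudo-F can be negative; such values are reported as-is.

The Mantel test correlates the strict lower triangles of two distance
matrices with a simultaneous row/column permutation null, here used to test
isolation by distance (differentiation vs. great-circle geography).

The scenario classifier combines four significance flags — GAMOVA of a trait
on the selected-locus and neutral-locus differentiation matrices, and Mantel
tests of the two matrices against geography — into the causal reading of the
trait's among-population divergence: clinal selection (1.1), local selection
(1.2), selection confounded with neutral structure (2), neutral geography
(3.1), chance (3.2), or no signal at all.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import DistMatrix, PopulationMap

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def geo_distance_matrix(pops: PopulationMap) -> DistMatrix:
    """Great-circle (haversine) distances among populations, in km."""
    t = pops.table
    lat = np.radians(t["latitude"].to_numpy(float))
    lon = np.radians(t["longitude"].to_numpy(float))
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("missing coordinate in population map")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + \
        np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistMatrix(labels=pops.population_ids, values=d, kind="geo_km")


# ---------------------------------------------------------------------------
# GAMOVA / MDMR
# ---------------------------------------------------------------------------

@dataclass
class GamovaResult:
    trait: str
    locus_set: str
    pseudo_f: float
    p_value: float
    n_perm: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d * d) @ j


def _model_ss(g: np.ndarray, x: np.ndarray) -> float:
    """Model sum of squares tr(GH) for the design [1, x]."""
    n = g.shape[0]
    design = np.column_stack([np.ones(n), x])
    hat = design @ np.linalg.solve(design.T @ design, design.T)
    return float(np.trace(g @ hat))


def _pseudo_f(g: np.ndarray, x: np.ndarray) -> float:
    num = _model_ss(g, x)
    den = np.trace(g) - num
    return float(num / den * (g.shape[0] - 2))


def gamova(d: DistMatrix, trait_means: dict[str, float] | "np.ndarray",
           n_perm: int = 9_999, seed: int | None = None,
           trait_name: str = "", locus_set: str = "") -> GamovaResult:
    """Single-predictor GAMOVA of a distance matrix on population trait means.

    ``trait_means`` is either a mapping population -> value or an array in
    the matrix's label order.  The p-value permutes trait values across
    populations: p = (1 + #{extreme permutations}) / (1 + n_perm).  The
    permutation ranking uses the model sum of squares tr(GH): because tr(G)
    is permutation-invariant this orders permutations exactly as the F ratio
    does whenever the residual trace is positive, and it stays monotone in
    fit quality on strongly non-Euclidean matrices, where a near-perfect fit
    can drive the residual trace (and hence the F ratio) negative.
    """
    if isinstance(trait_means, dict):
        x = np.array([trait_means[l] for l in d.labels], dtype=float)
    else:
        x = np.asarray(trait_means, dtype=float)
    n = len(d.labels)
    if n < 4:
        raise ValueError("GAMOVA needs at least 4 populations (residual df)")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across populations")
    g = _gower_center(d.values)
    f_obs = _pseudo_f(g, x)
    ss_obs = _model_ss(g, x)
    rng = np.random.default_rng(seed)
    count = 0
    xp = x.copy()
    for _ in range(n_perm):
        rng.shuffle(xp)
        if _model_ss(g, xp) >= ss_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return GamovaResult(trait=trait_name, locus_set=locus_set,
                        pseudo_f=f_obs, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    label: str
    r: float
    p_value: float
    n_perm: int
    alternative: str


def _tri_corr(a: np.ndarray, b: np.ndarray, idx: tuple) -> float:
    x, y = a[idx], b[idx]
    return float(np.corrcoef(x, y)[0, 1])


def mantel(d1: DistMatrix, d2: DistMatrix, n_perm: int = 9_999,
           seed: int | None = None, alternative: str = "greater",
           label: str = "", exhaustive: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices over the same labels.

    r is the Pearson correlation of the strict lower triangles; the null
    permutes rows and columns of the second matrix simultaneously.  With
    ``exhaustive`` every relabeling is enumerated (small n only).  The
    default one-sided alternative ("greater") matches the isolation-by-
    distance question; "two-sided" and "less" are available.
    """
    if d1.labels != d2.labels:
        d2 = d2.reorder(d1.labels)
    n = len(d1.labels)
    idx = np.tril_indices(n, k=-1)
    if np.ptp(d1.values[idx]) == 0 or np.ptp(d2.values[idx]) == 0:
        raise ValueError("constant lower triangle; Mantel r undefined")
    r_obs = _tri_corr(d1.values, d2.values, idx)

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        if alternative == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = sum(
            extreme(_tri_corr(d1.values, d2.values[np.ix_(p, p)], idx))
            for p in perms)
        p_val = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        order = np.arange(n)
        for _ in range(n_perm):
            rng.shuffle(order)
            if extreme(_tri_corr(d1.values, d2.values[np.ix_(order, order)], idx)):
                count += 1
        p_val = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(label=label, r=r_obs, p_value=p_val,
                        n_perm=n_used, alternative=alternative)


# ---------------------------------------------------------------------------
# Trait-climate regression
# ---------------------------------------------------------------------------

def trait_env_regression(trait_means: dict[str, float],
                         env_values: dict[str, float],
                         drop: list[str] | None = None
                         ) -> tuple[float, float, float]:
    """OLS of population trait means on one climate variable.

    Returns (slope, intercept, r_squared); ``drop`` omits named populations
    (logged), mirroring the practice of excluding climatically isolated
    sites before regressing.
    """
    drop = set(drop or [])
    if drop:
        log.info("regression omitting populations: %s", sorted(drop))
    pops = [p for p in trait_means if p in env_values and p not in drop]
    if len(pops) < 3:
        raise ValueError("need at least 3 populations after drops")
    x = np.array([env_values[p] for p in pops], dtype=float)
    y = np.array([trait_means[p] for p in pops], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# Scenario classification
# ---------------------------------------------------------------------------

INTERPRETATIONS = {
    "1.1": "trait divergence driven by selection along a geographical cline",
    "1.2": "trait divergence driven by local (non-clinal) selection",
    "2": ("trait correlates with both locus sets; neutral processes cannot "
          "be excluded as a cause of the divergence"),
    "3.1": ("trait divergence driven by neutral geographical processes "
            "(isolation by distance, founder effects, phylogeography)"),
    "3.2": "trait divergence attributable to chance",
    "no_signal": "no significant association with either locus set",
}


@dataclass
class ScenarioCall:
    trait: str
    locus_set: str
    scenario: str
    interpretation: str
    gamova_selected: bool
    gamova_neutral: bool
    mantel_selected: bool
    mantel_neutral: bool


def classify_scenario(gamova_sel: bool, gamova_neut: bool,
                      mantel_sel: bool, mantel_neut: bool,
                      trait: str = "", locus_set: str = "") -> ScenarioCall:
    """Map the four significance flags to a divergence scenario.

    Decision table (sel/neut refer to the GAMOVA on the selected/neutral
    locus-set matrix; mantel flags to isolation-by-distance on each set):
    (+, -) -> 1.1 if the selected set shows IBD else 1.2; (+, +) -> 2;
    (-, +) -> 3.1 if the neutral set shows IBD else 3.2; (-, -) -> no_signal.
    Total and deterministic over all 16 flag combinations.
    """
    if gamova_sel and not gamova_neut:
        scenario = "1.1" if mantel_sel else "1.2"
    elif gamova_sel and gamova_neut:
        scenario = "2"
    elif gamova_neut:
        scenario = "3.1" if mantel_neut else "3.2"
    else:
        scenario = "no_signal"
    return ScenarioCall(trait=trait, locus_set=locus_set, scenario=scenario,
                        interpretation=INTERPRETATIONS[scenario],
                        gamova_selected=gamova_sel, gamova_neutral=gamova_neut,
                        mantel_selected=mantel_sel, mantel_neutral=mantel_neut)
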