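"""Synthetic datasets with known ground truth.

Emulates the study design the pipeline targets: ~12 populations of a
short-lived herb sampled along a steep aridity transect, fingerprinted at
~732 dominant loci with weak neutral structure (background F_ST ~ 0.02), a
small set of loci whose band-allele frequencies are clinal in climate,
quantitative traits driven by those loci, and leaf/flower shape data whose
leading axis of variation tracks a trait.

Neutral population frequencies follow the Balding-Nichols Beta model
``p_j ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency p; an
optional isolation-by-distance knob correlates the Beta deviates of nearby
populations through a Gaussian copula with exponential spatial correlation,
leaving the marginal F_ST untouched.  Selected loci have
``logit(p_j) = a + slope * z_j`` with z the standardized environmental value
of population j.  Band phenotypes are dominant under Hardy-Weinberg:
``P(band) = 1 - (1 - p_j)^2``.

All generators are fully determined by (seed, parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .datatypes import ClimateTable, MarkerMatrix, PopulationMap, TraitSet

log = logging.getLogger(__name__)

#: realistic-looking affine ranges for the 20 bioclimatic variables:
#: bio01..bio11 temperature-like (degrees C), bio12..bio20 precipitation-like
#: (mm).  (low at mesic end, high at arid end) per variable; bio12 (annual
#: precipitation) is set separately from ``prec_range``.
_BIO_RANGES: dict[str, tuple[float, float]] = {
    "bio01": (19.0, 22.5), "bio02": (10.0, 14.5), "bio03": (35.0, 41.0),
    "bio04": (550.0, 720.0), "bio05": (31.0, 40.0), "bio06": (6.0, 8.5),
    "bio07": (24.0, 32.0), "bio08": (13.0, 16.0), "bio09": (26.0, 31.0),
    "bio10": (26.0, 31.5), "bio11": (11.5, 14.0),
    "bio13": (35.0, 18.0), "bio14": (1.0, 0.0), "bio15": (55.0, 90.0),
    "bio16": (90.0, 45.0), "bio17": (6.0, 2.0), "bio18": (20.0, 6.0),
    "bio19": (80.0, 40.0), "bio20": (50.0, 25.0),
}


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    selected_ids: list[str]
    slopes: dict[str, float]
    fst_background: float
    seed: int
    env_var: str
    transect_pos: pd.Series = field(default=None)  # per population, km
    env_z: pd.Series = field(default=None)  # standardized env value per pop
    selected_pop_freqs: pd.DataFrame = field(default=None)  # pops x selected loci
    trait_classes: dict[str, str] = field(default_factory=dict)
    trait_coupling: float = 0.0
    trait_noise_sd: float = 0.0


# ---------------------------------------------------------------------------
# Populations and climate
# ---------------------------------------------------------------------------

def gen_metadata(n_pops: int = 12, gradient_length_km: float = 250.0,
                 seed: int = 0, n_ind: int = 15,
                 prec_range: tuple[float, float] = (100.0, 200.0),
                 inter_corr: float = 0.9,
                 climate_noise: float = 0.05) -> tuple[PopulationMap, ClimateTable]:
    """Populations on a 1-D transect plus a correlated climate table.

    Populations are spaced evenly (with jitter) along a west-east transect of
    the given length; every bioclimatic variable is an affine function of
    transect position mixed with noise so that pairwise correlations are
    about ``inter_corr**2`` and a leading climate PC exists.  The annual
    precipitation variable (bio12) decreases from ``prec_range[1]`` at the
    mesic end to ``prec_range[0]`` at the arid end.  With
    ``gradient_length_km=0`` all populations are co-located and every climate
    column is constant.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    base = np.linspace(0.0, 1.0, n_pops)
    if gradient_length_km > 0:
        jitter = rng.uniform(-0.5, 0.5, n_pops) / (2.0 * (n_pops - 1))
        frac = np.clip(base + jitter, 0.0, 1.0)
    else:
        frac = np.zeros(n_pops)
    pos_km = frac * gradient_length_km

    # place the transect in an arid subtropical coastal strip; x is longitude
    lat0, lon0 = 33.6, 8.6
    lat = lat0 + rng.uniform(-0.1, 0.1, n_pops) * (gradient_length_km > 0)
    km_per_deg_lon = 111.32 * np.cos(np.radians(lat0))
    lon = lon0 + pos_km / km_per_deg_lon

    pops = [f"pop{i + 1:02d}" for i in range(n_pops)]
    pop_map = PopulationMap(pd.DataFrame({
        "population_id": pops, "latitude": lat, "longitude": lon,
        "n_individuals": n_ind,
    }))

    # standardized transect signal; degenerate gradient -> all-zero signal
    if np.ptp(frac) > 0:
        z = (frac - frac.mean()) / frac.std()
    else:
        z = np.zeros(n_pops)
    span = np.ptp(frac)

    clim = {"population_id": pops}
    rows = {}
    for name, (lo, hi) in _BIO_RANGES.items():
        eps = rng.standard_normal(n_pops)
        mix = inter_corr * z + np.sqrt(max(0.0, 1.0 - inter_corr ** 2)) * eps
        mix = mix + climate_noise * span * rng.standard_normal(n_pops)
        rows[name] = lo + (hi - lo) * (mix - mix.min()) / max(np.ptp(mix), 1e-12) \
            if span > 0 else np.full(n_pops, (lo + hi) / 2.0)
    # annual precipitation decreases with aridity (increasing position)
    eps = rng.standard_normal(n_pops)
    mix = inter_corr * z + np.sqrt(max(0.0, 1.0 - inter_corr ** 2)) * eps
    if span > 0:
        scaled = (mix - mix.min()) / max(np.ptp(mix), 1e-12)
        rows["bio12"] = prec_range[1] - (prec_range[1] - prec_range[0]) * scaled
    else:
        rows["bio12"] = np.full(n_pops, float(np.mean(prec_range)))
    for name in sorted(rows):
        clim[name] = rows[name]
    clim["latitude"] = lat
    clim["longitude"] = lon
    climate = ClimateTable(pd.DataFrame(clim))
    # transect position retained for generators downstream
    climate.table.attrs["transect_km"] = dict(zip(pops, pos_km))
    return pop_map, climate


# ---------------------------------------------------------------------------
# Dominant marker matrix
# ---------------------------------------------------------------------------

def _neutral_pop_freqs(p_anc: np.ndarray, fst: float, n_pops: int,
                       rng: np.random.Generator,
                       corr: np.ndarray | None = None) -> np.ndarray:
    """Balding-Nichols frequencies, optionally spatially correlated.

    With ``corr`` given (pops x pops correlation matrix), Beta deviates are
    drawn through a Gaussian copula so that nearby populations co-vary
    (isolation by distance).  Correlated deviates shrink the within-locus
    across-population spread, so the marginal Beta variance is inflated by
    the appropriate factor to keep the realized per-locus differentiation at
    the nominal ``fst``.
    """
    L = p_anc.size
    if corr is not None:
        k = n_pops
        # expected (K/(K-1))-corrected sample variance under correlation C is
        # sigma^2 * (K/(K-1)) * (1 - mean(C)); compensate so realized F_ST
        # stays at the target
        gamma = (k / (k - 1)) * (1.0 - corr.mean())
        fst = min(fst / max(gamma, 1e-6), 0.8)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    if corr is None:
        return rng.beta(a[:, None], b[:, None], size=(L, n_pops))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))
    zn = rng.standard_normal((L, n_pops)) @ chol.T
    u = stats.norm.cdf(zn)
    return stats.beta.ppf(u, a[:, None], b[:, None])


def gen_aflp(meta: tuple[PopulationMap, ClimateTable],
             n_neutral: int = 700, n_selected: int = 30,
             fst_background: float = 0.02, slope: float = 1.5,
             n_ind: int | dict[str, int] = 15,
             error_rate: float = 0.09, n_replicates: int = 24,
             env_var: str = "bio12", ibd: bool = True,
             ibd_length_frac: float = 1.0 / 3.0, ibd_strength: float = 0.2,
             seed: int = 0) -> tuple[MarkerMatrix, SimTruth]:
    """Simulate a dominant band matrix with neutral and clinal loci.

    Neutral loci: ancestral band-allele frequency ~ Uniform(0.1, 0.9),
    population frequencies from the Beta island model at ``fst_background``
    (spatially autocorrelated if ``ibd``).  Selected loci: logit-linear cline
    in the standardized ``env_var`` value, intercept drawn so mid-transect
    frequencies are intermediate.  ``n_replicates`` individuals are duplicated
    with per-locus bit-flip probability ``error_rate`` and appended as
    replicate pairs.
    """
    pop_map, climate = meta
    if not (0.0 < fst_background <= 0.5):
        raise ValueError("fst_background must be in (0, 0.5]")
    pops = pop_map.population_ids
    k = len(pops)
    sizes = {p: (n_ind[p] if isinstance(n_ind, dict) else int(n_ind)) for p in pops}
    if min(sizes.values()) < 2:
        raise ValueError("need at least 2 individuals per population")
    rng = np.random.default_rng(seed)

    env = climate.values_for([env_var]).loc[pops, env_var].to_numpy(float)
    if np.ptp(env) > 0:
        env_z = (env - env.mean()) / env.std()
    else:
        env_z = np.zeros(k)

    corr = None
    if ibd:
        pos = np.array([climate.table.attrs.get("transect_km", {}).get(p, i)
                        for i, p in enumerate(pops)], dtype=float)
        span = max(np.ptp(pos), 1e-9)
        length = ibd_length_frac * span
        corr = np.exp(-np.abs(pos[:, None] - pos[None, :]) / max(length, 1e-9))
        # ibd_strength scales how much of each deviate is spatially shared:
        # off-diagonal correlation s^2 * exp(-d/l), diagonal stays 1
        corr = ibd_strength ** 2 * corr
        np.fill_diagonal(corr, 1.0)

    p_anc = rng.uniform(0.1, 0.9, n_neutral)
    neut = _neutral_pop_freqs(p_anc, fst_background, k, rng, corr)

    if n_selected > 0:
        # clinal shift applied on top of the same neutral island-model
        # background, so slope = 0 reduces exactly to a neutral locus
        anc_sel = rng.uniform(0.3, 0.7, n_selected)
        base = _neutral_pop_freqs(anc_sel, fst_background, k, rng, corr)
        sel = expit(logit(np.clip(base, 1e-9, 1 - 1e-9))
                    + slope * env_z[None, :])
        n_clip = int(np.sum((sel < 0.001) | (sel > 0.999)))
        if n_clip:
            log.warning("clipped %d clinal frequencies to [0.001, 0.999]", n_clip)
        sel = np.clip(sel, 0.001, 0.999)
        freqs = np.vstack([neut, sel])
    else:
        freqs = neut
    locus_ids = [f"L{i + 1:03d}" for i in range(n_neutral)] + \
                [f"S{i + 1:03d}" for i in range(n_selected)]
    sel_ids = locus_ids[n_neutral:]
    slopes = {l: float(slope) for l in sel_ids}

    # dominant band phenotypes under Hardy-Weinberg
    ind_ids, pop_of, rows = [], {}, []
    for j, pop in enumerate(pops):
        band_prob = 1.0 - (1.0 - freqs[:, j]) ** 2
        draws = rng.random((sizes[pop], freqs.shape[0])) < band_prob[None, :]
        for i in range(sizes[pop]):
            ind = f"{pop}_i{i + 1:02d}"
            ind_ids.append(ind)
            pop_of[ind] = pop
            rows.append(draws[i].astype(np.int8))
    bands = np.array(rows, dtype=np.int8)

    # replicate pairs: copy of an existing individual with bit-flip noise
    replicate_pairs = []
    if n_replicates > 0:
        chosen = rng.choice(len(ind_ids), size=min(n_replicates, len(ind_ids)),
                            replace=False)
        rep_rows = []
        for c in chosen:
            src = ind_ids[c]
            rep = f"{src}_rep"
            flips = rng.random(bands.shape[1]) < error_rate
            rep_rows.append(np.where(flips, 1 - bands[c], bands[c]).astype(np.int8))
            ind_ids.append(rep)
            pop_of[rep] = pop_of[src]
            replicate_pairs.append((src, rep))
        bands = np.vstack([bands, np.array(rep_rows, dtype=np.int8)])

    matrix = MarkerMatrix(individual_ids=ind_ids, locus_ids=locus_ids,
                          bands=bands, pop_of=pop_of,
                          replicate_pairs=replicate_pairs)
    truth = SimTruth(
        selected_ids=sel_ids, slopes=slopes, fst_background=fst_background,
        seed=seed, env_var=env_var,
        transect_pos=pd.Series(climate.table.attrs.get("transect_km", {}),
                               dtype=float).reindex(pops),
        env_z=pd.Series(env_z, index=pops),
        selected_pop_freqs=pd.DataFrame(
            freqs[n_neutral:].T, index=pops, columns=sel_ids),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

DEFAULT_TRAIT_CLASSES: dict[str, str] = {
    "V01": "selected", "V02": "neutral_ibd", "V03": "random", "V04": "random",
    "V05": "random", "V06": "random", "V07": "neutral_ibd", "V08": "random",
    "V09": "random", "V10": "random",
}


def gen_traits(meta: tuple[PopulationMap, ClimateTable], truth: SimTruth,
               matrix: MarkerMatrix, coupling: float = 1.0,
               noise_sd: float = 1.0,
               trait_classes: dict[str, str] | None = None,
               seed: int = 0) -> TraitSet:
    """Per-individual quantitative traits in three generative flavors.

    ``selected`` traits follow the standardized population mean band-presence
    frequency of the clinal loci (the genetic signal a selected trait would
    hitchhike on); ``neutral_ibd`` traits follow transect position (pure
    geography); ``random`` traits are individual noise.  Individual values
    add Gaussian noise of ``noise_sd`` to the population signal.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    pop_map, climate = meta
    pops = pop_map.population_ids
    classes = dict(DEFAULT_TRAIT_CLASSES if trait_classes is None else trait_classes)
    rng = np.random.default_rng(seed)

    if truth.selected_pop_freqs is not None and truth.selected_pop_freqs.shape[1]:
        sel_sig = truth.selected_pop_freqs.mean(axis=1).reindex(pops).to_numpy()
        sel_sig = (sel_sig - sel_sig.mean()) / max(sel_sig.std(), 1e-12)
    else:
        sel_sig = np.zeros(len(pops))
    pos = truth.transect_pos.reindex(pops).to_numpy(float)
    if np.ptp(pos) > 0:
        pos_sig = (pos - pos.mean()) / pos.std()
    else:
        pos_sig = np.zeros(len(pops))

    base = matrix.drop_replicates()
    inds = base.individual_ids
    pop_idx = np.array([pops.index(base.pop_of[i]) for i in inds])
    data = {"individual_id": inds,
            "population_id": [base.pop_of[i] for i in inds]}
    for trait, cls in classes.items():
        if cls == "selected":
            mu = coupling * sel_sig[pop_idx]
        elif cls == "neutral_ibd":
            mu = coupling * pos_sig[pop_idx]
        elif cls == "random":
            mu = np.zeros(len(inds))
        else:
            raise ValueError(f"unknown trait class {cls!r}")
        data[trait] = mu + noise_sd * rng.standard_normal(len(inds))
    truth.trait_classes = classes
    truth.trait_coupling = coupling
    truth.trait_noise_sd = noise_sd
    return TraitSet(individuals=pd.DataFrame(data), trait_classes=classes)


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

def gen_leaf_outlines(n_per_pop: int, aspect_by_pop: dict[str, float],
                      lobing: float = 0.2, n_lobes: int = 9,
                      n_points: int = 256, aspect_jitter: float = 0.08,
                      seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """Closed lobed leaf outlines, one polygon per leaf.

    Each outline is an ellipse with per-leaf aspect ratio drawn around its
    population target, radius-modulated by a sinusoidal lobing term
    ``r(t) = 1 + lobing * sin(n_lobes * t)``.  With lobing < 0.5 the outline
    is star-shaped (radius stays positive) and cannot self-intersect.
    """
    if n_points < 64:
        raise ValueError("need at least 64 outline points")
    if not (0.0 <= lobing < 0.5):
        raise ValueError("lobing must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    out = []
    for pop, target in aspect_by_pop.items():
        for _ in range(n_per_pop):
            aspect = target * np.exp(aspect_jitter * rng.standard_normal())
            r = 1.0 + lobing * np.sin(n_lobes * t)
            xy = np.column_stack([aspect * r * np.cos(t), r * np.sin(t)])
            out.append((pop, xy))
    return out


def gen_flower_landmarks(n_per_pop: int, pops: list[str],
                         petal_length: float = 8.0, petal_width: float = 3.0,
                         length_sd: float = 0.5, landmark_noise: float = 0.08,
                         seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """37-point flower configurations: center, 4 petal tips, 32 margin points.

    Petals radiate at 45/135/225/315 degrees; each contributes margin points
    at 25/50/75/95% of petal length on both sides of the midrib (4 fractions
    x 2 sides x 4 petals = 32 semilandmarks).  Landmark noise is isotropic
    Gaussian.
    """
    rng = np.random.default_rng(seed)
    fracs = np.array([0.25, 0.50, 0.75, 0.95])
    # petal half-width profile along the midrib, broadest near 60% length
    half_w = 0.5 * petal_width * np.sin(np.pi * fracs ** 0.8)
    out = []
    for pop in pops:
        for _ in range(n_per_pop):
            pts = [np.zeros(2)]
            tips = []
            margins = []
            for ang_deg in (45.0, 135.0, 225.0, 315.0):
                ang = np.radians(ang_deg)
                u = np.array([np.cos(ang), np.sin(ang)])      # midrib direction
                v = np.array([-np.sin(ang), np.cos(ang)])     # perpendicular
                length = petal_length + length_sd * rng.standard_normal()
                tips.append(length * u)
                for f, w in zip(fracs, half_w):
                    margins.append(f * length * u + w * v)
                    margins.append(f * length * u - w * v)
            config = np.vstack(pts + tips + margins)
            config += landmark_noise * rng.standard_normal(config.shape)
            out.append((pop, config))
    return out


def gen_shapes(n_per_pop: int, aspect_by_pop: dict[str, float],
               lobing: float = 0.2, n_lobes: int = 9, n_points: int = 256,
               seed: int = 0):
    """Leaf outlines plus flower landmark configurations for the same pops."""
    leaves = gen_leaf_outlines(n_per_pop, aspect_by_pop, lobing=lobing,
                               n_lobes=n_lobes, n_points=n_points, seed=seed)
    flowers = gen_flower_landmarks(n_per_pop, list(aspect_by_pop), seed=seed + 1)
    return leaves, flowers
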