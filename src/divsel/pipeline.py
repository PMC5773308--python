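"""End-to-end orchestration: detectors -> partitions -> scenario calls.

``detect_outliers`` runs the configured locus-selection detectors and builds
the consensus selected/neutral partitions; ``run_scenario_analysis`` computes
the differentiation matrices for each partition, the Mantel
isolation-by-distance tests and the per-trait GAMOVAs, and classifies every
trait into a divergence scenario; ``run_all`` chains the two and returns
tab-ready result tables.  ``simulate_bundle`` produces a complete synthetic
input bundle (markers, populations, climate, traits including derived shape
scores) with known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import climate_pca, logistic_scan, scan_selected_loci
from .config import PipelineConfig
from .datatypes import DistMatrix, TraitSet
from .fmodel import FModelResult, fit_bayes_fmodel
from .inference import (ScenarioCall, classify_scenario, gamova,
                        geo_distance_matrix, mantel)
from .io import Dataset
from .morpho import derive_flower_traits, derive_leaf_traits
from .outliers import (LocusPartition, NeutralEnvelope, bayes_qvalues,
                       consensus_partition, fdist_classify, trimmed_mean_fst)
from .popgen import LocusStats, compute_locus_stats, pairwise_phi_pt
from .simulate import (SimTruth, gen_aflp, gen_flower_landmarks,
                       gen_leaf_outlines, gen_metadata, gen_traits)

log = logging.getLogger(__name__)


@dataclass
class OutlierResults:
    locus_stats: LocusStats
    trimmed_mean: float | None
    envelope: NeutralEnvelope | None
    fdist_table: pd.DataFrame | None
    fmodel: FModelResult | None
    scan: pd.DataFrame | None
    flags: dict[str, set[str]]
    partitions: list[LocusPartition]
    locus_table: pd.DataFrame = field(default=None)


def detect_outliers(dataset: Dataset, config: PipelineConfig | None = None,
                    seed: int | None = None) -> OutlierResults:
    """Run the configured detectors and assemble per-locus results."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    matrix = dataset.markers.drop_replicates()
    log.info("outlier stage: %d loci, %d populations, detectors=%s",
             matrix.n_loci, len(matrix.populations), config.detectors)

    stats = compute_locus_stats(matrix)
    table = stats.table.copy()
    flags: dict[str, set[str]] = {}
    trimmed = envelope = fdist_table = fmodel = scan = None

    if "fdist" in config.detectors:
        sizes = list(matrix.pop_sizes().values())
        trimmed, envelope = trimmed_mean_fst(
            stats, sizes, n_sims=config.n_envelope_sims,
            ci=config.envelope_ci, max_iter=config.trim_max_iter,
            seed=int(rng.integers(2 ** 31)), he_window=config.he_window)
        log.info("trimmed mean F_ST = %.4f", trimmed)
        fdist_table = fdist_classify(stats, envelope, fdr=config.fdr)
        table = table.join(fdist_table[["empirical_p", "outside_ci"]])
        table["outlier_fdist"] = fdist_table["outlier"]
        flags["fdist"] = set(fdist_table.index[fdist_table["outlier"]])

    if "bayes" in config.detectors:
        fmodel = fit_bayes_fmodel(matrix, schedule=config.mcmc,
                                  prior_odds=config.prior_odds,
                                  seed=int(rng.integers(2 ** 31)))
        pp = fmodel.table["posterior_prob"]
        q = pd.Series(np.nan, index=pp.index)
        ok = pp.notna()
        q[ok] = bayes_qvalues(pp[ok].to_numpy())
        table["posterior_prob"] = pp
        table["q_value"] = q
        table["outlier_bayes"] = (q <= config.bayes_q_threshold).fillna(False)
        flags["bayes"] = set(table.index[table["outlier_bayes"]])

    if "scan" in config.detectors:
        pca = climate_pca(dataset.climate)
        scan = logistic_scan(matrix, dataset.climate,
                             pca_components=pca.scores,
                             alpha=config.assoc_alpha, rule=config.assoc_rule)
        by_locus = scan_selected_loci(scan)
        table["scan_variables"] = [",".join(by_locus.get(l, [])) or ""
                                   for l in table.index]
        table["outlier_scan"] = [l in by_locus for l in table.index]
        flags["scan"] = set(by_locus)

    scanned = stats.table.dropna(subset=["fst"]).index.tolist()
    partitions = []
    for rule in config.partition_rules:
        if all(m in flags for m in rule):
            partitions.append(consensus_partition(flags, scanned, tuple(rule)))
    return OutlierResults(locus_stats=stats, trimmed_mean=trimmed,
                          envelope=envelope, fdist_table=fdist_table,
                          fmodel=fmodel, scan=scan, flags=flags,
                          partitions=partitions, locus_table=table)


@dataclass
class ScenarioResults:
    gamova_table: pd.DataFrame
    mantel_table: pd.DataFrame
    scenario_table: pd.DataFrame
    calls: list[ScenarioCall]


def run_scenario_analysis(dataset: Dataset, partitions: list[LocusPartition],
                          config: PipelineConfig | None = None,
                          seed: int | None = None,
                          traits: TraitSet | None = None) -> ScenarioResults:
    """GAMOVA + Mantel cross-tests and the scenario call for every trait."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    matrix = dataset.markers.drop_replicates()
    traits = traits or dataset.traits
    if traits is None:
        raise ValueError("no trait table available")
    means = traits.population_means()
    geo = geo_distance_matrix(dataset.populations)

    gam_rows, man_rows, calls = [], [], []
    for part in partitions:
        sets: dict[str, DistMatrix | None] = {}
        for name, loci in (("selected", part.selected), ("neutral", part.neutral)):
            if len(loci) == 0:
                log.warning("partition %s has an empty %s set; its tests are "
                            "skipped", part.rule, name)
                sets[name] = None
                continue
            sets[name] = pairwise_phi_pt(matrix.subset_loci(loci))
        mantel_flags = {}
        for name, dm in sets.items():
            if dm is None or np.ptp(dm.lower_triangle()) == 0:
                mantel_flags[name] = False
                man_rows.append({"rule": part.rule, "locus_set": name,
                                 "n_loci": len(getattr(part, name)),
                                 "r": np.nan, "p_value": np.nan})
                continue
            res = mantel(dm, geo, n_perm=config.n_permutations,
                         seed=int(rng.integers(2 ** 31)),
                         label=f"{part.rule}:{name}")
            mantel_flags[name] = res.p_value <= config.alpha
            man_rows.append({"rule": part.rule, "locus_set": name,
                             "n_loci": len(getattr(part, name)),
                             "r": res.r, "p_value": res.p_value})
        for trait in traits.trait_names:
            tvals = means[trait].to_dict()
            sig = {}
            for name, dm in sets.items():
                if dm is None or np.ptp(np.asarray(list(tvals.values()))) == 0:
                    sig[name] = False
                    continue
                res = gamova(dm, tvals, n_perm=config.n_permutations,
                             seed=int(rng.integers(2 ** 31)),
                             trait_name=trait, locus_set=f"{part.rule}:{name}")
                sig[name] = res.p_value <= config.alpha
                gam_rows.append({"rule": part.rule, "locus_set": name,
                                 "trait": trait, "pseudo_f": res.pseudo_f,
                                 "p_value": res.p_value})
            call = classify_scenario(sig.get("selected", False),
                                     sig.get("neutral", False),
                                     mantel_flags.get("selected", False),
                                     mantel_flags.get("neutral", False),
                                     trait=trait, locus_set=part.rule)
            calls.append(call)
    scen = pd.DataFrame([{
        "rule": c.locus_set, "trait": c.trait, "scenario": c.scenario,
        "gamova_selected": c.gamova_selected, "gamova_neutral": c.gamova_neutral,
        "mantel_selected": c.mantel_selected, "mantel_neutral": c.mantel_neutral,
        "interpretation": c.interpretation,
    } for c in calls])
    return ScenarioResults(gamova_table=pd.DataFrame(gam_rows),
                           mantel_table=pd.DataFrame(man_rows),
                           scenario_table=scen, calls=calls)


@dataclass
class PipelineResult:
    outliers: OutlierResults
    scenarios: ScenarioResults

    def tables(self) -> dict[str, pd.DataFrame]:
        t = {"locus_stats": self.outliers.locus_table.rename_axis("locus"),
             "gamova": self.scenarios.gamova_table,
             "mantel": self.scenarios.mantel_table,
             "scenarios": self.scenarios.scenario_table}
        return t


def run_all(dataset: Dataset, config: PipelineConfig | None = None,
            seed: int | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    out = detect_outliers(dataset, config, seed=seed)
    scen = run_scenario_analysis(dataset, out.partitions, config, seed=seed + 1)
    return PipelineResult(outliers=out, scenarios=scen)


# ---------------------------------------------------------------------------
# Synthetic bundle
# ---------------------------------------------------------------------------

def simulate_bundle(seed: int = 0, n_pops: int = 12, n_ind: int = 15,
                    n_neutral: int = 700, n_selected: int = 30,
                    fst_background: float = 0.02, slope: float = 1.5,
                    coupling: float = 1.0, noise_sd: float = 1.0,
                    error_rate: float = 0.09, n_replicates: int = 24,
                    include_shapes: bool = True,
                    aspect_range: tuple[float, float] = (1.5, 3.5),
                    ) -> tuple[Dataset, SimTruth, dict]:
    """Generate the full default study emulation with ground truth.

    The leaf-shape generator is coupled to the "selected" trait: each
    population's target aspect ratio interpolates over ``aspect_range``
    according to its standardized selected-trait signal, so the leading leaf
    shape axis (V15) tracks the clinal genetic signal the way a trait under
    climate-dependent selection would.
    """
    meta = gen_metadata(n_pops=n_pops, seed=seed, n_ind=n_ind)
    pop_map, climate = meta
    matrix, truth = gen_aflp(meta, n_neutral=n_neutral, n_selected=n_selected,
                             fst_background=fst_background, slope=slope,
                             n_ind=n_ind, error_rate=error_rate,
                             n_replicates=n_replicates, seed=seed + 1)
    traits = gen_traits(meta, truth, matrix, coupling=coupling,
                        noise_sd=noise_sd, seed=seed + 2)
    shapes: dict = {}
    if include_shapes:
        pops = pop_map.population_ids
        if truth.selected_pop_freqs is not None and truth.selected_pop_freqs.shape[1]:
            sig = truth.selected_pop_freqs.mean(axis=1).reindex(pops)
            z = (sig - sig.min()) / max(sig.max() - sig.min(), 1e-12)
        else:
            z = pd.Series(0.5, index=pops)
        aspect_by_pop = {p: aspect_range[0] +
                         (aspect_range[1] - aspect_range[0]) * float(z[p])
                         for p in pops}
        leaves = gen_leaf_outlines(n_ind, aspect_by_pop, seed=seed + 3)
        flowers = gen_flower_landmarks(n_ind, pops, seed=seed + 4)
        labels_l, leaf_scores, leaf_pct = derive_leaf_traits(leaves)
        labels_f, flower_scores, flower_pct = derive_flower_traits(flowers)
        base = traits.individuals
        flower_cols = {f"V{i + 11:02d}": flower_scores[:, i]
                       for i in range(min(4, flower_scores.shape[1]))}
        leaf_cols = {f"V{i + 15:02d}": leaf_scores[:, i]
                     for i in range(min(3, leaf_scores.shape[1]))}
        # shapes are generated population-blockwise in the same order as
        # individuals, one shape per individual
        shape_df = pd.DataFrame({**flower_cols, **leaf_cols})
        shape_df.index = base.index
        traits = TraitSet(individuals=pd.concat([base, shape_df], axis=1),
                          trait_classes={**traits.trait_classes,
                                         **{c: "shape_selected" if c == "V15"
                                            else "shape_random"
                                            for c in shape_df.columns}})
        truth.trait_classes = traits.trait_classes
        shapes = {"leaves": leaves, "flowers": flowers,
                  "leaf_pct": leaf_pct, "flower_pct": flower_pct,
                  "aspect_by_pop": aspect_by_pop}
    dataset = Dataset(markers=matrix, populations=pop_map, climate=climate,
                      traits=traits,
                      zero_variance_loci=matrix.zero_variance_loci())
    return dataset, truth, shapes
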