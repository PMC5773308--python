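"""Delimited readers/writers and dataset assembly.

All tables are tab-separated UTF-8 with a header row, '.' decimal and "NA"
as the missing token — the lingua franca for band matrices exported from
fingerprint-scoring software.  The marker table carries one row per
individual with ``individual_id`` and ``population_id`` columns followed by
one 0/1 column per locus.  Outlines and landmark configurations are
two-column x/y files, one file per shape.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .datatypes import (MISSING, ClimateTable, MarkerMatrix, PopulationMap,
                        TraitSet)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Marker matrix
# ---------------------------------------------------------------------------

def write_marker_matrix(matrix: MarkerMatrix, path: str | Path,
                        missing_token: str = "NA") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id\tpopulation_id\t" + "\t".join(matrix.locus_ids) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            vals = [missing_token if v == MISSING else str(int(v))
                    for v in matrix.bands[i]]
            fh.write(f"{ind}\t{matrix.pop_of[ind]}\t" + "\t".join(vals) + "\n")
    if matrix.replicate_pairs:
        with open(path.with_suffix(".replicates.tsv"), "w") as fh:
            fh.write("individual_a\tindividual_b\n")
            for a, b in matrix.replicate_pairs:
                fh.write(f"{a}\t{b}\n")


def read_marker_matrix(path: str | Path, missing_token: str = "NA") -> MarkerMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["individual_id", "population_id"]:
            raise ValueError(f"{path}: marker table must start with "
                             "individual_id and population_id columns")
        locus_ids = header[2:]
        if len(set(locus_ids)) != len(locus_ids):
            seen: set[str] = set()
            dup = next(l for l in locus_ids if l in seen or seen.add(l))
            raise ValueError(f"{path}: duplicated locus id {dup!r}")
        ids, pop_of, rows = [], {}, []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            ind, pop = parts[0], parts[1]
            vals = np.empty(len(locus_ids), dtype=np.int8)
            for j, tok in enumerate(parts[2:]):
                if tok == missing_token:
                    vals[j] = MISSING
                elif tok in ("0", "1"):
                    vals[j] = int(tok)
                else:
                    raise ValueError(
                        f"{path}: non-binary band value {tok!r} at line "
                        f"{lineno} (individual {ind!r}), locus "
                        f"{locus_ids[j]!r}")
            ids.append(ind)
            pop_of[ind] = pop
            rows.append(vals)
    pairs: list[tuple[str, str]] = []
    rep_path = path.with_suffix(".replicates.tsv")
    if rep_path.exists():
        rep = pd.read_csv(rep_path, sep="\t")
        pairs = list(zip(rep["individual_a"], rep["individual_b"]))
    return MarkerMatrix(individual_ids=ids, locus_ids=locus_ids,
                        bands=np.array(rows, dtype=np.int8), pop_of=pop_of,
                        replicate_pairs=pairs)


# ---------------------------------------------------------------------------
# Small tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="NA")


def read_population_map(path: str | Path) -> PopulationMap:
    return PopulationMap(pd.read_csv(path, sep="\t"))


def read_climate_table(path: str | Path) -> ClimateTable:
    return ClimateTable(pd.read_csv(path, sep="\t"))


def read_trait_table(path: str | Path) -> TraitSet:
    return TraitSet(individuals=pd.read_csv(path, sep="\t"))


def write_shapes(shapes: list[tuple[str, np.ndarray]], out_dir: str | Path,
                 prefix: str) -> list[Path]:
    """One two-column x/y file per shape; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (pop, xy) in enumerate(shapes):
        p = out_dir / f"{prefix}_{i + 1:04d}_{pop}.xy"
        np.savetxt(p, xy, fmt="%.8g", delimiter="\t")
        paths.append(p)
    return paths


def read_shape(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    markers: MarkerMatrix
    populations: PopulationMap
    climate: ClimateTable
    traits: TraitSet | None = None
    zero_variance_loci: list[str] = field(default_factory=list)


def load_dataset(paths: dict[str, str | Path],
                 config: PipelineConfig | None = None) -> Dataset:
    """Read and cross-reference the full input bundle.

    ``paths`` needs keys ``markers``, ``populations`` and ``climate``
    (``traits`` optional).  Every individual must map to a known population
    and every population must have climate and coordinates; violations are
    hard errors naming the offender.  Missing band scores are resolved by
    the configured policy (drop the individual, or score as band-absent).
    Zero-variance loci are flagged (kept, but excluded from outlier scans).
    """
    config = config or PipelineConfig()
    markers = read_marker_matrix(paths["markers"], config.missing_token)
    pop_map = read_population_map(paths["populations"])
    climate = read_climate_table(paths["climate"])
    traits = read_trait_table(paths["traits"]) if "traits" in paths else None

    known = set(pop_map.population_ids)
    for ind in markers.individual_ids:
        if markers.pop_of[ind] not in known:
            raise ValueError(f"individual {ind!r} is assigned to unknown "
                             f"population {markers.pop_of[ind]!r}")
    missing_clim = known - set(climate.population_ids)
    if missing_clim:
        raise ValueError(f"populations without climate data: {sorted(missing_clim)}")

    if np.any(markers.bands == MISSING):
        if config.missing_policy == "drop_individual":
            bad = [ind for i, ind in enumerate(markers.individual_ids)
                   if np.any(markers.bands[i] == MISSING)]
            keep = [ind for ind in markers.individual_ids if ind not in set(bad)]
            log.warning("dropping %d individuals with missing scores", len(bad))
            rows = [markers.individual_ids.index(i) for i in keep]
            markers = MarkerMatrix(
                individual_ids=keep, locus_ids=markers.locus_ids,
                bands=markers.bands[rows],
                pop_of={i: markers.pop_of[i] for i in keep},
                replicate_pairs=[(a, b) for a, b in markers.replicate_pairs
                                 if a in set(keep) and b in set(keep)])
        elif config.missing_policy == "as_absence":
            bands = markers.bands.copy()
            bands[bands == MISSING] = 0
            markers = MarkerMatrix(markers.individual_ids, markers.locus_ids,
                                   bands, markers.pop_of, markers.replicate_pairs)
        else:
            raise ValueError(f"unknown missing policy {config.missing_policy!r}")

    return Dataset(markers=markers, populations=pop_map, climate=climate,
                   traits=traits,
                   zero_variance_loci=markers.zero_variance_loci())


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: PipelineConfig | None = None,
                  seed: int | None = None) -> None:
    """Write result tables plus a run manifest to ``out_dir``.

    Each entry of ``tables`` becomes ``<name>.tsv`` with stable column order
    and fixed float precision; the manifest records the configuration, the
    seed and the software version so any run can be reproduced.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")
    for name, df in tables.items():
        write_table(df, out_dir / f"{name}.tsv",
                    index=df.index.name is not None)
    manifest = {
        "software": "divsel",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if config else None,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
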