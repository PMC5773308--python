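"""Core in-memory containers for the selection-scan pipeline.

The pipeline works on four cross-referenced inputs: a binary individuals x
loci band matrix from dominant fingerprinting (AFLP-style), a population map
with coordinates, a per-population climate table, and a per-individual trait
table.  All containers are thin dataclasses around numpy/pandas objects with
explicit validation; missing band scores are encoded as -1 in the int8 band
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class MarkerMatrix:
    """Individuals x loci dominant (band presence/absence) matrix.

    Parameters
    ----------
    individual_ids : list of str
        One id per row of ``bands``.
    locus_ids : list of str
        One id per column of ``bands``.
    bands : ndarray of int8
        Entries in {0, 1} or -1 for a missing score.
    pop_of : dict
        Maps every individual id to its population id.
    replicate_pairs : list of (str, str)
        Ids of replicated individuals (same DNA scored twice), used only for
        the replicate error-rate estimate.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    bands: np.ndarray
    pop_of: dict[str, str]
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.int8)
        if self.bands.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"band matrix shape {self.bands.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.bands, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary band value {self.bands[i, j]} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if len(set(self.locus_ids)) != len(self.locus_ids):
            seen: set[str] = set()
            dup = next(l for l in self.locus_ids if l in seen or seen.add(l))
            raise ValueError(f"duplicated locus id {dup!r}")
        for ind in self.individual_ids:
            if ind not in self.pop_of:
                raise ValueError(f"individual {ind!r} maps to no population")

    # -- convenience views -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population ids in first-appearance order of their individuals."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.pop_of[ind], None)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population's individuals."""
        idx: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individual_ids):
            idx.setdefault(self.pop_of[ind], []).append(i)
        return {p: np.asarray(v, dtype=int) for p, v in idx.items()}

    def pop_sizes(self) -> dict[str, int]:
        return {p: len(v) for p, v in self.pop_indices().items()}

    def subset_pops(self, pops: list[str]) -> "MarkerMatrix":
        keep = [i for i, ind in enumerate(self.individual_ids)
                if self.pop_of[ind] in set(pops)]
        ids = [self.individual_ids[i] for i in keep]
        return MarkerMatrix(
            individual_ids=ids,
            locus_ids=list(self.locus_ids),
            bands=self.bands[keep],
            pop_of={i: self.pop_of[i] for i in ids},
            replicate_pairs=[(a, b) for a, b in self.replicate_pairs
                             if a in set(ids) and b in set(ids)],
        )

    def subset_loci(self, loci: list[str]) -> "MarkerMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        cols = [pos[l] for l in loci]
        return MarkerMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=list(loci),
            bands=self.bands[:, cols],
            pop_of=dict(self.pop_of),
            replicate_pairs=list(self.replicate_pairs),
        )

    def drop_replicates(self) -> "MarkerMatrix":
        """Matrix without the duplicate member of each replicate pair."""
        dup = {b for _, b in self.replicate_pairs}
        keep = [i for i, ind in enumerate(self.individual_ids) if ind not in dup]
        ids = [self.individual_ids[i] for i in keep]
        return MarkerMatrix(
            individual_ids=ids,
            locus_ids=list(self.locus_ids),
            bands=self.bands[keep],
            pop_of={i: self.pop_of[i] for i in ids},
            replicate_pairs=[],
        )

    def zero_variance_loci(self) -> list[str]:
        """Loci monomorphic across all scored individuals (kept but not scanned)."""
        scored = self.bands != MISSING
        any_scored = scored.any(axis=0)
        ones = ((self.bands == 1) & scored).any(axis=0)
        zeros = ((self.bands == 0) & scored).any(axis=0)
        mono = ~any_scored | ~(ones & zeros)
        return [l for l, m in zip(self.locus_ids, mono) if m]


@dataclass
class PopulationMap:
    """Population ids with WGS84 coordinates and sample sizes."""

    table: pd.DataFrame  # columns: population_id, latitude, longitude, n_individuals

    def __post_init__(self) -> None:
        req = {"population_id", "latitude", "longitude", "n_individuals"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"population map missing columns {sorted(missing)}")
        if self.table["population_id"].duplicated().any():
            raise ValueError("duplicated population ids in population map")
        lat = self.table["latitude"].to_numpy(float)
        lon = self.table["longitude"].to_numpy(float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates out of WGS84 bounds")

    @property
    def population_ids(self) -> list[str]:
        return self.table["population_id"].tolist()


@dataclass
class ClimateTable:
    """One row per population: bio01..bio20 plus latitude/longitude."""

    table: pd.DataFrame  # index-free, column population_id + numeric columns

    def __post_init__(self) -> None:
        if "population_id" not in self.table.columns:
            raise ValueError("climate table needs a population_id column")
        if self.table["population_id"].duplicated().any():
            raise ValueError("duplicated population ids in climate table")
        num = self.table.drop(columns=["population_id"])
        if num.isna().any().any():
            col = num.columns[num.isna().any()][0]
            raise ValueError(f"missing climate value in column {col!r}; "
                             "imputation is not performed")

    @property
    def population_ids(self) -> list[str]:
        return self.table["population_id"].tolist()

    @property
    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c != "population_id"]

    def values_for(self, variables: list[str] | None = None) -> pd.DataFrame:
        cols = variables if variables is not None else self.variables
        return self.table.set_index("population_id")[cols]


@dataclass
class TraitSet:
    """Per-individual trait values and their population means.

    ``individuals`` holds one row per individual with a ``population_id``
    column and one column per trait (V01..V17 in the full pipeline).  Shape
    scores (V11..V17) are centered across individuals by construction.
    """

    individuals: pd.DataFrame
    trait_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("individual_id", "population_id"):
            if col not in self.individuals.columns:
                raise ValueError(f"trait table needs column {col!r}")

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.individuals.columns
                if c not in ("individual_id", "population_id")]

    def population_means(self) -> pd.DataFrame:
        """Arithmetic trait means over non-missing individuals, per population."""
        return (self.individuals
                .drop(columns=["individual_id"])
                .groupby("population_id", sort=False)
                .mean())


@dataclass
class DistMatrix:
    """Symmetric population-level distance / differentiation matrix."""

    labels: list[str]
    values: np.ndarray
    kind: str  # phi_pt | geo_km | bray_curtis_individual

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def reorder(self, labels: list[str]) -> "DistMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[l] for l in labels]
        return DistMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]
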