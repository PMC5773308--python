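"""Structured run configuration.

A single dataclass holds every tunable of the pipeline.  Defaults reproduce
the published analysis settings: 1,000,000 neutral simulations with a 0.95
confidence envelope and FDR 0.05 for the F_ST-outlier search, an MCMC
schedule of 250,000 iterations with 50,000 burn-in and thinning 20 after
50 pilot runs of 5,000 iterations, and 9,999 permutations for the
distance-matrix tests.  Configs round-trip through YAML; command-line flags
override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class MCMCSchedule:
    iterations: int = 250_000
    burn_in: int = 50_000
    thinning: int = 20
    n_pilot: int = 50
    pilot_length: int = 5_000

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PipelineConfig:
    seed: int = 0
    # F_ST-envelope outlier search
    n_envelope_sims: int = 1_000_000
    envelope_ci: float = 0.95
    fdr: float = 0.05
    trim_max_iter: int = 5
    he_window: int = 2_000
    # Bayesian F-model
    mcmc: MCMCSchedule = field(default_factory=MCMCSchedule)
    prior_odds: float = 10.0
    bayes_q_threshold: float = 0.05
    # logistic environment-association scan
    assoc_alpha: float = 0.05
    assoc_rule: str = "both"  # require G AND Wald below the Bonferroni level
    # distance-matrix inference
    n_permutations: int = 9_999
    alpha: float = 0.05
    mantel_matrix: str = "phi_pt"
    # consensus partition rules: each rule intersects the named detectors
    partition_rules: tuple[tuple[str, ...], ...] = (
        ("fdist", "bayes"),
        ("fdist", "bayes", "scan"),
        ("scan",),
    )
    # which detectors to run (fdist = envelope simulation, bayes = F-model,
    # scan = logistic environment association)
    detectors: tuple[str, ...] = ("fdist", "bayes", "scan")
    # data handling
    missing_token: str = "NA"
    missing_policy: str = "drop_individual"  # or "as_absence"
    inbreeding_f: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = MCMCSchedule(**raw["mcmc"])
        if "partition_rules" in raw:
            raw["partition_rules"] = tuple(tuple(r) for r in raw["partition_rules"])
        if "detectors" in raw:
            raw["detectors"] = tuple(raw["detectors"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
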