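"""Threshold configuration.

Every numeric cutoff used by the analysis lives in :class:`ThresholdConfig`
so that a run is fully described by one small config file.  Defaults follow
standard practice in genome-resolved rumen metagenomics: 95% ANI delimits a
species, MAG quality requires >=90% completeness and <=5% contamination,
presence requires >=90% breadth of coverage, co-abundance edges require
Spearman rho >= 0.75, core genera require 80% host prevalence and support
from at least two source datasets, 16S BLAST evidence requires alignments
>=250 bp at >=90% identity, and discoveries are controlled at BH-FDR 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class ThresholdConfig:
    #: ANI fraction at/above which two genomes belong to one species cluster.
    ani_species: float = 0.95
    #: minimum CheckM completeness (percent) for a high-quality genome.
    quality_completeness_min: float = 90.0
    #: maximum CheckM contamination (percent) for a high-quality genome.
    quality_contamination_max: float = 5.0
    #: minimum breadth of coverage (fraction) for a presence call.
    breadth_presence_min: float = 0.90
    #: minimum Spearman rho for a co-abundance network edge.
    spearman_edge_min: float = 0.75
    #: minimum fraction of hosts for the prevalence-based core source.
    core_prevalence_min: float = 0.80
    #: number of source datasets a core genus must appear in.
    core_min_datasets: int = 2
    #: minimum BLAST alignment length (bp) for a core-ESV hit.
    blast_len_min: int = 250
    #: minimum BLAST percent identity for a core-ESV hit.
    blast_ident_min: float = 90.0
    #: BH false-discovery-rate threshold.
    fdr_alpha: float = 0.05
    #: random seed for Louvain community detection.
    louvain_seed: int = 1
    #: Louvain resolution parameter.
    louvain_resolution: float = 1.0
    #: stepwise completeness at/above which a KEGG module counts as complete.
    module_complete_cutoff: float = 0.75

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("ani_species", "breadth_presence_min",
                     "core_prevalence_min", "fdr_alpha",
                     "module_complete_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0,1], got {v}")
        if not -1.0 <= self.spearman_edge_min <= 1.0:
            raise ValueError("spearman_edge_min must be a correlation in [-1,1]")
        for name in ("quality_completeness_min", "quality_contamination_max",
                     "blast_ident_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percent in [0,100], got {v}")
        for name in ("core_min_datasets", "blast_len_min"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.louvain_resolution <= 0:
            raise ValueError("louvain_resolution must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
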