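"""Shared domain dataclasses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

#: Recognized genome collections.  "study" marks genomes assembled in the
#: longitudinal experiment itself; the rest are published rumen collections.
DATASETS = ("study", "hungate1000", "stewart2018", "stewart2019", "xie2021",
            "other")

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus",
                   "species")

#: Diet phases across the 14 sampling time points (days 2-750 after birth).
DIETS = ("colostrum", "milk_grain", "grain", "low_fiber", "high_fiber")


class TimePoint(NamedTuple):
    tp: int
    day: int
    diet: str


#: The sampling grid: 14 time points over ~750 days, spanning five diet
#: phases (colostrum first days, milk replacer + grain to day 60, starter
#: grain to day 90, low-fiber ration to day 180, high-fiber ration to ~725
#: days, then back to a low-fiber lactation ration).
DEFAULT_TIMEPOINTS: tuple[TimePoint, ...] = (
    TimePoint(1, 2, "colostrum"),
    TimePoint(2, 5, "milk_grain"),
    TimePoint(3, 15, "milk_grain"),
    TimePoint(4, 25, "milk_grain"),
    TimePoint(5, 50, "milk_grain"),
    TimePoint(6, 70, "grain"),
    TimePoint(7, 100, "low_fiber"),
    TimePoint(8, 130, "low_fiber"),
    TimePoint(9, 170, "low_fiber"),
    TimePoint(10, 200, "high_fiber"),
    TimePoint(11, 300, "high_fiber"),
    TimePoint(12, 400, "high_fiber"),
    TimePoint(13, 700, "high_fiber"),
    TimePoint(14, 750, "low_fiber"),
)


@dataclass
class GenomeRecord:
    """One genome (MAG or isolate) with quality metrics and provenance."""

    genome_id: str
    dataset: str
    completeness: float   # percent, CheckM-style
    contamination: float  # percent
    n50: int              # bp
    genome_size: int      # bp
    n_contigs: int
    taxonomy: str         # 7-rank ';'-separated string, empty ranks allowed

    def __post_init__(self) -> None:
        if self.dataset not in DATASETS:
            raise ValueError(
                f"{self.genome_id}: unknown dataset {self.dataset!r}")
        if self.genome_size <= 0:
            raise ValueError(f"{self.genome_id}: genome_size must be > 0")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if self.contamination < 0:
            raise ValueError(f"{self.genome_id}: contamination must be >= 0")

    def rank(self, rank: str) -> str:
        """Return one taxonomic rank label ('' if unassigned)."""
        idx = TAXONOMIC_RANKS.index(rank)
        parts = self.taxonomy.split(";")
        return parts[idx].strip() if idx < len(parts) else ""


@dataclass
class SampleMeta:
    sample_id: str
    animal_id: str
    day: int
    tp: int
    diet: str

    def __post_init__(self) -> None:
        if not 1 <= self.tp <= 14:
            raise ValueError(f"{self.sample_id}: tp must be in 1..14")
        if self.diet not in DIETS:
            raise ValueError(f"{self.sample_id}: unknown diet {self.diet!r}")


@dataclass(frozen=True)
class BlastHit:
    """One BLASTn (outfmt 6) hit of a core 16S ESV against a genome."""

    esv_id: str
    genome_id: str
    pident: float  # percent identity
    length: int    # alignment length, bp

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError("pident must be in [0,100]")
        if self.length < 0:
            raise ValueError("length must be >= 0")


@dataclass
class SpeciesCluster:
    """An ANI-connected set of genomes collapsed into one species."""

    cluster_id: int
    members: frozenset[str]
    representative: str | None = None
    is_novel: bool | None = None
    datasets_present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster members must be non-empty")
        if self.representative is not None \
                and self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass
class CoreGenusSet:
    """Core genera with per-genus provenance (which sources back each)."""

    genera: set[str]
    provenance: dict[str, set[str]]


@dataclass
class EnrichmentResult:
    """One hypergeometric over-representation test.

    k successes among n draws from an urn of N items of which K are
    successes; q is the BH-adjusted p; gene_ratio = k/n.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float = float("nan")
    gene_ratio: float = float("nan")
    group: str | None = None


class Reaction(NamedTuple):
    """A metabolic reaction as substrate/product metabolite sets."""

    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
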