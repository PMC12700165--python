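"""Species-level dereplication of genome collections.

Genomes passing quality filters are clustered into species by
single-linkage connected components over pairwise ANI edges at the 95%
species threshold.  Each cluster receives a quality-scored representative
and a novelty flag: a species is *novel* when every member was assembled
in the longitudinal study itself, i.e. no published rumen collection
contains an overlapping genome at >=95% ANI.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import pandas as pd

from .config import ThresholdConfig
from .errors import ConsistencyError
from .types import GenomeRecord, SpeciesCluster


def filter_high_quality(records: list[GenomeRecord],
                        cfg: ThresholdConfig) -> list[GenomeRecord]:
    """Keep genomes with completeness >= min and contamination <= max.

    Both boundaries are inclusive (>=90% complete, <=5% contaminated by
    default).
    """
    return [r for r in records
            if r.completeness >= cfg.quality_completeness_min
            and r.contamination <= cfg.quality_contamination_max]


def cluster_by_ani(edges: list[tuple[str, str, float]],
                   genomes: list[str],
                   cfg: ThresholdConfig) -> list[SpeciesCluster]:
    """Cluster genomes into species as ANI connected components.

    Edges with ani >= ``cfg.ani_species`` link genomes; components of the
    resulting graph are species clusters, genomes without a qualifying
    edge become singletons.  Cluster ids are assigned by lexicographically
    smallest member, so the output is independent of input order.
    """
    known = set(genomes)
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    for a, b, ani in edges:
        if a not in known or b not in known:
            missing = a if a not in known else b
            raise ConsistencyError(
                f"ANI edge references unknown genome {missing!r}")
        if ani >= cfg.ani_species:
            graph.add_edge(a, b)
    components = sorted((frozenset(c) for c in nx.connected_components(graph)),
                        key=min)
    return [SpeciesCluster(cluster_id=i, members=members)
            for i, members in enumerate(components, start=1)]


def select_representative(cluster: SpeciesCluster,
                          records: dict[str, GenomeRecord]) -> str:
    """Pick the member maximizing completeness - 5 x contamination.

    Ties go to the larger N50, then to the lexicographically smallest
    genome id.
    """
    def key(genome_id: str):
        r = records[genome_id]
        return (-(r.completeness - 5.0 * r.contamination), -r.n50, genome_id)

    return min(cluster.members, key=key)


def annotate_clusters(clusters: list[SpeciesCluster],
                      records: dict[str, GenomeRecord],
                      ) -> list[SpeciesCluster]:
    """Fill in representatives and datasets_present for every cluster."""
    for c in clusters:
        c.representative = select_representative(c, records)
        c.datasets_present = frozenset(records[g].dataset for g in c.members)
    return clusters


def flag_novelty(clusters: list[SpeciesCluster]) -> list[SpeciesCluster]:
    """Mark clusters whose members all come from the study itself."""
    for c in clusters:
        if not c.datasets_present:
            raise ValueError(
                f"cluster {c.cluster_id}: datasets_present not populated")
        c.is_novel = c.datasets_present == frozenset({"study"})
    return clusters


def overlap_counts(clusters: list[SpeciesCluster]) -> pd.DataFrame:
    """Count clusters per exclusive dataset combination (UpSet-style).

    Each cluster contributes to exactly one combination — the set of
    datasets its members come from — so counts sum to the number of
    clusters.
    """
    counter = Counter("+".join(sorted(c.datasets_present)) for c in clusters)
    rows = sorted(counter.items())
    return pd.DataFrame(rows, columns=["dataset_combo", "n_clusters"])


def dereplicate(records: list[GenomeRecord],
                edges: list[tuple[str, str, float]],
                cfg: ThresholdConfig) -> list[SpeciesCluster]:
    """Quality-filter, cluster, annotate and novelty-flag in one call."""
    hq = filter_high_quality(records, cfg)
    hq_ids = {r.genome_id for r in hq}
    hq_edges = [(a, b, v) for a, b, v in edges
                if a in hq_ids and b in hq_ids]
    clusters = cluster_by_ani(hq_edges, sorted(hq_ids), cfg)
    annotate_clusters(clusters, {r.genome_id: r for r in hq})
    return flag_novelty(clusters)


def clusters_frame(clusters: list[SpeciesCluster]) -> pd.DataFrame:
    """Long-format cluster membership table."""
    rows = []
    for c in clusters:
        for g in sorted(c.members):
            rows.append((c.cluster_id, g, g == c.representative,
                         bool(c.is_novel)))
    return pd.DataFrame(rows, columns=["cluster_id", "genome_id",
                                       "is_representative", "is_novel"])
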