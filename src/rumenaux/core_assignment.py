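"""Core-microbiome genus list and per-genome core flags.

The core genus list combines three sources: two published core-taxa
lists and a host-prevalence criterion (genera present in at least 80% of
sampled animals).  A genus is core when backed by at least two of the
three sources.  Individual genomes are then flagged core when a 16S ESV
from a core genus hits them by BLAST with alignment length >= 250 bp and
identity >= 90%.
"""

from __future__ import annotations

from .config import ThresholdConfig
from .io import warn
from .types import BlastHit, CoreGenusSet


def derive_core_genera(source1: set[str], source2: set[str],
                       prevalence: dict[str, float],
                       cfg: ThresholdConfig) -> CoreGenusSet:
    """Apply the two-of-three rule across the core sources.

    The third source is derived from ``prevalence``: genera at or above
    ``cfg.core_prevalence_min`` fraction of hosts.  Provenance records
    which sources back each core genus.
    """
    bad = [g for g, p in prevalence.items() if not 0.0 <= p <= 1.0]
    if bad:
        raise ValueError(f"prevalence out of [0,1] for genus {bad[0]!r}")
    source3 = {g for g, p in prevalence.items()
               if p >= cfg.core_prevalence_min}
    sources = {"source1": source1, "source2": source2,
               "prevalence": source3}
    provenance: dict[str, set[str]] = {}
    for name, genera in sources.items():
        for genus in genera:
            provenance.setdefault(genus, set()).add(name)
    core = {g for g, names in provenance.items()
            if len(names) >= cfg.core_min_datasets}
    return CoreGenusSet(genera=core,
                        provenance={g: provenance[g] for g in core})


def assign_core_flags(hits: list[BlastHit], core_esvs: dict[str, str],
                      cfg: ThresholdConfig,
                      genomes: list[str] | None = None) -> dict[str, bool]:
    """Flag genomes hit by a core-genus ESV at the length/identity cutoffs.

    One passing hit (length >= 250 bp and identity >= 90%, both
    inclusive) suffices.  Hits from ESVs absent from ``core_esvs`` are
    skipped with a warning.  If ``genomes`` is given, the returned map
    covers all of them (False where no passing hit exists).
    """
    flags: dict[str, bool] = dict.fromkeys(genomes or [], False)
    for hit in hits:
        if hit.esv_id not in core_esvs:
            warn(f"skipping hit from unknown ESV {hit.esv_id!r}")
            continue
        passing = (hit.length >= cfg.blast_len_min
                   and hit.pident >= cfg.blast_ident_min)
        if passing:
            flags[hit.genome_id] = True
        else:
            flags.setdefault(hit.genome_id, False)
    return flags
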