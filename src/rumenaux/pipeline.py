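"""End-to-end pipeline over a bundle directory.

Stages run in dependency order (derep -> abundance -> core -> cluster ->
enrich -> modules -> complement).  Each stage reads the tabular inputs
it needs from the input directory, writes TSV outputs to the output
directory, and records content checksums of its inputs in a manifest so
unchanged stages are skipped on re-runs.  Any stage failure aborts the
run with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import abundance as ab_mod
from . import complementarity as compl
from . import core_assignment as core_mod
from . import dereplication as derep_mod
from . import enrichment as enr
from . import io as rio
from . import kegg_modules as kmod
from . import temporal_clustering as tclust
from .config import ThresholdConfig
from .errors import StageError

STAGE_ORDER = ("derep", "abundance", "core", "cluster", "enrich",
               "modules", "complement")

STAGE_INPUTS = {
    "derep": ["genomes.tsv", "ani.tsv"],
    "abundance": ["depth.tsv", "library_sizes.tsv", "sample_meta.tsv",
                  "genomes.tsv", "ani.tsv"],
    "core": ["core_source1.txt", "core_source2.txt", "prevalence.tsv",
             "esv_map.tsv", "blast_hits.tsv", "genomes.tsv"],
    "cluster": ["depth.tsv", "library_sizes.tsv", "sample_meta.tsv"],
    "enrich": ["genomes.tsv", "ani.tsv", "group_functions.tsv",
               "cluster_gene_functions.tsv", "depth.tsv",
               "library_sizes.tsv", "sample_meta.tsv"],
    "modules": ["module_definitions.tsv", "ko_annotations.tsv"],
    "complement": ["ko_annotations.tsv", "module_definitions.tsv",
                   "reactions.tsv", "depth.tsv", "sample_meta.tsv",
                   "genomes.tsv", "ani.tsv"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_signature(stage: str, indir: Path,
                     cfg: ThresholdConfig) -> dict[str, str]:
    sig = {"config": json.dumps(dataclasses.asdict(cfg), sort_keys=True)}
    for name in STAGE_INPUTS[stage]:
        path = indir / name
        sig[name] = _sha256(path) if path.exists() else "missing"
    return sig


# --- shared helpers --------------------------------------------------------


def _dereplicate(indir: Path, cfg: ThresholdConfig):
    records = rio.read_genome_table(indir / "genomes.tsv")
    edges = rio.read_ani_table(indir / "ani.tsv")
    return records, derep_mod.dereplicate(records, edges, cfg)


def _genome_groups(indir: Path, cfg: ThresholdConfig) -> dict[str, str]:
    """Genome -> auxiliary/non_auxiliary from novelty of its species
    cluster (auxiliary = member of a novel, study-only species)."""
    _, clusters = _dereplicate(indir, cfg)
    groups = {}
    for c in clusters:
        label = "auxiliary" if c.is_novel else "non_auxiliary"
        for g in c.members:
            groups[g] = label
    return groups


def _abundance_inputs(indir: Path, cfg: ThresholdConfig):
    depth, breadth = rio.read_depth_table(indir / "depth.tsv")
    lib = pd.read_csv(indir / "library_sizes.tsv", sep="\t",
                      index_col="sample_id")["library_size"]
    meta = rio.read_sample_meta(indir / "sample_meta.tsv")
    norm = ab_mod.normalize_depth(depth, lib)
    presence = ab_mod.compute_presence(breadth, cfg)
    rel = ab_mod.relative_abundance(norm, presence)
    return rel, presence, meta


# --- stages ----------------------------------------------------------------


def stage_derep(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    _, clusters = _dereplicate(indir, cfg)
    derep_mod.clusters_frame(clusters).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    derep_mod.overlap_counts(clusters).to_csv(
        outdir / "overlaps.tsv", sep="\t", index=False)


def stage_abundance(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    rel, presence, meta = _abundance_inputs(indir, cfg)
    presence.stack().rename("present").reset_index().to_csv(
        outdir / "presence.tsv", sep="\t", index=False)
    rel.stack().rename("abundance").reset_index().to_csv(
        outdir / "abundance.tsv", sep="\t", index=False,
        float_format="%.10g")
    groups = _genome_groups(indir, cfg)
    groups = {g: groups[g] for g in rel.index}
    ab_mod.group_abundance_by_tp(rel, groups, meta).to_csv(
        outdir / "group_by_tp.tsv", sep="\t", float_format="%.10g")
    records = {r.genome_id: r
               for r in rio.read_genome_table(indir / "genomes.tsv")}
    taxonomy = {g: records[g].rank("class") for g in rel.index
                if g in records}
    rio.write_matrix(ab_mod.taxon_aggregate(rel, taxonomy, "class"),
                     outdir / "class_abundance.tsv", index_name="class")


def stage_core(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    source1 = rio.read_genus_list(indir / "core_source1.txt")
    source2 = rio.read_genus_list(indir / "core_source2.txt")
    prevalence = rio.read_prevalence_table(indir / "prevalence.tsv")
    core = core_mod.derive_core_genera(source1, source2, prevalence, cfg)
    pd.DataFrame(
        [(g, ",".join(sorted(core.provenance[g]))) for g in sorted(core.genera)],
        columns=["genus", "sources"]).to_csv(
        outdir / "core_genera.tsv", sep="\t", index=False)
    esv_map = rio.read_esv_map(indir / "esv_map.tsv")
    core_esvs = {e: g for e, g in esv_map.items() if g in core.genera}
    hits = rio.read_blast_tabular(indir / "blast_hits.tsv")
    genomes = [r.genome_id
               for r in rio.read_genome_table(indir / "genomes.tsv")]
    flags = core_mod.assign_core_flags(hits, core_esvs, cfg, genomes=genomes)
    pd.DataFrame(sorted(flags.items()),
                 columns=["genome_id", "is_core"]).to_csv(
        outdir / "core_flags.tsv", sep="\t", index=False)


def stage_cluster(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    rel, _, meta = _abundance_inputs(indir, cfg)
    profiles = tclust.tp_profiles(rel, meta)
    corr = tclust.spearman_matrix(profiles)
    net = tclust.build_network(corr, cfg)
    pd.DataFrame([(a, b, d["weight"]) for a, b, d in net.edges(data=True)],
                 columns=["genome_a", "genome_b", "weight"]).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False,
        float_format="%.10g")
    assignment = tclust.detect_communities(net, cfg)
    pd.DataFrame(sorted(assignment.items()),
                 columns=["genome_id", "cluster_id"]).to_csv(
        outdir / "cluster_membership.tsv", sep="\t", index=False)
    tclust.cluster_peaks(assignment, rel, meta).to_csv(
        outdir / "cluster_summary.tsv", sep="\t", float_format="%.10g")


def stage_enrich(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    records, clusters = _dereplicate(indir, cfg)
    by_id = {r.genome_id: r for r in records}
    families = {c.representative: by_id[c.representative].rank("family")
                for c in clusters}
    novelty = {c.representative: bool(c.is_novel) for c in clusters}
    fam = enr.family_novelty_enrichment(families, novelty, cfg)
    enr.results_frame(fam, cfg).to_csv(outdir / "family_enrichment.tsv",
                                       sep="\t", index=False,
                                       float_format="%.10g")
    groups = _genome_groups(indir, cfg)
    gf = rio.read_function_table(indir / "group_functions.tsv")
    fn_sets = {g: set(fs) for g, fs in gf.items()}
    res = enr.group_function_enrichment(
        fn_sets, {g: groups[g] for g in fn_sets}, cfg)
    enr.results_frame(res, cfg).to_csv(
        outdir / "group_function_enrichment.tsv", sep="\t", index=False,
        float_format="%.10g")
    enr.top_enriched(res, cfg).to_csv(outdir / "top_functions.tsv",
                                      sep="\t", index=False,
                                      float_format="%.10g")
    if not (outdir / "cluster_membership.tsv").exists():
        stage_cluster(indir, outdir, cfg)
    membership = pd.read_csv(outdir / "cluster_membership.tsv", sep="\t")
    assignment = dict(zip(membership["genome_id"],
                          membership["cluster_id"]))
    cgf = rio.read_function_table(indir / "cluster_gene_functions.tsv")
    cres = enr.cluster_function_enrichment(assignment, cgf, cfg)
    enr.results_frame(cres, cfg).to_csv(
        outdir / "cluster_function_enrichment.tsv", sep="\t", index=False,
        float_format="%.10g")


def stage_modules(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    defs = kmod.parse_module_table(
        rio.read_module_definitions(indir / "module_definitions.tsv"))
    ko_counts = rio.read_ko_table(indir / "ko_annotations.tsv")
    ko_sets = {g: set(kos) for g, kos in ko_counts.items()}
    comp, complete = kmod.completeness_matrix(
        defs, ko_sets, complete_cutoff=cfg.module_complete_cutoff)
    rio.write_matrix(comp, outdir / "module_completeness.tsv",
                     index_name="genome_id")
    rio.write_matrix(complete.astype(int), outdir / "module_complete.tsv",
                     index_name="genome_id")


def stage_complement(indir: Path, outdir: Path, cfg: ThresholdConfig) -> None:
    defs = kmod.parse_module_table(
        rio.read_module_definitions(indir / "module_definitions.tsv"))
    ko_counts = rio.read_ko_table(indir / "ko_annotations.tsv")
    ko_sets = {g: set(kos) for g, kos in ko_counts.items()}
    groups = _genome_groups(indir, cfg)
    aux_sets = {g: k for g, k in ko_sets.items()
                if groups.get(g) == "auxiliary"}
    target_sets = {g: k for g, k in ko_sets.items()
                   if groups.get(g) == "non_auxiliary"}
    table = rio.read_reaction_table(indir / "reactions.tsv")
    records = compl.pairwise_records(aux_sets, target_sets, defs,
                                     reaction_table=table)
    records.to_csv(outdir / "complementarity_records.tsv", sep="\t",
                   index=False, float_format="%.10g")
    _, presence, meta = _abundance_inputs(indir, cfg)
    tp_presence = compl.presence_by_tp(presence, meta)
    raw, zs, n_contrib = compl.aggregate_contribution_by_tp(records,
                                                            tp_presence)
    rio.write_matrix(raw, outdir / "contribution_by_module_raw.tsv",
                     index_name="module_id")
    rio.write_matrix(zs, outdir / "contribution_by_module_z.tsv",
                     index_name="module_id")
    n_contrib.rename("n_contributors").to_frame().to_csv(
        outdir / "n_contributors.tsv", sep="\t")
    craw, cz = compl.rank_contributors(records, tp_presence)
    rio.write_matrix(craw, outdir / "contributors_by_genome_raw.tsv",
                     index_name="aux_genome")
    rio.write_matrix(cz, outdir / "contributors_by_genome_z.tsv",
                     index_name="aux_genome")
    persistent = compl.persistent_contributors(records, tp_presence)
    pd.DataFrame({"aux_genome": sorted(persistent)}).to_csv(
        outdir / "persistent_contributors.tsv", sep="\t", index=False)


STAGE_FUNCS = {
    "derep": stage_derep,
    "abundance": stage_abundance,
    "core": stage_core,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "modules": stage_modules,
    "complement": stage_complement,
}

STAGE_OUTPUTS = {
    "derep": ["clusters.tsv", "overlaps.tsv"],
    "abundance": ["presence.tsv", "abundance.tsv", "group_by_tp.tsv",
                  "class_abundance.tsv"],
    "core": ["core_genera.tsv", "core_flags.tsv"],
    "cluster": ["network_edges.tsv", "cluster_membership.tsv",
                "cluster_summary.tsv"],
    "enrich": ["family_enrichment.tsv", "group_function_enrichment.tsv",
               "top_functions.tsv", "cluster_function_enrichment.tsv"],
    "modules": ["module_completeness.tsv", "module_complete.tsv"],
    "complement": ["complementarity_records.tsv",
                   "contribution_by_module_raw.tsv",
                   "contribution_by_module_z.tsv", "n_contributors.tsv",
                   "contributors_by_genome_raw.tsv",
                   "contributors_by_genome_z.tsv",
                   "persistent_contributors.tsv"],
}


def run_stage(stage: str, indir: str | Path, outdir: str | Path,
              cfg: ThresholdConfig | None = None) -> None:
    """Run one stage, translating any failure into a StageError."""
    cfg = cfg or ThresholdConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        STAGE_FUNCS[stage](indir, outdir, cfg)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc


def run_all(indir: str | Path, outdir: str | Path,
            cfg: ThresholdConfig | None = None,
            force: bool = False) -> dict:
    """Run every stage in order with checksum-based skip logic.

    Returns the manifest (per-stage input signatures and statuses).
    A stage is skipped when its input signatures match the previous run
    and all its outputs exist.
    """
    cfg = cfg or ThresholdConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
    manifest = {"stages": {}, "order": list(STAGE_ORDER)}
    for stage in STAGE_ORDER:
        sig = _stage_signature(stage, indir, cfg)
        outputs_exist = all((outdir / f).exists()
                            for f in STAGE_OUTPUTS[stage])
        prior = previous.get("stages", {}).get(stage, {})
        if not force and outputs_exist and prior.get("signature") == sig:
            manifest["stages"][stage] = {"signature": sig,
                                         "status": "skipped"}
            continue
        run_stage(stage, indir, outdir, cfg)
        manifest["stages"][stage] = {"signature": sig, "status": "run"}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
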