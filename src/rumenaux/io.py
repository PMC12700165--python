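"""Typed readers and writers for the pipeline's tabular artifacts.

All inputs and outputs are UTF-8, tab-delimited text with a header row;
lines starting with '#' are treated as comments and skipped.  Readers
validate schemas eagerly and raise :class:`~rumenaux.errors.SchemaError` /
:class:`~rumenaux.errors.TableParseError` with the offending column or row.
Matrix writers print 10 significant digits so that write -> read round-trips
are exact at that precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, TableParseError
from .types import BlastHit, GenomeRecord, Reaction

_FLOAT_FMT = "%.10g"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kwargs)


def _require_columns(df: pd.DataFrame, required: Iterable[str],
                     path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) "
                          f"{', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & (df[column] != "")
    bad |= (df[column] == "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableParseError(
            f"{path}: non-numeric value {df[column].iloc[row]!r} in column "
            f"'{column}' at data row {row + 1}")
    return out


# ---------------------------------------------------------------------------
# genome quality table


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read a genome quality table into :class:`GenomeRecord` objects.

    Required columns: genome_id, dataset, completeness, contamination,
    n50, genome_size, n_contigs, taxonomy.  Duplicate genome ids are
    rejected.
    """
    df = _read_tsv(path)
    required = ("genome_id", "dataset", "completeness", "contamination",
                "n50", "genome_size", "n_contigs", "taxonomy")
    _require_columns(df, required, path)
    dupes = df["genome_id"][df["genome_id"].duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicate genome_id {dupes.iloc[0]!r}")
    numeric = {c: _numeric(df, c, path)
               for c in ("completeness", "contamination", "n50",
                         "genome_size", "n_contigs")}
    records = []
    for i in range(len(df)):
        records.append(GenomeRecord(
            genome_id=df["genome_id"].iloc[i],
            dataset=df["dataset"].iloc[i],
            completeness=float(numeric["completeness"].iloc[i]),
            contamination=float(numeric["contamination"].iloc[i]),
            n50=int(numeric["n50"].iloc[i]),
            genome_size=int(numeric["genome_size"].iloc[i]),
            n_contigs=int(numeric["n_contigs"].iloc[i]),
            taxonomy=df["taxonomy"].iloc[i],
        ))
    return records


def write_genome_table(records: Iterable[GenomeRecord],
                       path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# pairwise ANI table


def read_ani_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read pairwise ANI values as undirected edges.

    The ani column may be a fraction (0-1) or a percent (0-100); the
    dialect is auto-detected (a maximum above 1.5 means percent).  Self
    pairs are dropped; when both directions of a pair are present the
    larger value is kept.
    """
    df = _read_tsv(path)
    _require_columns(df, ("genome_a", "genome_b", "ani"), path)
    ani = _numeric(df, "ani", path).to_numpy(dtype=float)
    if len(ani) and (ani.min() < 0 or ani.max() > 100):
        raise ValueError(f"{path}: ani values must lie in [0,100]")
    if len(ani) and ani.max() > 1.5:  # percent dialect
        ani = ani / 100.0
    best: dict[tuple[str, str], float] = {}
    for a, b, v in zip(df["genome_a"], df["genome_b"], ani):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if v > best.get(key, -1.0):
            best[key] = float(v)
    return [(a, b, v) for (a, b), v in sorted(best.items())]


def write_ani_table(edges: Iterable[tuple[str, str, float]],
                    path: str | Path) -> None:
    df = pd.DataFrame(edges, columns=["genome_a", "genome_b", "ani"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# depth / breadth table


def read_depth_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format depth table into dense depth and breadth matrices.

    Input columns: genome_id, sample_id, mean_depth (>=0), breadth
    ([0,1]).  Genome-sample pairs absent from the file get depth 0 and
    breadth 0.  Returns ``(depth, breadth)`` as genome x sample frames
    with sorted axes.
    """
    df = _read_tsv(path)
    _require_columns(df, ("genome_id", "sample_id", "mean_depth", "breadth"),
                     path)
    depth = _numeric(df, "mean_depth", path)
    breadth = _numeric(df, "breadth", path)
    if (depth < 0).any():
        raise ValueError(f"{path}: mean_depth must be >= 0")
    if (breadth < 0).any() or (breadth > 1).any():
        raise ValueError(f"{path}: breadth must lie in [0,1]")
    long = pd.DataFrame({"genome_id": df["genome_id"],
                         "sample_id": df["sample_id"],
                         "mean_depth": depth, "breadth": breadth})
    depth_m = long.pivot_table(index="genome_id", columns="sample_id",
                               values="mean_depth", fill_value=0.0,
                               aggfunc="max").sort_index(axis=0).sort_index(axis=1)
    breadth_m = long.pivot_table(index="genome_id", columns="sample_id",
                                 values="breadth", fill_value=0.0,
                                 aggfunc="max").sort_index(axis=0).sort_index(axis=1)
    return depth_m, breadth_m


def write_depth_table(depth: pd.DataFrame, breadth: pd.DataFrame,
                      path: str | Path) -> None:
    long = depth.stack().rename("mean_depth").to_frame()
    long["breadth"] = breadth.stack()
    long = long.reset_index()
    long.columns = ["genome_id", "sample_id", "mean_depth", "breadth"]
    long.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def _subject_genome(sseqid: str) -> str:
    # concatenated-contig databases name subjects "<genome>|<contig>"
    return sseqid.split("|", 1)[0].split()[0]


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Read standard 12-column BLAST outfmt-6 hits.

    The subject genome id is the sseqid prefix before the first '|' or
    whitespace.  Lines with fewer than 12 columns raise a format error
    naming the line.
    """
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise TableParseError(
                    f"{path}: line {lineno}: expected 12 BLAST outfmt-6 "
                    f"columns, found {len(fields)}")
            try:
                pident = float(fields[2])
                length = int(fields[3])
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {lineno}: {exc}") from exc
            hits.append(BlastHit(esv_id=fields[0],
                                 genome_id=_subject_genome(fields[1]),
                                 pident=pident, length=length))
    return hits


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, animal_id, day, tp, diet).

    Returns a frame indexed by sample_id.  Within each animal, day must
    increase strictly with tp.
    """
    df = _read_tsv(path)
    _require_columns(df, ("sample_id", "animal_id", "day", "tp", "diet"), path)
    day = _numeric(df, "day", path).astype(int)
    tp = _numeric(df, "tp", path).astype(int)
    meta = pd.DataFrame({"animal_id": df["animal_id"].to_numpy(),
                         "day": day.to_numpy(), "tp": tp.to_numpy(),
                         "diet": df["diet"].to_numpy()},
                        index=pd.Index(df["sample_id"], name="sample_id"))
    if (meta["tp"] < 1).any() or (meta["tp"] > 14).any():
        raise ValueError(f"{path}: tp must lie in 1..14")
    for animal, sub in meta.groupby("animal_id"):
        sub = sub.sort_values("tp")
        if (sub["day"].diff().dropna() <= 0).any():
            raise ValueError(
                f"{path}: day must increase strictly with tp for animal "
                f"{animal}")
    return meta.sort_index()


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# KO annotations, module definitions, reactions, functions


def read_ko_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read per-genome KO copy counts (genome_id, ko, count)."""
    df = _read_tsv(path)
    _require_columns(df, ("genome_id", "ko", "count"), path)
    count = _numeric(df, "count", path).astype(int)
    if (count < 1).any():
        raise ValueError(f"{path}: KO copy counts must be >= 1")
    out: dict[str, dict[str, int]] = {}
    for g, k, c in zip(df["genome_id"], df["ko"], count):
        out.setdefault(g, {})[k] = out.get(g, {}).get(k, 0) + int(c)
    return out


def write_ko_table(ko_counts: dict[str, dict[str, int]],
                   path: str | Path) -> None:
    rows = [(g, k, c) for g in sorted(ko_counts)
            for k, c in sorted(ko_counts[g].items())]
    pd.DataFrame(rows, columns=["genome_id", "ko", "count"]).to_csv(
        path, sep="\t", index=False)


def read_module_definitions(path: str | Path) -> pd.DataFrame:
    """Read KEGG module definitions (module_id, name, definition)."""
    df = _read_tsv(path)
    _require_columns(df, ("module_id", "name", "definition"), path)
    return df[["module_id", "name", "definition"]]


def read_reaction_table(path: str | Path,
                        currency: set[str] | None = None,
                        ) -> dict[str, list[Reaction]]:
    """Read KO -> reaction mappings.

    Columns: ko, reaction_id, substrates, products, reversible, with
    metabolite lists '|'-joined.  Currency metabolites (if given) are
    removed from both sides; reactions left with an empty side are
    dropped.
    """
    df = _read_tsv(path)
    _require_columns(df, ("ko", "reaction_id", "substrates", "products",
                          "reversible"), path)
    currency = currency or set()
    table: dict[str, list[Reaction]] = {}
    for _, row in df.iterrows():
        subs = frozenset(m for m in row["substrates"].split("|")
                         if m and m not in currency)
        prods = frozenset(m for m in row["products"].split("|")
                          if m and m not in currency)
        if not subs or not prods:
            continue
        rev = str(row["reversible"]).strip().lower() in ("1", "true", "yes")
        table.setdefault(row["ko"], []).append(
            Reaction(substrates=subs, products=prods, reversible=rev))
    return table


def read_function_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read per-genome function (pathway-level) gene counts."""
    df = _read_tsv(path)
    _require_columns(df, ("genome_id", "function", "count"), path)
    count = _numeric(df, "count", path).astype(int)
    out: dict[str, dict[str, int]] = {}
    for g, f, c in zip(df["genome_id"], df["function"], count):
        out.setdefault(g, {})[f] = out.get(g, {}).get(f, 0) + int(c)
    return out


# ---------------------------------------------------------------------------
# core-microbiome inputs


def read_genus_list(path: str | Path) -> set[str]:
    """Read a plain-text genus list (one genus per line)."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_prevalence_table(path: str | Path) -> dict[str, float]:
    """Read genus -> fraction-of-hosts prevalence."""
    df = _read_tsv(path)
    _require_columns(df, ("genus", "prevalence"), path)
    prev = _numeric(df, "prevalence", path)
    if (prev < 0).any() or (prev > 1).any():
        raise ValueError(f"{path}: prevalence must lie in [0,1]")
    return dict(zip(df["genus"], prev.astype(float)))


def read_esv_map(path: str | Path) -> dict[str, str]:
    """Read ESV -> genus assignments (esv_id, genus)."""
    df = _read_tsv(path)
    _require_columns(df, ("esv_id", "genus"), path)
    return dict(zip(df["esv_id"], df["genus"]))


# ---------------------------------------------------------------------------
# generic matrices


def write_matrix(df: pd.DataFrame, path: str | Path,
                 index_name: str = "id") -> None:
    """Write a matrix as TSV with 10-significant-digit floats."""
    out = df.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if numeric:
        df = df.astype(float)
    return df


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
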