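"""Presence calls and relative abundance from depth/breadth matrices.

A genome is *present* in a sample when its breadth of coverage (fraction
of positions covered by at least one read) reaches 90%.  Relative
abundance within a sample is the genome's mean depth divided by the
summed depth of all present genomes, after depths are normalized to the
smallest library.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .io import warn


def normalize_depth(depth: pd.DataFrame,
                    library_sizes: pd.Series) -> pd.DataFrame:
    """Scale each sample's depths by min(library sizes)/its library size.

    This mirrors normalizing coverage to the shallowest sequencing run so
    that depths are comparable across samples.
    """
    sizes = library_sizes.reindex(depth.columns)
    if sizes.isna().any():
        missing = sizes.index[sizes.isna()][0]
        raise ValueError(f"no library size for sample {missing!r}")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    factors = sizes.min() / sizes
    return depth.mul(factors, axis=1)


def compute_presence(breadth: pd.DataFrame,
                     cfg: ThresholdConfig) -> pd.DataFrame:
    """Boolean genome x sample presence at breadth >= threshold (inclusive)."""
    vals = breadth.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("breadth values must lie in [0,1]")
    return breadth >= cfg.breadth_presence_min


def relative_abundance(depth: pd.DataFrame,
                       presence: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized depth with absent genomes zeroed first.

    Every column sums to 1 except all-absent columns, which stay zero
    (with a warning).
    """
    if depth.shape != presence.shape:
        raise ValueError("depth and presence matrices must be conformable")
    masked = depth.where(presence.to_numpy(), 0.0)
    sums = masked.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warn(f"{int(zero.sum())} sample(s) have no present genome; "
             "their abundance columns stay zero")
    safe = sums.replace(0, np.nan)
    out = masked.div(safe, axis=1).fillna(0.0)
    return out


def group_abundance_by_tp(ab: pd.DataFrame, groups: dict[str, str],
                          sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-TP percent of community held by each genome group.

    For each time point the within-sample group sums are averaged over
    that TP's samples (animals are equal replicates) and rescaled so the
    groups total 100%.  Returns a TP x group frame of percents.
    """
    unlabeled = [g for g in ab.index if g not in groups]
    if unlabeled:
        raise ValueError(f"genome {unlabeled[0]!r} has no group label")
    group_names = sorted(set(groups.values()))
    group_sums = pd.DataFrame(
        {name: ab.loc[[g for g in ab.index if groups[g] == name]].sum(axis=0)
         for name in group_names})
    group_sums["tp"] = sample_meta.loc[group_sums.index, "tp"].to_numpy()
    rows = {}
    for tp, sub in group_sums.groupby("tp"):
        means = sub[group_names].mean(axis=0)
        total = means.sum()
        if total == 0:
            warn(f"TP {tp} has no abundance signal; omitted")
            continue
        rows[int(tp)] = 100.0 * means / total
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "tp"
    return out


def taxon_aggregate(ab: pd.DataFrame, taxonomy: dict[str, str],
                    rank: str = "class") -> pd.DataFrame:
    """Sum abundances over genomes sharing a taxon label at one rank.

    ``taxonomy`` maps genome -> label at the requested rank; empty or
    missing labels pool into "Unclassified".  Column sums are preserved.
    """
    if rank not in ("phylum", "class", "order", "family", "genus"):
        raise ValueError(f"unsupported rank {rank!r}")
    labels = [taxonomy.get(g, "") or "Unclassified" for g in ab.index]
    out = ab.groupby(pd.Index(labels, name=rank)).sum()
    return out.sort_index()


def normalized_copy_number(ko_counts: dict[str, dict[str, int]],
                           ab: pd.DataFrame,
                           ko_set: set[str]) -> pd.Series:
    """Abundance-weighted mean copy number of a KO set per sample.

    For each sample, sum over genomes of abundance x (total copies of
    the KOs of interest in that genome).  Used e.g. to profile ABC
    transporter gene dosage along the time series.
    """
    copies = pd.Series(
        {g: sum(c for k, c in ko_counts.get(g, {}).items() if k in ko_set)
         for g in ab.index}, dtype=float)
    return ab.mul(copies, axis=0).sum(axis=0)
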