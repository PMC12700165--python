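"""Pairwise pathway completion between genome groups (cross-feeding
potential).

Two complementarity currencies are computed for an (auxiliary, target)
genome pair:

* **completion gain** — the increase in a KEGG module's stepwise
  completeness when the target's KO set is unioned with the auxiliary
  genome's KOs;
* **metabolite gain** — the number of additional metabolites reachable
  by network (scope) expansion from seed compounds once the auxiliary
  genome's reactions are added.

Gains are then aggregated per time point over pairs whose two genomes
are both detected at that TP, normalized by the number of contributing
auxiliary genomes, and z-scaled for heatmap-style comparison.  A
*persistent contributor* is an auxiliary genome that still shows positive
gain in at least two distinct time points after the onset of the adult
fibrous diet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .kegg_modules import ModuleDefinition, stepwise_completeness
from .types import Reaction


# --- module-space gains ----------------------------------------------------

def completion_gain(aux_kos: set[str], target_kos: set[str],
                    defs: dict[str, ModuleDefinition]) -> dict[str, float]:
    """Per-module completeness gain of the target from the auxiliary KOs.

    gain(m) = completeness(m, target | aux) - completeness(m, target);
    non-negative by monotonicity of stepwise completeness.
    """
    union = set(target_kos) | set(aux_kos)
    gains = {}
    for mid, mdef in defs.items():
        before = stepwise_completeness(mdef.steps, target_kos, defs)
        after = stepwise_completeness(mdef.steps, union, defs)
        gains[mid] = after - before
    return gains


# --- metabolite-space gains ------------------------------------------------

def reactions_for(kos: set[str],
                  table: dict[str, list[Reaction]]) -> list[Reaction]:
    """All reactions catalyzed by a KO set (deduplicated, stable order)."""
    seen: list[Reaction] = []
    for ko in sorted(set(kos) & set(table)):
        for r in table[ko]:
            if r not in seen:
                seen.append(r)
    return seen


def scope_expansion(reactions: list[Reaction],
                    seeds: set[str]) -> set[str]:
    """Iterative fixpoint of metabolite reachability (network expansion).

    A reaction fires when all its substrates are reachable; its products
    then join the reachable set.  Reversible reactions can fire in both
    directions.  Returns the final set including the seeds.
    """
    if not seeds:
        raise ValueError("seed metabolite set must be non-empty")
    reach = set(seeds)
    changed = True
    while changed:
        changed = False
        for r in reactions:
            if r.substrates <= reach and not r.products <= reach:
                reach |= r.products
                changed = True
            if r.reversible and r.products <= reach \
                    and not r.substrates <= reach:
                reach |= r.substrates
                changed = True
    return reach


def default_seeds(table: dict[str, list[Reaction]]) -> set[str]:
    """Dataset-independent seed choice: substrates that are never products."""
    subs: set[str] = set()
    prods: set[str] = set()
    for reactions in table.values():
        for r in reactions:
            subs |= r.substrates
            prods |= r.products
            if r.reversible:
                subs |= r.products
                prods |= r.substrates
    return subs - prods


def metabolite_gain(aux_kos: set[str], target_kos: set[str],
                    table: dict[str, list[Reaction]],
                    seeds: set[str]) -> int:
    """Count of new metabolites reachable once aux reactions are added."""
    alone = scope_expansion(reactions_for(target_kos, table), seeds)
    joint = scope_expansion(
        reactions_for(set(target_kos) | set(aux_kos), table), seeds)
    return len(joint) - len(alone)


# --- pairwise record table -------------------------------------------------

def pairwise_records(aux_sets: dict[str, set[str]],
                     target_sets: dict[str, set[str]],
                     defs: dict[str, ModuleDefinition],
                     reaction_table: dict[str, list[Reaction]] | None = None,
                     seeds: set[str] | None = None) -> pd.DataFrame:
    """All (aux, target, module) completion-gain records with gain > 0.

    When a reaction table is given, each record also carries the pair's
    metabolite gain (identical across the pair's modules).
    """
    if reaction_table is not None and seeds is None:
        seeds = default_seeds(reaction_table)
    rows = []
    for aux in sorted(aux_sets):
        for target in sorted(target_sets):
            gains = completion_gain(aux_sets[aux], target_sets[target], defs)
            positive = {m: g for m, g in gains.items() if g > 0}
            if not positive:
                continue
            mg = np.nan
            if reaction_table is not None:
                mg = metabolite_gain(aux_sets[aux], target_sets[target],
                                     reaction_table, seeds)
            for mid in sorted(positive):
                rows.append((aux, target, mid, positive[mid], mg))
    return pd.DataFrame(rows, columns=["aux_genome", "target_genome",
                                       "module_id", "gain",
                                       "metabolite_gain"])


# --- temporal aggregation --------------------------------------------------

def presence_by_tp(presence: pd.DataFrame,
                   sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Genome x TP presence: present in >= 1 sample of the time point."""
    tps = sample_meta.loc[presence.columns, "tp"]
    return presence.T.groupby(tps.to_numpy()).any().T.sort_index(axis=1)


def _zscore(values: np.ndarray) -> np.ndarray:
    """Sample-SD (n-1) z-score; constant or single-value input maps to
    zeros."""
    if len(values) < 2:
        return np.zeros_like(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def aggregate_contribution_by_tp(records: pd.DataFrame,
                                 tp_presence: pd.DataFrame,
                                 gain_column: str = "gain",
                                 ) -> tuple[pd.DataFrame, pd.DataFrame,
                                            pd.Series]:
    """Module x TP contribution matrix (raw and z-scaled) + contributor
    counts.

    At each TP the eligible records are those whose aux and target are
    both present.  Per module, the raw value is the summed gain over
    eligible records divided by the number of distinct contributing aux
    genomes (those with any positive gain at that TP).  Rows are then
    z-scored across the TPs that had contributors; TPs without
    contributors stay 0 and are excluded from the row statistics.
    """
    tps = list(tp_presence.columns)
    modules = sorted(records["module_id"].unique())
    raw = pd.DataFrame(0.0, index=pd.Index(modules, name="module_id"),
                       columns=tps)
    n_contrib = pd.Series(0, index=pd.Index(tps, name="tp"))
    for tp in tps:
        present = set(tp_presence.index[tp_presence[tp]])
        elig = records[records["aux_genome"].isin(present)
                       & records["target_genome"].isin(present)]
        contributors = elig.loc[elig[gain_column] > 0, "aux_genome"].unique()
        n_contrib[tp] = len(contributors)
        if len(contributors) == 0:
            continue
        sums = elig.groupby("module_id")[gain_column].sum()
        raw.loc[sums.index, tp] = sums.to_numpy() / len(contributors)
    zs = pd.DataFrame(0.0, index=raw.index, columns=raw.columns)
    active = [tp for tp in tps if n_contrib[tp] > 0]
    if active:
        for mid in raw.index:
            zs.loc[mid, active] = _zscore(raw.loc[mid, active].to_numpy())
    return raw, zs, n_contrib


def rank_contributors(records: pd.DataFrame,
                      tp_presence: pd.DataFrame,
                      gain_column: str = "gain",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aux-genome x TP total-gain matrix, z-scaled within each TP column.

    Rows (genomes) are ordered by similarity of their z-profiles
    (average-linkage hierarchical clustering on Euclidean distances) so
    related contribution patterns sit together, as in a clustered
    heatmap.
    """
    tps = list(tp_presence.columns)
    aux_ids = sorted(records["aux_genome"].unique())
    raw = pd.DataFrame(0.0, index=pd.Index(aux_ids, name="aux_genome"),
                       columns=tps)
    for tp in tps:
        present = set(tp_presence.index[tp_presence[tp]])
        elig = records[records["aux_genome"].isin(present)
                       & records["target_genome"].isin(present)]
        sums = elig.groupby("aux_genome")[gain_column].sum()
        raw.loc[sums.index, tp] = sums.to_numpy()
    zs = pd.DataFrame({tp: _zscore(raw[tp].to_numpy()) for tp in tps},
                      index=raw.index)
    if len(zs) > 2:
        order = leaves_list(average(pdist(zs.to_numpy())))
        raw, zs = raw.iloc[order], zs.iloc[order]
    return raw, zs


def persistent_contributors(records: pd.DataFrame,
                            tp_presence: pd.DataFrame,
                            onset_tp: int = 7,
                            min_later_stages: int = 2,
                            gain_column: str = "gain") -> set[str]:
    """Aux genomes with positive gain in >= N distinct TPs after onset."""
    if not 1 <= onset_tp <= 14:
        raise ValueError("onset_tp must lie in 1..14")
    later = [tp for tp in tp_presence.columns if tp > onset_tp]
    counts: dict[str, int] = {}
    for tp in later:
        present = set(tp_presence.index[tp_presence[tp]])
        elig = records[records["aux_genome"].isin(present)
                       & records["target_genome"].isin(present)]
        for aux in elig.loc[elig[gain_column] > 0, "aux_genome"].unique():
            counts[aux] = counts.get(aux, 0) + 1
    return {aux for aux, c in counts.items() if c >= min_later_stages}
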