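"""Hypergeometric over-representation tests with BH-FDR control.

One test core serves three analyses that differ only in their counting
unit: family-level novelty enrichment counts genomes, group-level
function enrichment counts genome-function incidences, and per-cluster
function enrichment counts genes.  BH correction is applied jointly
across all tests of one analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig
from .types import EnrichmentResult


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _finalize(results: list[EnrichmentResult],
              ) -> list[EnrichmentResult]:
    """Attach BH q-values and gene ratios; deterministic order."""
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.gene_ratio = r.k / r.n if r.n else 0.0
    return results


def results_frame(results: list[EnrichmentResult],
                  cfg: ThresholdConfig) -> pd.DataFrame:
    rows = [{"term": r.term, "group": r.group, "k": r.k, "K": r.K,
             "n": r.n, "N": r.N, "p_value": r.p_value, "q_value": r.q_value,
             "gene_ratio": r.gene_ratio,
             "significant": r.q_value < cfg.fdr_alpha}
            for r in results]
    return pd.DataFrame(rows)


def family_novelty_enrichment(families: dict[str, str],
                              novelty: dict[str, bool],
                              cfg: ThresholdConfig,
                              ) -> list[EnrichmentResult]:
    """Which families hold more novel species than expected by chance?

    Counting unit: representative genomes.  Per family: N = all
    representatives, K = representatives in the family, n = all novel
    representatives, k = novel representatives in the family.
    ``families`` maps genome -> family label ("" pools as Unclassified).
    """
    genomes = sorted(families)
    labels = {g: families[g] or "Unclassified" for g in genomes}
    N = len(genomes)
    n = sum(bool(novelty[g]) for g in genomes)
    results = []
    for fam in sorted(set(labels.values())):
        members = [g for g in genomes if labels[g] == fam]
        K = len(members)
        k = sum(bool(novelty[g]) for g in members)
        p = hypergeometric_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(term=fam, k=k, K=K, n=n, N=N,
                                        p_value=p))
    return _finalize(results)


def group_function_enrichment(functions_by_genome: dict[str, set[str]],
                              groups: dict[str, str],
                              cfg: ThresholdConfig,
                              ) -> list[EnrichmentResult]:
    """Function enrichment of auxiliary vs non-auxiliary genome groups.

    Counting unit: genome-function incidences.  For each function f and
    group g: k = incidences of f in g, n = all incidences in g,
    K = incidences of f overall, N = all incidences.  One one-sided test
    per (function, group); BH joint across all of them.
    """
    if not groups:
        raise ValueError("no genomes supplied")
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    incid = [(g, f) for g in sorted(functions_by_genome)
             for f in sorted(functions_by_genome[g])]
    N = len(incid)
    if N == 0:
        raise ValueError("no genome-function incidences")
    all_functions = sorted({f for _, f in incid})
    results = []
    for name in group_names:
        in_group = [(g, f) for g, f in incid if groups[g] == name]
        n = len(in_group)
        if n == 0:
            raise ValueError(f"group {name!r} has no incidences")
        for func in all_functions:
            K = sum(1 for _, f in incid if f == func)
            k = sum(1 for _, f in in_group if f == func)
            p = hypergeometric_upper_tail(k, K, n, N)
            results.append(EnrichmentResult(term=func, group=name,
                                            k=k, K=K, n=n, N=N, p_value=p))
    return _finalize(results)


def top_enriched(results: list[EnrichmentResult], cfg: ThresholdConfig,
                 top: int = 10) -> pd.DataFrame:
    """Top-N significant terms per group by ascending q (then p, term)."""
    df = results_frame(results, cfg)
    df = df[df["significant"]]
    df = df.sort_values(["group", "q_value", "p_value", "term"])
    return df.groupby("group", dropna=False).head(top).reset_index(drop=True)


def cluster_function_enrichment(assignment: dict[str, int],
                                gene_counts: dict[str, dict[str, int]],
                                cfg: ThresholdConfig,
                                ) -> list[EnrichmentResult]:
    """Per-cluster function enrichment with gene-level counting.

    Only clusters with >= 2 genomes are testable.  For each (cluster,
    function): k = genes of the function in the cluster, n = genes in
    the cluster, K = genes of the function across all clustered genomes,
    N = all genes.  BH is joint across every (cluster, function) pair.
    """
    sizes: dict[int, int] = {}
    for cid in assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    eligible = {cid for cid, s in sizes.items() if s >= 2}
    clustered = [g for g, cid in assignment.items() if cid in eligible]
    totals: dict[str, int] = {}
    for g in clustered:
        for f, c in gene_counts.get(g, {}).items():
            totals[f] = totals.get(f, 0) + c
    N = sum(totals.values())
    results = []
    for cid in sorted(eligible):
        members = [g for g in clustered if assignment[g] == cid]
        counts: dict[str, int] = {}
        for g in members:
            for f, c in gene_counts.get(g, {}).items():
                counts[f] = counts.get(f, 0) + c
        n = sum(counts.values())
        for func in sorted(totals):
            k = counts.get(func, 0)
            p = hypergeometric_upper_tail(k, totals[func], n, N)
            results.append(EnrichmentResult(term=func, group=str(cid),
                                            k=k, K=totals[func], n=n, N=N,
                                            p_value=p))
    return _finalize(results)
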