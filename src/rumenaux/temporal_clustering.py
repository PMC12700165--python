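"""Co-abundance network construction and Louvain community detection.

Genome temporal profiles (per-TP mean relative abundance) are compared
by Spearman correlation; correlations below 0.75 are discarded, the
remainder form an undirected weighted network, and Louvain modularity
maximization (seeded, so reproducible) partitions it into clusters of
genomes with shared temporal dynamics.  Each cluster is annotated with
the time point at which its summed abundance peaks and the diet fed at
that time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import louvain_communities
from scipy import stats

from .config import ThresholdConfig


def tp_profiles(ab: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Average per-sample abundances into genome x TP profiles."""
    tps = sample_meta.loc[ab.columns, "tp"]
    return ab.T.groupby(tps.to_numpy()).mean().T.sort_index(axis=1)


def spearman_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between genome profiles (rows).

    Average ranks break ties.  Correlations involving a constant
    (invariant) profile are undefined and set to 0.  Requires at least
    three time-point columns.
    """
    if profiles.shape[1] < 3:
        raise ValueError("spearman_matrix needs >= 3 time-point columns")
    mat = profiles.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # constant profiles produce undefined rho, mapped to 0 below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(mat, axis=1).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(profiles), len(profiles)):  # 2-genome case
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    constant = mat.std(axis=1) == 0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    return pd.DataFrame(rho, index=profiles.index, columns=profiles.index)


def build_network(corr: pd.DataFrame, cfg: ThresholdConfig) -> nx.Graph:
    """Keep edges with rho >= threshold (0.75 survives; below it is cut)."""
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    graph = nx.Graph()
    graph.add_nodes_from(corr.index)
    vals = corr.to_numpy()
    ids = list(corr.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= cfg.spearman_edge_min:
                graph.add_edge(ids[i], ids[j], weight=float(vals[i, j]))
    return graph


def detect_communities(net: nx.Graph,
                       cfg: ThresholdConfig) -> dict[str, int]:
    """Louvain partition of the co-abundance network.

    Modularity maximization on edge weights with the configured seed and
    resolution; isolated nodes come out as singleton clusters.  Cluster
    ids are renumbered 1..k by descending size, ties by smallest member,
    so labels are deterministic.
    """
    if net.number_of_nodes() == 0:
        return {}
    communities = louvain_communities(net, weight="weight",
                                      resolution=cfg.louvain_resolution,
                                      seed=cfg.louvain_seed)
    ordered = sorted((frozenset(c) for c in communities),
                     key=lambda c: (-len(c), min(c)))
    assignment: dict[str, int] = {}
    for cid, members in enumerate(ordered, start=1):
        for g in members:
            assignment[g] = cid
    return assignment


def cluster_peaks(assignment: dict[str, int], ab: pd.DataFrame,
                  sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Annotate clusters with their peak TP, peak abundance and diet.

    The cluster's per-TP total is the mean over that TP's samples of the
    summed member abundances; the peak is the argmax (earliest TP on
    ties).
    """
    missing = [g for g in assignment if g not in ab.index]
    if missing:
        raise ValueError(f"clustered genome {missing[0]!r} missing from "
                         "abundance matrix")
    tps = sample_meta.loc[ab.columns, "tp"].to_numpy()
    tp_diet = (sample_meta.drop_duplicates("tp")
               .set_index("tp")["diet"].to_dict())
    rows = []
    for cid in sorted(set(assignment.values())):
        members = [g for g, c in assignment.items() if c == cid]
        totals = ab.loc[members].sum(axis=0)
        per_tp = totals.groupby(tps).mean().sort_index()
        peak_tp = int(per_tp.idxmax())  # idxmax takes the first (earliest) tie
        rows.append({"cluster_id": cid, "n_genomes": len(members),
                     "peak_tp": peak_tp,
                     "peak_total_abundance": float(per_tp.loc[peak_tp]),
                     "diet_at_peak": tp_diet[peak_tp]})
    return pd.DataFrame(rows).set_index("cluster_id")
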