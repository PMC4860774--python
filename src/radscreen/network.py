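"""Functional-network filtering, subnetwork clustering, and gene-set
enrichment.

Candidate genes are mapped onto a weighted functional-association network
(edges kept above a confidence cut-off, 0.5 by default); candidates with
no qualifying edge to another candidate drop out as isolated nodes.  The
induced subnetwork is partitioned by a shared-neighbourhood agglomerative
clustering: cluster similarity is the weighted Jaccard of closed
neighbourhoods and clusters merge greedily while the best connected pair
stays above a similarity threshold.  Clusters (or the whole candidate
list) are annotated by hypergeometric over-representation of gene sets
with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubNetwork",
    "ClusterSet",
    "to_graph",
    "induced_subnetwork",
    "cluster_subnetwork",
    "hypergeometric_upper_tail",
    "bh_adjust",
    "enrich",
    "enrich_clusters",
]

logger = logging.getLogger(__name__)


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected weighted graph from a (gene_a, gene_b, confidence)
    edge table."""
    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        g.add_edge(str(rec.gene_a), str(rec.gene_b), confidence=float(rec.confidence))
    return g


@dataclass
class SubNetwork:
    """Candidate-induced subgraph plus coverage bookkeeping."""

    graph: nx.Graph                       # nodes: candidates with >=1 edge
    isolated: set                         # candidates in network, no qualifying edge
    missing_from_network: set             # candidates absent from the network

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)


def induced_subnetwork(network, candidates, min_confidence: float = 0.5) -> SubNetwork:
    """Subgraph of the functional network induced by the candidate genes.

    ``network`` may be an edge DataFrame or a networkx Graph with a
    ``confidence`` edge attribute.  Only edges between two candidates with
    confidence >= ``min_confidence`` qualify; candidates without one are
    returned as isolated, and candidates the network has never seen are
    listed separately (a coverage report, not an error).
    """
    g = network if isinstance(network, nx.Graph) else to_graph(network)
    candidates = {str(c) for c in candidates}
    missing = candidates - set(g.nodes)
    present = candidates - missing

    sub = nx.Graph()
    for u, v, data in g.subgraph(present).edges(data=True):
        if data.get("confidence", 0.0) >= min_confidence:
            sub.add_edge(u, v, confidence=data["confidence"])
    isolated = present - set(sub.nodes)
    if missing:
        logger.info("%d candidate(s) absent from the network", len(missing))
    return SubNetwork(sub, isolated, missing)


@dataclass
class ClusterSet:
    """Disjoint clusters of subnetwork nodes; small groups stay unclustered."""

    clusters: list                        # list of frozensets, deterministic order
    unclustered: set = field(default_factory=set)

    def membership(self) -> dict:
        return {g: i for i, cl in enumerate(self.clusters) for g in cl}


def _weighted_jaccard(a: dict, b: dict) -> float:
    keys = a.keys() | b.keys()
    num = sum(min(a.get(k, 0.0), b.get(k, 0.0)) for k in keys)
    den = sum(max(a.get(k, 0.0), b.get(k, 0.0)) for k in keys)
    return num / den if den > 0 else 0.0


def cluster_subnetwork(
    subnetwork, similarity_threshold: float = 0.3, min_cluster_size: int = 3
) -> ClusterSet:
    """Shared-neighbourhood agglomerative clustering of a weighted graph.

    Every node starts as a singleton carrying its closed neighbourhood as
    a weight vector (self-weight 1, neighbours at edge confidence).
    Cluster similarity is the weighted Jaccard of the element-wise maximum
    of member vectors; only clusters joined by at least one edge may
    merge, so connected components never coalesce.  The best pair merges
    while its similarity stays >= the threshold; ties resolve to the pair
    whose lexically smallest member comes first.  Clusters below
    ``min_cluster_size`` are reported as unclustered.
    """
    g = subnetwork.graph if isinstance(subnetwork, SubNetwork) else subnetwork
    nodes = sorted(g.nodes)
    if not nodes:
        return ClusterSet([], set())

    neigh = {
        n: {n: 1.0, **{m: g[n][m].get("confidence", 1.0) for m in g[n]}}
        for n in nodes
    }
    clusters = {i: {n} for i, n in enumerate(nodes)}
    vectors = {i: dict(neigh[n]) for i, n in enumerate(nodes)}

    def connected(i, j):
        return any(g.has_edge(u, v) for u in clusters[i] for v in clusters[j])

    while True:
        best = None  # (similarity, tie_key, i, j)
        ids = sorted(clusters)
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                if not connected(i, j):
                    continue
                sim = _weighted_jaccard(vectors[i], vectors[j])
                if sim < similarity_threshold:
                    continue
                tie_key = tuple(sorted(clusters[i] | clusters[j]))
                if best is None or (sim, ) > (best[0], ) or (
                    sim == best[0] and tie_key < best[1]
                ):
                    best = (sim, tie_key, i, j)
        if best is None:
            break
        _, _, i, j = best
        clusters[i] |= clusters.pop(j)
        vj = vectors.pop(j)
        vi = vectors[i]
        for k, w in vj.items():
            vi[k] = max(vi.get(k, 0.0), w)

    final, unclustered = [], set()
    for members in clusters.values():
        if len(members) >= min_cluster_size:
            final.append(frozenset(members))
        else:
            unclustered |= members
    final.sort(key=lambda c: (-len(c), sorted(c)))
    return ClusterSet(final, unclustered)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the over-representation
    tail including the observed overlap.

    N: universe size, K: annotated genes in the universe, n: candidates,
    k: annotated candidates.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent hypergeometric arguments N={N}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(candidates, gene_sets, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets among candidates.

    Gene sets are intersected with the universe before counting; only sets
    overlapping the candidates (k >= 1) are tested, and BH adjustment runs
    across all tested sets.  Candidates outside the universe are dropped
    with a logged count.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("enrichment universe is empty")
    cand = {str(g) for g in candidates}
    dropped = cand - universe
    if dropped:
        logger.info("%d candidate(s) outside the universe dropped", len(dropped))
    cand &= universe

    rows = []
    for name in sorted(gene_sets):
        gs = gene_sets[name]
        members = {str(g) for g in gs.genes} & universe
        k = len(members & cand)
        if k < 1 or not members:
            continue
        p = hypergeometric_upper_tail(len(universe), len(members), len(cand), k)
        rows.append((name, gs.description, len(universe), len(members),
                     len(cand), k, p))
    df = pd.DataFrame(
        rows,
        columns=["set_name", "description", "universe_size", "set_size",
                 "n_candidates", "overlap", "p_value"],
    )
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(
            by=["p_adjusted", "p_value", "set_name"], kind="stable"
        ).reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def enrich_clusters(cluster_set: ClusterSet, gene_sets, universe) -> pd.DataFrame:
    """Per-cluster enrichment; returns a long table with a cluster column."""
    frames = []
    for i, members in enumerate(cluster_set.clusters):
        res = enrich(members, gene_sets, universe)
        if len(res) == 0:
            continue
        res.insert(0, "cluster", i)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "set_name", "description", "universe_size",
                     "set_size", "n_candidates", "overlap", "p_value",
                     "p_adjusted"]
        )
    return pd.concat(frames, ignore_index=True)
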