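"""Probability-weighted bipartite interaction networks and Markov clustering.

Predicted pair probabilities define edge weights of a bipartite
ncRNA-protein graph.  Clusters are found with the Markov cluster algorithm
(MCL): starting from the column-stochastic adjacency matrix with unit
self-loops, alternate *expansion* (matrix squaring, spreading flow) and
*inflation* (elementwise power followed by column renormalization,
sharpening flow) until the matrix stops changing; clusters are read off the
attractor structure of the limit matrix.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "mcl_cluster",
    "mcl_matrix",
    "read_edge_list",
    "write_edge_list",
    "write_clusters",
]


def build_network(scored_pairs, min_weight: float = 0.0) -> nx.Graph:
    """Bipartite graph from (protein_id, rna_id, weight) triples.

    Edges below ``min_weight`` are dropped; the node set is exactly the set
    of endpoints of retained edges.  Duplicate (protein, rna) entries keep
    the maximum weight (with a warning).
    """
    best: dict[tuple[str, str], float] = {}
    for pid, rid, w in scored_pairs:
        w = float(w)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"edge weight {w} outside [0, 1]")
        key = (pid, rid)
        if key in best:
            logger.warning("duplicate pair %s; keeping max weight", key)
            best[key] = max(best[key], w)
        else:
            best[key] = w
    g = nx.Graph()
    for (pid, rid), w in best.items():
        if w >= min_weight:
            g.add_node(pid, kind="protein", bipartite=0)
            g.add_node(rid, kind="rna", bipartite=1)
            g.add_edge(pid, rid, weight=w)
    return g


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    sums[sums == 0] = 1.0
    return M / sums


def mcl_matrix(
    A: np.ndarray,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-12,
    callback=None,
) -> np.ndarray:
    """Run MCL on a symmetric weighted adjacency matrix; returns the limit matrix.

    Unit self-loops are added before normalization.  ``callback(M)`` is
    invoked after every inflation step (used to check column-stochasticity).
    """
    n = A.shape[0]
    M = np.asarray(A, dtype=float) + np.eye(n)
    M = _normalize_columns(M)
    for _ in range(max_iter):
        prev = M
        M = M @ M                       # expansion
        M = np.power(M, inflation)      # inflation
        M = _normalize_columns(M)
        M[M < prune] = 0.0
        M = _normalize_columns(M)
        if callback is not None:
            callback(M)
        if np.abs(M - prev).max() < tol:
            break
    return M


def _clusters_from_matrix(M: np.ndarray) -> list[set[int]]:
    """Read clusters off the limit matrix's attractor rows."""
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 1e-8]
    clusters: list[set[int]] = []
    for i in attractors:
        members = set(np.nonzero(M[i] > 1e-8)[0].tolist()) | {i}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # merging may chain: re-consolidate
            changed = True
            while changed:
                changed = False
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        if clusters[a] & clusters[b]:
                            clusters[a] |= clusters.pop(b)
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            # attach to the strongest attractor's cluster; singleton fallback
            col = M[:, i]
            if col.max() > 0:
                target = int(np.argmax(col))
                for c in clusters:
                    if target in c:
                        c.add(i)
                        break
                else:
                    clusters.append({i})
            else:
                clusters.append({i})
    return clusters


def mcl_cluster(
    net: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Markov clustering of a weighted network; returns disjoint node sets.

    Deterministic: nodes are processed in sorted order, so the result does
    not depend on insertion order.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes())
    A = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    M = mcl_matrix(A, inflation=inflation, max_iter=max_iter, tol=tol)
    idx_clusters = _clusters_from_matrix(M)
    clusters = [set(nodes[i] for i in c) for c in idx_clusters]
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "rna_id": str})
    return list(zip(df["protein_id"], df["rna_id"], df["weight"].astype(float)))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, data in net.edges(data=True):
        if net.nodes[u].get("kind") == "protein":
            rows.append((u, v, data["weight"]))
        else:
            rows.append((v, u, data["weight"]))
    pd.DataFrame(rows, columns=["protein_id", "rna_id", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_clusters(clusters: list[set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write("\t".join(sorted(c)) + "\n")
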