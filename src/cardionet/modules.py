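"""TF co-expression network construction and bridge-bisection partitioning.

The network links two DE TF genes when the Pearson correlation of their
treatment-condition expression profiles across timepoints meets a threshold
(default 0.9, positive correlations only).  The network is then partitioned
by iterated bridge bisection: among the bridges of the largest divisible
partition, the one whose removal yields the most balanced split (smallest
larger-side size) is cut, provided both sides stay above a minimum size;
partitions that admit no cut are final.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .datatypes import DECallTable, ModulePartition, RESIDUAL_MODULE, pearson


def pairwise_pcc(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of profile rows; NaN for zero variance."""
    arr = profiles.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    corr = unit @ unit.T
    corr = np.clip(corr, -1.0, 1.0)
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def build_tf_network(profiles: pd.DataFrame,
                     threshold: float = 0.9) -> nx.Graph:
    """Undirected co-expression graph over profile rows.

    An edge (u, v) carries attribute ``pcc`` and is present iff
    PCC(profile_u, profile_v) >= threshold.  Zero-variance profiles produce
    no edges.  All profile rows appear as nodes (possibly isolated).
    """
    if profiles.shape[1] < 3:
        raise ValueError("profiles need at least 3 timepoints")
    graph = nx.Graph()
    graph.add_nodes_from(profiles.index)
    corr = pairwise_pcc(profiles).to_numpy()
    nodes = list(profiles.index)
    n = len(nodes)
    for i in range(n):
        row = corr[i]
        for j in range(i + 1, n):
            r = row[j]
            if not np.isnan(r) and r >= threshold:
                graph.add_edge(nodes[i], nodes[j], pcc=float(r))
    return graph


def find_bridges(graph: nx.Graph) -> list[tuple]:
    """All bridges of a simple undirected graph (iterative low-link DFS).

    A bridge is an edge whose removal increases the number of connected
    components.  Edges are returned as (u, v) sorted within the pair and the
    list sorted overall, for determinism.
    """
    disc: dict = {}
    low: dict = {}
    bridges: list[tuple] = []
    timer = 0
    adj = {u: list(graph.adj[u]) for u in graph.nodes}
    for root in graph.nodes:
        if root in disc:
            continue
        # stack entries: (node, parent, iterator over neighbours)
        stack = [(root, None, iter(adj[root]))]
        disc[root] = low[root] = timer
        timer += 1
        parent_edge_used: dict = {root: False}
        while stack:
            node, parent, it = stack[-1]
            advanced = False
            for nbr in it:
                if nbr == parent and not parent_edge_used.get(node, False):
                    # skip the tree edge back to the parent exactly once;
                    # a second occurrence would be a parallel edge
                    parent_edge_used[node] = True
                    continue
                if nbr in disc:
                    low[node] = min(low[node], disc[nbr])
                else:
                    disc[nbr] = low[nbr] = timer
                    timer += 1
                    parent_edge_used[nbr] = False
                    stack.append((nbr, node, iter(adj[nbr])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                if parent is not None:
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        bridges.append(tuple(sorted((parent, node))))
    return sorted(bridges)


def _split_sizes(graph: nx.Graph, nodes: set, edge: tuple) -> tuple[set, set]:
    """Components of ``nodes`` after removing a bridge, as two node sets."""
    u, v = edge
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for nbr in graph.adj[x]:
            if nbr not in nodes or nbr in seen:
                continue
            if (x, nbr) == (u, v) or (x, nbr) == (v, u):
                continue
            seen.add(nbr)
            stack.append(nbr)
    side_u = seen
    side_v = nodes - seen
    return side_u, side_v


def bisect_network(graph: nx.Graph, min_size: int = 10) -> ModulePartition:
    """Partition a co-expression graph by iterated bridge bisection.

    Connected components larger than ``min_size`` are divisible; repeatedly,
    the largest not-yet-final partition is examined: among its bridges whose
    removal leaves both sides with more than ``min_size`` nodes, the one
    with the smallest balancing value (size of the larger side) is cut, ties
    broken by lexicographically smallest edge.  A partition with no
    admissible cut is final.  Components of size <= ``min_size`` and
    isolated nodes are assigned to the residual module (id 0); final modules
    are numbered 1..k by decreasing size (ties by smallest member id).
    """
    work = graph.copy()
    residual: list = []
    active: list[set] = []
    for comp in nx.connected_components(graph):
        if len(comp) > min_size:
            active.append(set(comp))
        else:
            residual.extend(comp)

    final: list[set] = []
    cuts: list[tuple[tuple, int]] = []
    while active:
        active.sort(key=lambda c: (-len(c), min(map(str, c))))
        part = active.pop(0)
        sub = work.subgraph(part)
        best_edge = None
        best_bal = None
        best_split = None
        for edge in find_bridges(sub):
            side_a, side_b = _split_sizes(work, part, edge)
            if min(len(side_a), len(side_b)) <= min_size:
                continue
            bal = max(len(side_a), len(side_b))
            if best_bal is None or bal < best_bal:
                best_edge, best_bal, best_split = edge, bal, (side_a, side_b)
        if best_edge is None:
            final.append(part)
            continue
        work.remove_edge(*best_edge)
        cuts.append((best_edge, best_bal))
        active.extend(best_split)

    final.sort(key=lambda c: (-len(c), min(map(str, c))))
    module_of: dict = {}
    for mid, comp in enumerate(final, start=1):
        for node in comp:
            module_of[node] = mid
    for node in residual:
        module_of[node] = RESIDUAL_MODULE
    return ModulePartition(module_of, cuts)


def coexpressed_de_genes(tf_profile: pd.Series, gene_profiles: pd.DataFrame,
                         threshold: float = 0.9) -> set:
    """DE genes whose treatment profile correlates with a TF's at >= threshold."""
    tf = tf_profile.to_numpy(dtype=float)
    out = set()
    for gene, row in gene_profiles.iterrows():
        r = pearson(tf, row.to_numpy(dtype=float))
        if not np.isnan(r) and r >= threshold:
            out.add(gene)
    return out


def module_regulation_summary(partition: ModulePartition,
                              calls: DECallTable) -> pd.DataFrame:
    """Up/down DE counts per module per timepoint.

    Returns a frame indexed by (module, timepoint) with columns ``up`` and
    ``down``; only nodes present in both the partition and the call table
    are counted.
    """
    rows = []
    labels = calls.labels
    for mid, members in partition.modules.items():
        present = [m for m in members if m in labels.index]
        sub = labels.loc[present]
        for t in labels.columns:
            rows.append({"module": mid, "timepoint": t,
                         "up": int((sub[t] == 1).sum()),
                         "down": int((sub[t] == -1).sum())})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.set_index(["module", "timepoint"])
    return frame
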