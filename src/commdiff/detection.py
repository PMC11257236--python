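"""Community detection and the two-level map-equation codelength.

Louvain modularity optimization is implemented natively with a
reproducibility policy: node sweep order is a seeded permutation per pass
and ties between equally improving moves go to the lowest community id.
Infomap is delegated to the igraph implementation of the Rosvall-Bergstrom
algorithm; the map-equation codelength itself is computed natively because
Map Equation Centrality needs codelength arithmetic.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition

__all__ = [
    "CodelengthReport",
    "louvain",
    "infomap",
    "map_equation_codelength",
]


# --------------------------------------------------------------------------
# Louvain


def louvain(graph: Graph, seed: int = 0) -> Partition:
    """Louvain modularity optimization (native implementation).

    Two phases repeated until modularity stops improving: greedy single-node
    moves over a seeded node permutation, then aggregation of communities
    into super-nodes.  Deterministic under a fixed seed.
    """
    if graph.M < 1:
        raise ValueError("Louvain requires at least one edge")
    rng = _random.Random(seed)
    n = graph.N
    # adjacency as dict-of-dicts with weights; self-weights for aggregation
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for u, v in graph.edge_array.T:
        adj[u][v] = adj[u].get(v, 0.0) + 1.0
        adj[v][u] = adj[v].get(u, 0.0) + 1.0
    self_w = [0.0] * n
    m2 = 2.0 * graph.M  # total weight of stub ends, constant across levels

    def local_moves(adj, self_w, comm):
        """Greedy single-node moves until none improves; mutates comm."""
        k = [sum(w.values()) + self_w[i] for i, w in enumerate(adj)]
        tot = [0.0] * (max(comm) + 1)
        for i, c in enumerate(comm):
            tot[c] += k[i]
        improved_any = False
        while True:
            moved = 0
            order = list(range(len(adj)))
            rng.shuffle(order)
            for i in order:
                ci = comm[i]
                # weights from i to each neighboring community
                w_to: dict[int, float] = {}
                for j, w in adj[i].items():
                    w_to[comm[j]] = w_to.get(comm[j], 0.0) + w
                tot[ci] -= k[i]
                best_c, best_gain = ci, 0.0
                base = w_to.get(ci, 0.0) - tot[ci] * k[i] / m2
                # ascending community id: ties go to the lowest id
                for c in sorted(w_to):
                    if c == ci:
                        continue
                    gain = (w_to[c] - tot[c] * k[i] / m2) - base
                    if gain > best_gain + 1e-12:
                        best_c, best_gain = c, gain
                tot[best_c] += k[i]
                if best_c != ci:
                    comm[i] = best_c
                    moved += 1
            if moved == 0:
                return improved_any
            improved_any = True

    node_to_orig: list[list[int]] = [[i] for i in range(n)]
    final_comm = np.arange(n)

    while True:
        n_cur = len(adj)
        comm = list(range(n_cur))
        improved_any = local_moves(adj, self_w, comm)
        # renumber communities densely
        remap: dict[int, int] = {}
        for c in comm:
            if c not in remap:
                remap[c] = len(remap)
        comm = [remap[c] for c in comm]
        n_new = len(remap)
        final_comm = np.asarray([comm[c] for c in final_comm])
        if not improved_any or n_new == n_cur:
            break
        # aggregate
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        new_self = [0.0] * n_new
        for i, w in enumerate(adj):
            ci = comm[i]
            new_self[ci] += self_w[i]
            for j, wij in w.items():
                cj = comm[j]
                if ci == cj:
                    new_self[ci] += wij  # counted twice over (i,j),(j,i)
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + wij
        adj, self_w = new_adj, new_self
        merged: list[list[int]] = [[] for _ in range(n_new)]
        for c_old, members in enumerate(node_to_orig):
            merged[comm[c_old]].extend(members)
        node_to_orig = merged

    # final node-level refinement: aggregation can leave single original
    # nodes with improving moves, which the contract forbids
    orig_adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for u, v in graph.edge_array.T:
        orig_adj[u][v] = 1.0
        orig_adj[v][u] = 1.0
    comm = list(final_comm)
    local_moves(orig_adj, [0.0] * n, comm)
    remap: dict[int, int] = {}
    for c in comm:
        if c not in remap:
            remap[c] = len(remap)
    final_comm = np.asarray([remap[c] for c in comm])

    width = len(str(max(final_comm.max(), 1)))
    assignment = {
        graph.labels[i]: f"c{final_comm[i]:0{width}d}" for i in range(n)
    }
    return Partition(graph, assignment)


# --------------------------------------------------------------------------
# Infomap (delegated engine)


def infomap(graph: Graph, seed: int = 0, trials: int = 10) -> Partition:
    """Two-level Infomap partition via the igraph engine.

    igraph draws from Python's ``random`` module, which is seeded locally
    here, so results are deterministic under a fixed seed.
    """
    if graph.M < 1:
        raise ValueError("Infomap requires at least one edge")
    try:
        import igraph as ig
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "the Infomap stage needs python-igraph; install it with "
            "'pip install igraph'"
        ) from err
    g = ig.Graph(n=graph.N, edges=[tuple(e) for e in graph.edge_array.T])
    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = g.community_infomap(trials=trials)
    finally:
        _random.setstate(state)
    memb = clustering.membership
    width = len(str(max(max(memb), 1)))
    assignment = {graph.labels[i]: f"c{memb[i]:0{width}d}" for i in range(graph.N)}
    return Partition(graph, assignment)


# --------------------------------------------------------------------------
# two-level map equation


@dataclass
class CodelengthReport:
    """Two-level description length of a random walk, in bits."""

    L: float
    index_len: float
    module_len: float


def _plogp(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def codelength_from_arrays(
    k: np.ndarray, k_inter: np.ndarray, membership: np.ndarray, n_comm: int
) -> tuple[float, float, float]:
    """Two-level codelength from degree arrays.

    Node visit rates are the undirected stationary distribution
    p_i = k_i / 2M; module exit rates are the per-module inter-community
    degree totals over 2M (no teleportation).  Zero-degree nodes and empty
    modules contribute nothing.  Returns (L, index_len, module_len).
    """
    two_m = float(k.sum())
    if two_m <= 0:
        return 0.0, 0.0, 0.0
    p = k / two_m
    q_m = np.bincount(membership, weights=k_inter, minlength=n_comm) / two_m
    p_m = np.bincount(membership, weights=k, minlength=n_comm) / two_m + q_m
    q = float(q_m.sum())
    # q*H(Q) = -sum q_m log(q_m/q)
    index_len = float(-_plogp(q_m).sum() + (q * np.log2(q) if q > 0 else 0.0))
    module_len = float(
        -_plogp(q_m).sum() - _plogp(p).sum() + _plogp(p_m).sum()
    )
    return index_len + module_len, index_len, module_len


def map_equation_codelength(graph: Graph, partition: Partition) -> CodelengthReport:
    """Two-level map-equation codelength of a partition, in bits.

    L = q * H(Q) + sum_m p_m * H(P_m), with degree-proportional visit
    rates.  The index (inter-module) term vanishes for a one-module
    partition.
    """
    if graph.M < 1:
        raise ValueError("codelength undefined for a graph with no edges")
    memb = partition.membership
    d_c = np.bincount(memb, weights=graph.degrees, minlength=partition.C)
    if np.any(d_c <= 0):
        raise ValueError("every community must have positive total degree")
    intra = memb[graph.edge_array[0]] == memb[graph.edge_array[1]]
    k_inter = np.zeros(graph.N)
    ends = np.concatenate(
        [graph.edge_array[0][~intra], graph.edge_array[1][~intra]]
    )
    np.add.at(k_inter, ends, 1.0)
    L, index_len, module_len = codelength_from_arrays(
        graph.degrees.astype(float), k_inter, memb, partition.C
    )
    return CodelengthReport(L=L, index_len=index_len, module_len=module_len)
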