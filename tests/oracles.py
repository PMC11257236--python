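"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by the most literal method
available — pairwise sums, exhaustive enumeration over random draws or
edge subsets, repeated pruning — so the production implementations are
checked against code that shares nothing with them.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from commdiff.graph import Graph, Partition


def pairwise_modularity(graph: Graph, partition: Partition) -> float:
    """Q via the O(N^2) double loop over node pairs:
    (1/2M) * sum_ij (A_ij - k_i k_j / 2M) * delta(c_i, c_j)."""
    a = graph.adj.toarray()
    k = graph.degrees
    m2 = 2.0 * graph.M
    memb = partition.membership
    q = 0.0
    for i in range(graph.N):
        for j in range(graph.N):
            if memb[i] == memb[j]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def edge_tally_profiles(graph: Graph, partition: Partition):
    """Per-node (k, k_intra, k_inter, k_by_comm, nnc) by looping over edges."""
    assign = partition.assignment
    k = {lab: 0 for lab in graph.labels}
    intra = {lab: 0 for lab in graph.labels}
    by_comm: dict[str, dict[str, int]] = {lab: {} for lab in graph.labels}
    for u, v in graph.edges():
        k[u] += 1
        k[v] += 1
        by_comm[u][assign[v]] = by_comm[u].get(assign[v], 0) + 1
        by_comm[v][assign[u]] = by_comm[v].get(assign[u], 0) + 1
        if assign[u] == assign[v]:
            intra[u] += 1
            intra[v] += 1
    out = {}
    for lab in graph.labels:
        nnc = sum(1 for c in by_comm[lab] if c != assign[lab])
        out[lab] = (k[lab], intra[lab], k[lab] - intra[lab], by_comm[lab], nnc)
    return out


def core_numbers_by_pruning(graph: Graph) -> dict[str, int]:
    """k-shell indices by literal repeated pruning."""
    adj = {lab: set() for lab in graph.labels}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    shell = {}
    remaining = set(graph.labels)
    k = 0
    while remaining:
        while True:
            prune = [v for v in remaining if len(adj[v] & remaining) <= k]
            if not prune:
                break
            for v in prune:
                shell[v] = k
                remaining.discard(v)
        k += 1
    return shell


def set_partitions(items):
    """All partitions of a collection (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def naive_codelength(graph: Graph, partition: Partition) -> float:
    """Two-level map-equation codelength straight from the formula, one
    module at a time, with explicit entropies."""

    def entropy(probs):
        return -sum(p * math.log2(p) for p in probs if p > 0)

    m2 = 2.0 * graph.M
    assign = partition.assignment
    modules = {}
    for lab in graph.labels:
        modules.setdefault(assign[lab], []).append(lab)
    k = {lab: int(graph.degrees[graph.index[lab]]) for lab in graph.labels}
    exit_deg = {c: 0 for c in modules}
    for u, v in graph.edges():
        if assign[u] != assign[v]:
            exit_deg[assign[u]] += 1
            exit_deg[assign[v]] += 1
    q = {c: exit_deg[c] / m2 for c in modules}
    q_tot = sum(q.values())
    index_len = q_tot * entropy([q[c] / q_tot for c in modules]) if q_tot > 0 else 0.0
    module_len = 0.0
    for c, members in modules.items():
        p_circ = q[c] + sum(k[lab] / m2 for lab in members)
        inner = [q[c] / p_circ] + [k[lab] / m2 / p_circ for lab in members]
        module_len += p_circ * entropy(inner)
    return index_len + module_len


def si_k4_expected_steps(lam: float) -> float:
    """Expected SI iterations to infect all of K4 from one seed, by
    absorption analysis on the infected-count chain (synchronous updates)."""
    from math import comb

    e = {4: 0.0}
    for j in (3, 2, 1):
        q = 1.0 - (1.0 - lam) ** j  # per-susceptible infection probability
        n_s = 4 - j
        stay = (1 - q) ** n_s
        acc = 1.0
        for add in range(1, n_s + 1):
            p_add = comb(n_s, add) * q**add * (1 - q) ** (n_s - add)
            acc += p_add * e[j + add]
        e[j] = acc / (1.0 - stay)
    return e[1]


def sir_exact_mean_final_r(graph: Graph, seeds, lam: float, psi: float) -> float:
    """Expected final recovered count by exhaustive enumeration of the
    outcome tree (infect from step-start infected, then recover)."""
    labels = graph.labels
    adj = {lab: set() for lab in labels}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)

    @lru_cache(maxsize=None)
    def expected(infected: frozenset, recovered: frozenset) -> float:
        if not infected:
            return float(len(recovered))
        sus = [v for v in labels if v not in infected and v not in recovered]
        exposed = [(v, sum(1 for u in adj[v] if u in infected)) for v in sus]
        exposed = [(v, m) for v, m in exposed if m > 0]
        total = 0.0
        inf_list = sorted(infected)
        for new_mask in itertools.product([0, 1], repeat=len(exposed)):
            p_new = 1.0
            new_nodes = []
            for (v, m), bit in zip(exposed, new_mask):
                p_v = 1.0 - (1.0 - lam) ** m
                p_new *= p_v if bit else (1.0 - p_v)
                if bit:
                    new_nodes.append(v)
            if p_new == 0.0:
                continue
            for rec_mask in itertools.product([0, 1], repeat=len(inf_list)):
                p_rec = 1.0
                recs = []
                for v, bit in zip(inf_list, rec_mask):
                    p_rec *= psi if bit else (1.0 - psi)
                    if bit:
                        recs.append(v)
                if p_rec == 0.0:
                    continue
                nxt_inf = (infected - frozenset(recs)) | frozenset(new_nodes)
                nxt_rec = recovered | frozenset(recs)
                total += p_new * p_rec * expected(nxt_inf, nxt_rec)
        return total

    return expected(frozenset(seeds), frozenset())


def ic_live_edge_mean(graph: Graph, seeds, p: float) -> float:
    """Expected IC cascade size as the live-edge (bond percolation)
    expectation, enumerated over all 2^M edge subsets."""
    edges = graph.edges()
    labels = set(graph.labels)
    total = 0.0
    for keep_mask in itertools.product([0, 1], repeat=len(edges)):
        prob = 1.0
        adj = {lab: set() for lab in labels}
        for (u, v), bit in zip(edges, keep_mask):
            prob *= p if bit else (1.0 - p)
            if bit:
                adj[u].add(v)
                adj[v].add(u)
        if prob == 0.0:
            continue
        seen = set(seeds)
        stack = list(seeds)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        total += prob * len(seen)
    return total


def lt_fixed_point(graph: Graph, seeds, xi: float) -> set:
    """LT final active set by literal synchronous iteration."""
    adj = {lab: set() for lab in graph.labels}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    active = set(seeds)
    while True:
        new = {
            v
            for v in graph.labels
            if v not in active
            and len(adj[v]) > 0
            and len(adj[v] & active) >= 1
            and len(adj[v] & active) / len(adj[v]) >= xi
        }
        if not new:
            return active
        active |= new
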