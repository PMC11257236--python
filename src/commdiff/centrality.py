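"""Community-aware centrality measures.

Each measure maps a (graph, partition) pair to one score per node, with
higher scores meaning more influential seeds.  The measures differ in how
they weigh a node's intra-community links (local, hub-like influence)
against its inter-community links (global, bridge-like influence):

========  ==========================================================
deg       classical degree baseline, community-agnostic
PC        participation coefficient: 1 - sum_c (k_{i,c}/k_i)^2
CBC       community-based centrality: sum_c k_{i,c} * n_c / N
Comm      Comm centrality: community-normalized intra and inter
          degrees reweighted by the community's own mixing
ks        k-shell with community: delta*core_intra + (1-delta)*core_inter
CBM       community-based mediator: entropy of the intra/inter degree
          split, scaled by k_i / 2M
CHB       community hub-bridge: n_c*k_intra + NNC*k_inter
MV+/-/abs modularity vitality: Q(G) - Q(G minus i), ranked for hubs
          (positive), bridges (negative) or both (magnitude)
MapEq     map-equation centrality: codelength vitality of node removal
========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition, CommunityProfiles, community_profiles, modularity
from .detection import codelength_from_arrays

__all__ = [
    "ScoreVector",
    "Ranking",
    "degree_baseline",
    "participation_coefficient",
    "community_based_centrality",
    "comm_centrality",
    "kshell_with_community",
    "community_based_mediator",
    "community_hub_bridge",
    "modularity_vitality",
    "map_equation_centrality",
    "rank",
    "MEASURES",
    "compute_measure",
]


@dataclass
class ScoreVector:
    """Node scores for one measure; higher is always more influential."""

    measure_id: str
    labels: tuple[str, ...]
    scores: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {lab: float(s) for lab, s in zip(self.labels, self.scores)}


@dataclass
class Ranking:
    """Nodes ordered most influential first."""

    measure_id: str
    ordered: list[str]
    tie_rule: str = "descending score, ties by ascending node label"


def _profiles(graph: Graph, partition: Partition, profiles) -> CommunityProfiles:
    if profiles is not None:
        return profiles
    return community_profiles(graph, partition)


def degree_baseline(graph: Graph) -> ScoreVector:
    return ScoreVector("deg", graph.labels, graph.degrees.astype(float))


def participation_coefficient(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> ScoreVector:
    """PC_i = 1 - sum_c (k_{i,c}/k_i)^2; 0 for purely internal nodes."""
    prof = _profiles(graph, partition, profiles)
    if np.any(prof.k == 0):
        raise ValueError("participation coefficient undefined for isolated nodes")
    kbc = prof.k_by_comm
    sq = kbc.copy()
    sq.data = sq.data**2
    scores = 1.0 - np.asarray(sq.sum(axis=1)).ravel() / prof.k.astype(float) ** 2
    return ScoreVector("PC", graph.labels, scores)


def community_based_centrality(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> ScoreVector:
    """CBC_i = sum_c k_{i,c} * (n_c / N); reduces to degree when C = 1."""
    prof = _profiles(graph, partition, profiles)
    weights = partition.sizes / graph.N
    scores = np.asarray(prof.k_by_comm @ weights).ravel()
    return ScoreVector("CBC", graph.labels, scores)


def comm_centrality(
    graph: Graph,
    partition: Partition,
    profiles: CommunityProfiles | None = None,
    R: float = 1.0,
) -> ScoreVector:
    """Comm centrality (Gupta et al.).

    Within community c with mixing fraction mu_c (share of c's link
    endpoints that leave c):

        (1 + mu_c) * (k_intra / max intra in c) * R
        + (1 - mu_c) * ((k_inter / max inter in c) * R)^2

    Zero-maximum terms contribute 0 by convention.
    """
    prof = _profiles(graph, partition, profiles)
    memb = partition.membership
    c_count = partition.C
    k_c = np.bincount(memb, weights=prof.k, minlength=c_count)
    inter_c = np.bincount(memb, weights=prof.k_inter, minlength=c_count)
    with np.errstate(invalid="ignore"):
        mu_c = np.where(k_c > 0, inter_c / np.maximum(k_c, 1), 0.0)
    max_intra = np.zeros(c_count)
    max_inter = np.zeros(c_count)
    np.maximum.at(max_intra, memb, prof.k_intra)
    np.maximum.at(max_inter, memb, prof.k_inter)
    intra_term = np.where(
        max_intra[memb] > 0, prof.k_intra / np.maximum(max_intra[memb], 1), 0.0
    )
    inter_term = np.where(
        max_inter[memb] > 0, prof.k_inter / np.maximum(max_inter[memb], 1), 0.0
    )
    scores = (1.0 + mu_c[memb]) * intra_term * R + (1.0 - mu_c[memb]) * (
        inter_term * R
    ) ** 2
    return ScoreVector("Comm", graph.labels, scores)


def _core_numbers(n: int, edges: np.ndarray) -> np.ndarray:
    """Iterative k-core decomposition of the graph given by ``edges`` (2xE)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges.T)
    core = nx.core_number(g)
    return np.fromiter((core[i] for i in range(n)), dtype=float)


def kshell_with_community(
    graph: Graph,
    partition: Partition,
    profiles: CommunityProfiles | None = None,
    delta: float = 0.5,
) -> ScoreVector:
    """delta * ks_intra + (1 - delta) * ks_inter.

    ``ks_intra`` is the k-shell index on the subgraph of intra-community
    edges only, ``ks_inter`` on the inter-community edges only.
    """
    memb = partition.membership
    intra = memb[graph.edge_array[0]] == memb[graph.edge_array[1]]
    ks_intra = _core_numbers(graph.N, graph.edge_array[:, intra])
    ks_inter = _core_numbers(graph.N, graph.edge_array[:, ~intra])
    scores = delta * ks_intra + (1.0 - delta) * ks_inter
    return ScoreVector("ks", graph.labels, scores)


def community_based_mediator(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> ScoreVector:
    """CBM_i = H_i * k_i / sum_j k_j with H_i the natural-log entropy of the
    (intra, inter) degree split; 0 log 0 = 0."""
    prof = _profiles(graph, partition, profiles)
    if np.any(prof.k == 0):
        raise ValueError("community-based mediator undefined for isolated nodes")
    rho = np.stack([prof.k_intra / prof.k, prof.k_inter / prof.k])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rho > 0, rho * np.log(rho), 0.0)
    entropy = -terms.sum(axis=0)
    scores = entropy * prof.k / prof.k.sum()
    return ScoreVector("CBM", graph.labels, scores)


def community_hub_bridge(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> ScoreVector:
    """CHB_i = n_{c_i} * k_intra + NNC_i * k_inter."""
    prof = _profiles(graph, partition, profiles)
    n_c = partition.sizes[partition.membership]
    scores = n_c * prof.k_intra + prof.nnc * prof.k_inter
    return ScoreVector("CHB", graph.labels, scores.astype(float))


def modularity_vitality(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> dict[str, ScoreVector]:
    """Vitality v(i) = Q(G) - Q(G minus i), computed by exact aggregate
    updates, returned under three rankings:

    - ``MV+``  : v itself (hubs: removing them hurts modularity most),
    - ``MV-``  : -v (bridges: removing them raises modularity),
    - ``|MV|`` : |v| (hubs and bridges together).

    When removing a node empties the graph, Q(G minus i) = 0 by convention.
    """
    if graph.M < 1:
        raise ValueError("modularity vitality requires at least one edge")
    prof = _profiles(graph, partition, profiles)
    memb = partition.membership
    m = float(graph.M)
    c_count = partition.C
    intra = memb[graph.edge_array[0]] == memb[graph.edge_array[1]]
    e_c = np.bincount(
        memb[graph.edge_array[0][intra]], minlength=c_count
    ).astype(float)
    d_c = np.bincount(memb, weights=graph.degrees, minlength=c_count)
    q_full = float(np.sum(e_c / m - (d_c / (2 * m)) ** 2))

    kbc = prof.k_by_comm.toarray()  # N x C link counts
    v = np.empty(graph.N)
    for i in range(graph.N):
        ki = float(graph.degrees[i])
        m_new = m - ki
        if m_new < 1:
            v[i] = q_full  # Q of the emptied graph is 0 by convention
            continue
        e_new = e_c.copy()
        e_new[memb[i]] -= prof.k_intra[i]
        d_new = d_c - kbc[i]
        d_new[memb[i]] -= ki
        q_new = float(np.sum(e_new / m_new - (d_new / (2 * m_new)) ** 2))
        v[i] = q_full - q_new
    return {
        "MV+": ScoreVector("MV+", graph.labels, v.copy()),
        "MV-": ScoreVector("MV-", graph.labels, -v),
        "|MV|": ScoreVector("|MV|", graph.labels, np.abs(v)),
    }


def map_equation_centrality(
    graph: Graph, partition: Partition, profiles: CommunityProfiles | None = None
) -> ScoreVector:
    """Codelength vitality of node removal under the two-level map equation.

    Score of node i is L(G) - L(G minus i): removing a node whose flow the
    modular code exploits heavily (a high intra-degree node) shrinks the
    remaining description the most, so such nodes score highest.  The
    partition is restricted to the remaining nodes; a graph emptied of
    edges has codelength 0 by convention.
    """
    if graph.M < 1:
        raise ValueError("map-equation centrality requires at least one edge")
    prof = _profiles(graph, partition, profiles)
    memb = partition.membership
    k = graph.degrees.astype(float)
    intra = memb[graph.edge_array[0]] == memb[graph.edge_array[1]]
    k_inter = np.zeros(graph.N)
    ends = np.concatenate([graph.edge_array[0][~intra], graph.edge_array[1][~intra]])
    np.add.at(k_inter, ends, 1.0)
    l_full, _, _ = codelength_from_arrays(k, k_inter, memb, partition.C)

    indptr, indices = graph.adj.indptr, graph.adj.indices
    scores = np.empty(graph.N)
    for i in range(graph.N):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        k_new = k.copy()
        k_new[nbrs] -= 1.0
        k_new[i] = 0.0
        ki_new = k_inter.copy()
        cross = nbrs[memb[nbrs] != memb[i]]
        ki_new[cross] -= 1.0
        ki_new[i] = 0.0
        l_new, _, _ = codelength_from_arrays(k_new, ki_new, memb, partition.C)
        scores[i] = l_full - l_new
    return ScoreVector("MapEq", graph.labels, scores)


def rank(scores: ScoreVector) -> Ranking:
    """Stable ranking: descending score, ties broken by ascending label."""
    if np.any(~np.isfinite(scores.scores)):
        raise ValueError("scores must be finite to rank")
    order = sorted(
        range(len(scores.labels)),
        key=lambda i: (-scores.scores[i], scores.labels[i]),
    )
    return Ranking(scores.measure_id, [scores.labels[i] for i in order])


# --------------------------------------------------------------------------
# registry used by the evaluation sweep and the CLI

MEASURES = (
    "deg",
    "pc",
    "cbc",
    "comm",
    "ks",
    "cbm",
    "chb",
    "mv+",
    "mv-",
    "mvabs",
    "mapeq",
)

_MV_KEY = {"mv+": "MV+", "mv-": "MV-", "mvabs": "|MV|"}


def compute_measure(
    measure: str,
    graph: Graph,
    partition: Partition,
    profiles: CommunityProfiles | None = None,
    *,
    R: float = 1.0,
    delta: float = 0.5,
    _mv_cache: dict | None = None,
) -> ScoreVector:
    """Compute one measure by its CLI identifier."""
    measure = measure.lower()
    if measure == "deg":
        return degree_baseline(graph)
    if measure == "pc":
        return participation_coefficient(graph, partition, profiles)
    if measure == "cbc":
        return community_based_centrality(graph, partition, profiles)
    if measure == "comm":
        return comm_centrality(graph, partition, profiles, R=R)
    if measure == "ks":
        return kshell_with_community(graph, partition, profiles, delta=delta)
    if measure == "cbm":
        return community_based_mediator(graph, partition, profiles)
    if measure == "chb":
        return community_hub_bridge(graph, partition, profiles)
    if measure in _MV_KEY:
        if _mv_cache is not None and "mv" in _mv_cache:
            trio = _mv_cache["mv"]
        else:
            trio = modularity_vitality(graph, partition, profiles)
            if _mv_cache is not None:
                _mv_cache["mv"] = trio
        return trio[_MV_KEY[measure]]
    if measure == "mapeq":
        return map_equation_centrality(graph, partition, profiles)
    raise ValueError(f"unknown measure {measure!r}")
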