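"""Core graph and partition data model.

Networks are simple, undirected and unweighted.  Node labels are opaque
strings; internally every node is mapped to a contiguous index through a
label -> index map sorted lexicographically, so all derived quantities are
independent of file line order.

The module also provides the shared structural quantities the rest of the
package consumes: per-node community profiles (intra/inter degree splits),
Newman modularity, and the empirical mixing parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "Partition",
    "NodeCommunityProfile",
    "CommunityProfiles",
    "LoadReport",
    "GraphParseError",
    "read_edge_list",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "community_profiles",
    "modularity",
    "empirical_mixing",
]


class GraphParseError(ValueError):
    """Raised for malformed edge-list or partition files."""


@dataclass
class LoadReport:
    """What was silently dropped while loading an edge list."""

    n_duplicate_edges: int = 0
    n_self_loops: int = 0


class Graph:
    """Simple undirected unweighted graph.

    Parameters
    ----------
    edges
        Iterable of (u, v) label pairs.  Duplicates (in either orientation)
        and self-loops are dropped and counted in :attr:`load_report`.
    nodes
        Optional iterable of extra node labels (isolated nodes).
    """

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        seen: set[tuple[str, str]] = set()
        report = LoadReport()
        labels: set[str] = {str(n) for n in nodes}
        for u, v in edges:
            u, v = str(u), str(v)
            labels.add(u)
            labels.add(v)
            if u == v:
                report.n_self_loops += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in seen:
                report.n_duplicate_edges += 1
                continue
            seen.add(key)
        if not labels:
            raise ValueError("graph must have at least one node")
        self.labels: tuple[str, ...] = tuple(sorted(labels))
        self.index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        if seen:
            ii = np.fromiter((self.index[u] for u, v in seen), dtype=np.int64)
            jj = np.fromiter((self.index[v] for u, v in seen), dtype=np.int64)
            self.edge_array = np.stack([ii, jj])  # 2 x M, u-index < v-index as labels
            data = np.ones(len(seen), dtype=np.float64)
            adj = sp.coo_matrix((data, (ii, jj)), shape=(n, n))
            adj = adj + adj.T
            self.adj = adj.tocsr()
        else:
            self.edge_array = np.zeros((2, 0), dtype=np.int64)
            self.adj = sp.csr_matrix((n, n), dtype=np.float64)
        self.degrees = np.asarray(self.adj.sum(axis=1)).ravel().astype(np.int64)
        self.load_report = report

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def M(self) -> int:
        return self.edge_array.shape[1]

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of node index ``i``."""
        return self.adj.indices[self.adj.indptr[i] : self.adj.indptr[i + 1]]

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.labels[u], self.labels[v]) for u, v in self.edge_array.T
        ]

    def subgraph_without(self, i: int) -> "Graph":
        """Copy of the graph with node index ``i`` and its edges removed."""
        keep = (self.edge_array[0] != i) & (self.edge_array[1] != i)
        edges = [
            (self.labels[u], self.labels[v])
            for u, v in self.edge_array[:, keep].T
        ]
        nodes = [lab for j, lab in enumerate(self.labels) if j != i]
        return Graph(edges, nodes=nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(N={self.N}, M={self.M})"


class Partition:
    """Node -> community assignment for a given graph.

    Every node of the graph belongs to exactly one non-empty community.
    Community labels are opaque; internally communities are indexed
    0..C-1 in lexicographic order of their labels.
    """

    def __init__(self, graph: Graph, assignment: Mapping[str, str]):
        missing = [lab for lab in graph.labels if lab not in assignment]
        unknown = [lab for lab in assignment if lab not in graph.index]
        if missing or unknown:
            raise ValueError(
                f"partition does not cover graph exactly: "
                f"missing={missing[:10]}, unknown={unknown[:10]}"
            )
        self.graph_labels = graph.labels
        self.comm_labels: tuple[str, ...] = tuple(
            sorted({str(assignment[lab]) for lab in graph.labels})
        )
        cidx = {c: i for i, c in enumerate(self.comm_labels)}
        self.membership = np.fromiter(
            (cidx[str(assignment[lab])] for lab in graph.labels), dtype=np.int64
        )
        self.sizes = np.bincount(self.membership, minlength=self.C)

    @property
    def C(self) -> int:
        return len(self.comm_labels)

    @property
    def assignment(self) -> dict[str, str]:
        return {
            lab: self.comm_labels[c]
            for lab, c in zip(self.graph_labels, self.membership)
        }

    @property
    def communities(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.membership == c) for c in range(self.C)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(C={self.C}, sizes={sorted(self.sizes, reverse=True)[:8]})"


@dataclass
class NodeCommunityProfile:
    """Degree split of one node with respect to a partition."""

    k: int
    k_intra: int
    k_inter: int
    k_by_comm: dict[str, int] = field(default_factory=dict)
    nnc: int = 0  # number of distinct *other* neighboring communities


class CommunityProfiles:
    """Vectorized per-node community profiles.

    Attributes
    ----------
    k, k_intra, k_inter, nnc : int arrays aligned with ``graph.labels``.
    k_by_comm : CSR matrix (N x C), entry (i, c) = number of links from
        node i into community c (including its own community).
    """

    def __init__(self, graph: Graph, partition: Partition):
        if partition.graph_labels != graph.labels:
            raise ValueError("partition was built for a different graph")
        n, c = graph.N, partition.C
        memb = partition.membership
        # one-hot community indicator (N x C); adj @ onehot tallies k_{i,c}
        onehot = sp.csr_matrix(
            (np.ones(n), (np.arange(n), memb)), shape=(n, c)
        )
        kbc = (graph.adj @ onehot).tocsr()
        kbc.eliminate_zeros()
        self.graph = graph
        self.partition = partition
        self.k_by_comm = kbc
        self.k = graph.degrees.copy()
        self.k_intra = np.asarray(
            kbc[np.arange(n), memb]
        ).ravel().astype(np.int64)
        self.k_inter = self.k - self.k_intra
        # distinct adjacent communities = nonzeros per row; subtract own
        # community when the node has intra links
        n_adj = np.diff(kbc.indptr).astype(np.int64)
        self.nnc = n_adj - (self.k_intra > 0)

    def __getitem__(self, label: str) -> NodeCommunityProfile:
        i = self.graph.index[label]
        row = self.k_by_comm.getrow(i)
        by_comm = {
            self.partition.comm_labels[c]: int(v)
            for c, v in zip(row.indices, row.data)
        }
        return NodeCommunityProfile(
            k=int(self.k[i]),
            k_intra=int(self.k_intra[i]),
            k_inter=int(self.k_inter[i]),
            k_by_comm=by_comm,
            nnc=int(self.nnc[i]),
        )


def read_edge_list(path) -> Graph:
    """Read a whitespace-separated edge list; '#' lines are comments.

    Duplicate edges and self-loops are dropped silently and counted in the
    returned graph's :attr:`Graph.load_report`.
    """
    edges: list[tuple[str, str]] = []
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected two node labels, got {stripped!r}"
                )
            edges.append((parts[0], parts[1]))
            n_lines += 1
    if n_lines == 0:
        raise GraphParseError(f"{path}: no edges found")
    return Graph(edges)


def write_edge_list(graph: Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges():
            fh.write(f"{u} {v}\n")


def read_partition(path, graph: Graph) -> Partition:
    """Read a ``node<TAB>community`` file covering exactly the graph's nodes."""
    assignment: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                parts = stripped.split()
            if len(parts) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 'node<TAB>community', got {stripped!r}"
                )
            assignment[parts[0]] = parts[1]
    return Partition(graph, assignment)


def write_partition(partition: Partition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab in partition.graph_labels:
            fh.write(f"{lab}\t{partition.assignment[lab]}\n")


def community_profiles(graph: Graph, partition: Partition) -> CommunityProfiles:
    """Per-node intra/inter degree split and per-community link counts."""
    return CommunityProfiles(graph, partition)


def modularity(graph: Graph, partition: Partition) -> float:
    """Newman modularity Q = sum_c [ e_c/M - (d_c / 2M)^2 ].

    ``e_c`` counts intra-community edges, ``d_c`` the total degree of
    community c.  Undefined (error) on an empty graph.
    """
    m = graph.M
    if m < 1:
        raise ValueError("modularity undefined for a graph with no edges")
    memb = partition.membership
    intra = memb[graph.edge_array[0]] == memb[graph.edge_array[1]]
    e_c = np.bincount(memb[graph.edge_array[0][intra]], minlength=partition.C)
    d_c = np.bincount(memb, weights=graph.degrees, minlength=partition.C)
    return float(np.sum(e_c / m - (d_c / (2.0 * m)) ** 2))


def empirical_mixing(
    graph: Graph, partition: Partition, method: str = "edges"
) -> float:
    """Realized mixing parameter of a partitioned graph.

    ``method="edges"`` (default) is the edge-weighted global fraction
    sum_i k_i^inter / sum_i k_i, which matches the LFR generator's
    constraint in expectation.  ``method="nodes"`` is the unweighted
    per-node mean of k_i^inter / k_i; the two diverge on graphs with
    heterogeneous degrees (e.g. stars).
    """
    if np.any(graph.degrees == 0):
        raise ValueError("mixing parameter undefined with isolated nodes")
    prof = community_profiles(graph, partition)
    if method == "edges":
        return float(prof.k_inter.sum() / prof.k.sum())
    if method == "nodes":
        return float(np.mean(prof.k_inter / prof.k))
    raise ValueError(f"unknown method {method!r}")
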