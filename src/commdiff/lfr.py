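"""LFR-style benchmark graphs with planted communities.

The generator produces networks with a truncated power-law degree
distribution (exponent gamma), power-law community sizes (exponent theta)
bounded to [c_min, c_max], and a tunable mixing parameter mu — the expected
fraction of each node's links that leave its community.  Low mu yields a
strong, well-separated community structure; mu near 1 dissolves it.

The construction follows the classic two-phase benchmark procedure:

1. sample a degree sequence from a truncated power law whose lower cutoff
   is tuned so the expected mean degree matches ``k_avg``, and community
   sizes from a power law on [c_min, c_max] summing to N;
2. split each node's degree into an internal part (stochastic rounding of
   ``(1-mu)*k``) and an external part, assign nodes to communities that can
   host their internal degree, and realize intra- and inter-community edges
   with configuration-model stub matching plus bounded swap repair so the
   graph stays simple.

Stochastic rounding keeps the expected internal fraction exactly ``1-mu``,
so the realized mixing concentrates tightly around the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition, empirical_mixing

__all__ = ["LFRParams", "LFRRealizationReport", "generate_lfr", "validate_realization"]

#: realized mixing must fall within this distance of the target
MIXING_TOLERANCE = 0.05


@dataclass
class LFRParams:
    """Parameters of one LFR benchmark realization.

    Defaults are desk-scale study conditions: 1000 nodes, mean degree 10,
    maximum degree 50, community sizes between 10 and 100.
    """

    N: int = 1000
    k_avg: float = 10.0
    k_max: int = 50
    gamma: float = 2.7
    theta: float = 2.0
    mu: float = 0.05
    c_min: int = 10
    c_max: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")
        if self.gamma <= 1 or self.theta <= 1:
            raise ValueError("power-law exponents must exceed 1")
        if self.c_min < 2:
            raise ValueError("c_min must be >= 2")
        if self.c_max > self.N:
            raise ValueError("c_max cannot exceed N")
        if self.k_max >= self.N:
            raise ValueError("k_max must be < N")
        if self.k_avg >= self.k_max:
            raise ValueError("k_avg must be below k_max")
        # the largest community must be able to host the largest intra-degree
        if self.k_max * (1.0 - self.mu) > self.c_max - 1:
            raise ValueError(
                "infeasible parameters: k_max*(1-mu) "
                f"= {self.k_max * (1 - self.mu):.1f} exceeds c_max-1 = {self.c_max - 1}"
            )


@dataclass
class LFRRealizationReport:
    realized_mu: float
    mean_degree: float
    gamma_hat: float
    community_sizes: tuple[int, int, float]  # (min, max, median)
    n_communities: int
    mixing_ok: bool
    sizes_ok: bool

    @property
    def passed(self) -> bool:
        return self.mixing_ok and self.sizes_ok


# --------------------------------------------------------------------------
# phase 1: degree and community-size sequences


def _truncated_powerlaw_mean(k_min: int, k_max: int, gamma: float) -> float:
    k = np.arange(k_min, k_max + 1, dtype=float)
    w = k**-gamma
    return float((k * w).sum() / w.sum())


def _sample_degrees(params: LFRParams, rng: np.random.Generator) -> np.ndarray:
    """Degrees from a truncated power law with mean tuned to k_avg.

    The integer lower cutoff bracketing k_avg is found by scanning, and the
    two adjacent cutoffs are mixed per-node so the expected mean equals
    k_avg exactly.
    """
    lo = 1
    while (
        lo < params.k_max
        and _truncated_powerlaw_mean(lo + 1, params.k_max, params.gamma) <= params.k_avg
    ):
        lo += 1
    m_lo = _truncated_powerlaw_mean(lo, params.k_max, params.gamma)
    m_hi = _truncated_powerlaw_mean(min(lo + 1, params.k_max), params.k_max, params.gamma)
    w_hi = 0.0 if m_hi <= m_lo else np.clip((params.k_avg - m_lo) / (m_hi - m_lo), 0, 1)

    def draw(k_min: int, size: int) -> np.ndarray:
        support = np.arange(k_min, params.k_max + 1, dtype=np.int64)
        p = support.astype(float) ** -params.gamma
        return rng.choice(support, size=size, p=p / p.sum())

    use_hi = rng.random(params.N) < w_hi
    degrees = np.empty(params.N, dtype=np.int64)
    degrees[~use_hi] = draw(lo, int((~use_hi).sum()))
    degrees[use_hi] = draw(min(lo + 1, params.k_max), int(use_hi.sum()))
    if degrees.sum() % 2:  # need an even number of stubs overall
        i = int(np.argmin(degrees))
        degrees[i] += 1
    return degrees


def _sample_community_sizes(params: LFRParams, rng: np.random.Generator) -> np.ndarray:
    support = np.arange(params.c_min, params.c_max + 1, dtype=np.int64)
    p = support.astype(float) ** -params.theta
    p /= p.sum()
    for _ in range(200):
        sizes: list[int] = []
        while sum(sizes) < params.N:
            sizes.append(int(rng.choice(support, p=p)))
        excess = sum(sizes) - params.N
        # shave the excess off communities that can spare it
        order = rng.permutation(len(sizes))
        for idx in order:
            if excess == 0:
                break
            spare = sizes[idx] - params.c_min
            take = min(spare, excess)
            sizes[idx] -= take
            excess -= take
        if excess == 0:
            return np.asarray(sizes, dtype=np.int64)
    raise RuntimeError("could not draw community sizes summing to N")


# --------------------------------------------------------------------------
# phase 2: assignment and edge realization


def _split_degrees(
    degrees: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Internal degree per node: stochastic rounding of (1-mu)*k."""
    target = (1.0 - mu) * degrees
    base = np.floor(target).astype(np.int64)
    frac = target - base
    return base + (rng.random(len(degrees)) < frac)


def _assign_communities(
    d_int: np.ndarray, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random assignment honoring per-community capacity n_c - 1 >= d_int."""
    n = len(d_int)
    for _ in range(50):
        free = sizes.copy()
        memb = np.full(n, -1, dtype=np.int64)
        order = np.argsort(-d_int, kind="stable")  # hardest first
        ok = True
        for i in order:
            feasible = np.flatnonzero((free > 0) & (sizes - 1 >= d_int[i]))
            if len(feasible) == 0:
                ok = False
                break
            c = int(rng.choice(feasible, p=free[feasible] / free[feasible].sum()))
            memb[i] = c
            free[c] -= 1
        if ok:
            return memb
    raise RuntimeError("could not place all nodes into communities")


def _match_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    existing: set[tuple[int, int]],
    same_group: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Pair stubs into simple edges; invalid pairs are repaired by edge
    swaps against already-accepted edges, and irreparable leftovers dropped.

    ``same_group`` (node -> group id), when given, additionally forbids
    edges inside a group (used for the inter-community stage).
    """

    def valid(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in existing or key in edges:
            return False
        if same_group is not None and same_group[u] == same_group[v]:
            return False
        return True

    edges: set[tuple[int, int]] = set()
    pool = stubs.copy()
    for _ in range(30):
        rng.shuffle(pool)
        leftovers: list[int] = []
        for a, b in zip(pool[0::2], pool[1::2]):
            u, v = int(a), int(b)
            if valid(u, v):
                edges.add((u, v) if u < v else (v, u))
            else:
                leftovers.extend((u, v))
        if len(pool) % 2:
            leftovers.append(int(pool[-1]))
        if not leftovers:
            return sorted(edges)
        pool = np.asarray(leftovers, dtype=np.int64)
        if len(pool) < 2:
            break
        # targeted swap repair: pull apart an accepted edge (x, y) so that
        # (u, x) and (v, y) both become valid
        if len(pool) <= 8 and edges:
            edge_list = list(edges)
            repaired: list[int] = []
            for a, b in zip(pool[0::2], pool[1::2]):
                u, v = int(a), int(b)
                done = False
                for j in rng.permutation(len(edge_list))[:200]:
                    x, y = edge_list[j]
                    if (x, y) not in edges:
                        continue
                    for xx, yy in ((x, y), (y, x)):
                        if valid(u, xx) and valid(v, yy):
                            edges.remove((x, y))
                            edges.add((u, xx) if u < xx else (xx, u))
                            edges.add((v, yy) if v < yy else (yy, v))
                            done = True
                            break
                    if done:
                        break
                if not done:
                    repaired.extend((u, v))
            if len(pool) % 2:
                repaired.append(int(pool[-1]))
            pool = np.asarray(repaired, dtype=np.int64)
            if len(pool) < 2:
                break
    return sorted(edges)  # leftover stubs dropped


def _realize(params: LFRParams, rng: np.random.Generator) -> tuple[Graph, Partition]:
    degrees = _sample_degrees(params, rng)
    sizes = _sample_community_sizes(params, rng)
    d_int = _split_degrees(degrees, params.mu, rng)
    np.minimum(d_int, degrees, out=d_int)
    memb = _assign_communities(d_int, sizes, rng)
    n_comm = len(sizes)

    # per-community stub sums must be even; bump one member up or down
    for c in range(n_comm):
        members = np.flatnonzero(memb == c)
        if d_int[members].sum() % 2:
            room = members[(d_int[members] < np.minimum(degrees[members], sizes[c] - 1))]
            if len(room):
                d_int[int(rng.choice(room))] += 1
            else:
                nonzero = members[d_int[members] > 0]
                d_int[int(rng.choice(nonzero))] -= 1
    d_ext = degrees - d_int
    if d_ext.sum() % 2:
        candidates = np.flatnonzero(d_ext > 0)
        if len(candidates):
            i = int(rng.choice(candidates))
            d_ext[i] -= 1
        else:  # everything internal; make room on one node
            i = int(np.argmax(degrees))
            d_ext[i] += 1
            d_int[i] -= 1

    edges: set[tuple[int, int]] = set()
    for c in range(n_comm):
        members = np.flatnonzero(memb == c)
        stubs = np.repeat(members, d_int[members])
        edges.update(_match_stubs(stubs, rng, existing=edges))
    stubs = np.repeat(np.arange(params.N), d_ext)
    edges.update(_match_stubs(stubs, rng, existing=edges, same_group=memb))

    width = len(str(params.N - 1))
    label = [f"n{i:0{width}d}" for i in range(params.N)]
    graph = Graph(
        [(label[u], label[v]) for u, v in sorted(edges)], nodes=label
    )
    assignment = {label[i]: f"c{memb[i]:04d}" for i in range(params.N)}
    return graph, Partition(graph, assignment)


def generate_lfr(params: LFRParams) -> tuple[Graph, Partition]:
    """Generate one LFR benchmark graph and its planted partition.

    Deterministic for fixed ``params.seed``.  A realization is rejected and
    redrawn (bounded, deterministic retry sequence) if it leaves isolated
    nodes or its realized mixing falls outside ``MIXING_TOLERANCE`` of the
    target.
    """
    params.validate()
    last_err: Exception | None = None
    for attempt in range(10):
        rng = np.random.default_rng([params.seed, attempt])
        try:
            graph, partition = _realize(params, rng)
        except RuntimeError as err:
            last_err = err
            continue
        if np.any(graph.degrees == 0):
            last_err = ValueError("realization produced isolated nodes")
            continue
        realized = empirical_mixing(graph, partition)
        if abs(realized - params.mu) <= MIXING_TOLERANCE:
            return graph, partition
        last_err = ValueError(
            f"realized mixing {realized:.3f} outside tolerance of target {params.mu}"
        )
    raise RuntimeError(f"LFR generation failed after bounded retries: {last_err}")


def _powerlaw_mle(values: np.ndarray, x_min: int) -> float:
    """Clauset-style continuous-approximation MLE of a discrete power-law
    tail exponent: alpha = 1 + n / sum(ln(x / (x_min - 1/2)))."""
    tail = values[values >= x_min]
    if len(tail) < 2:
        return float("nan")
    return float(1.0 + len(tail) / np.sum(np.log(tail / (x_min - 0.5))))


def validate_realization(
    graph: Graph, partition: Partition, params: LFRParams
) -> LFRRealizationReport:
    """Check a generated (graph, partition) pair against its parameters."""
    realized = empirical_mixing(graph, partition)
    k_min_tail = max(2, int(round(params.k_avg)))
    gamma_hat = _powerlaw_mle(graph.degrees.astype(float), k_min_tail)
    sizes = partition.sizes
    return LFRRealizationReport(
        realized_mu=realized,
        mean_degree=float(graph.degrees.mean()),
        gamma_hat=gamma_hat,
        community_sizes=(int(sizes.min()), int(sizes.max()), float(np.median(sizes))),
        n_communities=partition.C,
        mixing_ok=abs(realized - params.mu) <= MIXING_TOLERANCE,
        sizes_ok=bool(sizes.min() >= params.c_min and sizes.max() <= params.c_max),
    )
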