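"""Discrete-time Monte-Carlo simulators for SI, SIR, IC and LT dynamics.

All four models share one synchronous (parallel) update engine over the
graph's sparse adjacency: at each iteration the set of nodes that changes
state is computed from the state at the start of the iteration.  This makes
"iterations" the common time unit across models and turns the linear
threshold model into a deterministic fixed-point iteration.

Conventions that shift outbreak sizes, fixed here:

- SIR order within a step: infection attempts first (from the step-start
  infected set), then each of those infected nodes recovers with
  probability psi.  A node can never be infected and recover in the same
  step; the newly infected first transmit at the next step.
- IC: only the frontier (nodes activated at the previous step) attempts,
  once per inactive neighbor.
- LT: inactive node v activates when m_v / k_v >= xi_v with at least one
  active neighbor; active nodes never deactivate.

Per-repetition RNG streams are derived from the master seed by repetition
index, so repetitions are reproducible independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph

__all__ = [
    "DiffusionConfig",
    "DiffusionOutcome",
    "critical_threshold",
    "default_lambda",
    "simulate_si",
    "simulate_sir",
    "simulate_ic",
    "simulate_lt",
    "simulate",
]


@dataclass
class DiffusionConfig:
    """Parameters shared by the four models.

    lambda_ / psi are the SI & SIR per-contact infection and per-step
    recovery probabilities; p is the IC activation probability (scalar, or
    a per-edge map keyed by label pairs); threshold is the LT fractional
    threshold xi (scalar or per-node map).  ``reps`` independent
    repetitions are run, with per-rep RNG streams derived from ``seed``.
    """

    model: str = "sir"
    lambda_: float | None = None
    psi: float = 1.0
    p: float | dict | None = None
    threshold: float | dict = 0.5
    max_steps: int = 10_000
    reps: int = 100
    seed: int = 0
    stop_at_half: bool = True  # SI only: stop once half the network is infected

    def validate(self) -> None:
        for name, val in (("lambda_", self.lambda_), ("psi", self.psi)):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if isinstance(self.p, float) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.reps < 1 or self.max_steps < 1:
            raise ValueError("reps and max_steps must be >= 1")


@dataclass
class RepResult:
    final_counts: dict[str, int]
    steps: int
    t50: int | None = None  # SI: step at which >= 50% infected
    terminated: bool = True
    trajectory: list[tuple[int, ...]] = field(default_factory=list)


@dataclass
class DiffusionOutcome:
    model: str
    N: int
    reps: list[RepResult]

    @property
    def final_sizes(self) -> np.ndarray:
        """Ever-infected / ever-activated count per repetition."""
        key = {"si": "I", "sir": "R", "ic": "active", "lt": "active"}[self.model]
        if self.model == "sir":
            return np.array(
                [r.final_counts["R"] + r.final_counts["I"] for r in self.reps]
            )
        return np.array([r.final_counts[key] for r in self.reps])

    @property
    def mean_final_size(self) -> float:
        return float(self.final_sizes.mean())


def critical_threshold(graph: Graph) -> float:
    """Heterogeneous mean-field epidemic threshold <k> / (<k^2> - <k>)."""
    k = graph.degrees.astype(float)
    denom = (k**2).mean() - k.mean()
    if denom <= 0:
        raise ValueError("degenerate degree sequence")
    return float(k.mean() / denom)


def default_lambda(graph: Graph, factor: float = 1.5) -> float:
    """Default infection rate 1.5 x the network's critical threshold,
    clipped to [0, 1] — above-threshold so spreading phenomena are visible."""
    return float(min(1.0, factor * critical_threshold(graph)))


def _seed_indices(graph: Graph, seeds) -> np.ndarray:
    idx = np.array(sorted(graph.index[s] for s in seeds), dtype=np.int64)
    if len(idx) == 0:
        raise ValueError("seed set must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate seed nodes")
    return idx


def _rng(cfg: DiffusionConfig, rep: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, rep])


def simulate_si(graph: Graph, seeds, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Susceptible-Infected dynamics.

    Each infected node attempts to infect each susceptible neighbor
    independently with probability lambda; infections are permanent.  By
    default a run stops once at least half the network is infected (the
    crossing step is recorded as t50); runs that never cross carry
    t50 = None and are censored at max_steps.
    """
    cfg.validate()
    if cfg.lambda_ is None:
        raise ValueError("SI requires lambda_")
    lam = cfg.lambda_
    seed_idx = _seed_indices(graph, seeds)
    target = math.ceil(graph.N / 2)
    adj = graph.adj
    results = []
    for rep in range(cfg.reps):
        rng = _rng(cfg, rep)
        infected = np.zeros(graph.N, dtype=bool)
        infected[seed_idx] = True
        t50 = 0 if infected.sum() >= target else None
        traj = [(int(graph.N - infected.sum()), int(infected.sum()))]
        step = 0
        terminated = True
        while not (cfg.stop_at_half and t50 is not None):
            if step >= cfg.max_steps:
                terminated = False
                break
            m = adj @ infected.astype(np.float64)
            sus = ~infected
            exposed = sus & (m > 0)
            if lam > 0 and not exposed.any():
                break  # no susceptible node can ever be reached
            if lam == 0:
                break
            prob = 1.0 - (1.0 - lam) ** m[exposed]
            new = np.flatnonzero(exposed)[rng.random(exposed.sum()) < prob]
            step += 1
            if len(new) == 0 and not exposed.any():
                break
            infected[new] = True
            traj.append((int(graph.N - infected.sum()), int(infected.sum())))
            if t50 is None and infected.sum() >= target:
                t50 = step
            if infected.all():
                break
        results.append(
            RepResult(
                final_counts={
                    "S": int(graph.N - infected.sum()),
                    "I": int(infected.sum()),
                },
                steps=step,
                t50=t50,
                terminated=terminated,
                trajectory=traj,
            )
        )
    return DiffusionOutcome("si", graph.N, results)


def simulate_sir(graph: Graph, seeds, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Susceptible-Infected-Recovered dynamics.

    Per step: the step-start infected set attempts infections as in SI,
    then each of those nodes recovers with probability psi.  Terminates
    when no infected node remains; the final recovered count is the
    outbreak size.
    """
    cfg.validate()
    if cfg.lambda_ is None:
        raise ValueError("SIR requires lambda_")
    lam, psi = cfg.lambda_, cfg.psi
    seed_idx = _seed_indices(graph, seeds)
    adj = graph.adj
    results = []
    for rep in range(cfg.reps):
        rng = _rng(cfg, rep)
        infected = np.zeros(graph.N, dtype=bool)
        recovered = np.zeros(graph.N, dtype=bool)
        infected[seed_idx] = True
        traj = [(int(graph.N - len(seed_idx)), int(len(seed_idx)), 0)]
        step = 0
        terminated = True
        while infected.any():
            if step >= cfg.max_steps:
                terminated = False
                break
            step += 1
            m = adj @ infected.astype(np.float64)
            sus = ~infected & ~recovered
            exposed = sus & (m > 0)
            new = np.flatnonzero(exposed)[
                rng.random(exposed.sum()) < 1.0 - (1.0 - lam) ** m[exposed]
            ]
            recovering = np.flatnonzero(infected)[
                rng.random(infected.sum()) < psi
            ]
            infected[recovering] = False
            recovered[recovering] = True
            infected[new] = True
            traj.append(
                (
                    int(graph.N - infected.sum() - recovered.sum()),
                    int(infected.sum()),
                    int(recovered.sum()),
                )
            )
        results.append(
            RepResult(
                final_counts={
                    "S": int(graph.N - infected.sum() - recovered.sum()),
                    "I": int(infected.sum()),
                    "R": int(recovered.sum()),
                },
                steps=step,
                terminated=terminated,
                trajectory=traj,
            )
        )
    return DiffusionOutcome("sir", graph.N, results)


def _edge_probs(graph: Graph, p) -> np.ndarray | float:
    """Per-CSR-entry activation probabilities for IC."""
    if isinstance(p, dict):
        data = np.empty(graph.adj.nnz)
        indptr, indices = graph.adj.indptr, graph.adj.indices
        for u in range(graph.N):
            for pos in range(indptr[u], indptr[u + 1]):
                v = indices[pos]
                a, b = graph.labels[u], graph.labels[v]
                key = (a, b) if (a, b) in p else (b, a)
                data[pos] = p[key]
        if np.any((data < 0) | (data > 1)):
            raise ValueError("edge probabilities must lie in [0, 1]")
        return data
    return float(p)


def simulate_ic(graph: Graph, seeds, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Independent-cascade dynamics.

    Nodes activated at the previous step each get exactly one attempt per
    inactive neighbor, succeeding with probability P_{u,v}; the cascade
    ends when the frontier is empty.
    """
    cfg.validate()
    if cfg.p is None:
        raise ValueError("IC requires p")
    probs = _edge_probs(graph, cfg.p)
    per_edge = isinstance(probs, np.ndarray)
    seed_idx = _seed_indices(graph, seeds)
    indptr, indices = graph.adj.indptr, graph.adj.indices
    results = []
    for rep in range(cfg.reps):
        rng = _rng(cfg, rep)
        active = np.zeros(graph.N, dtype=bool)
        active[seed_idx] = True
        frontier = seed_idx
        traj = [(int(graph.N - active.sum()), int(active.sum()))]
        step = 0
        while len(frontier) and step < cfg.max_steps:
            step += 1
            starts = indptr[frontier]
            stops = indptr[frontier + 1]
            pos = np.concatenate(
                [np.arange(a, b) for a, b in zip(starts, stops)]
            ) if len(frontier) else np.empty(0, dtype=np.int64)
            targets = indices[pos]
            pr = probs[pos] if per_edge else probs
            hit = targets[(~active[targets]) & (rng.random(len(targets)) < pr)]
            frontier = np.unique(hit)
            active[frontier] = True
            traj.append((int(graph.N - active.sum()), int(active.sum())))
        results.append(
            RepResult(
                final_counts={
                    "inactive": int(graph.N - active.sum()),
                    "active": int(active.sum()),
                },
                steps=step,
                trajectory=traj,
            )
        )
    return DiffusionOutcome("ic", graph.N, results)


def simulate_lt(graph: Graph, seeds, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Linear-threshold dynamics (deterministic given thresholds).

    Per step, every inactive node v with at least one active neighbor and
    m_v / k_v >= xi_v activates; the process runs to its fixed point.
    Degree-0 nodes never activate.
    """
    cfg.validate()
    if isinstance(cfg.threshold, dict):
        xi = np.array([cfg.threshold[lab] for lab in graph.labels], dtype=float)
    else:
        xi = np.full(graph.N, float(cfg.threshold))
    if np.any((xi < 0) | (xi > 1)):
        raise ValueError("thresholds must lie in [0, 1]")
    seed_idx = _seed_indices(graph, seeds)
    adj = graph.adj
    k = np.maximum(graph.degrees, 1).astype(float)  # degree-0 guarded below
    results = []
    for rep in range(1):  # deterministic: one repetition suffices
        active = np.zeros(graph.N, dtype=bool)
        active[seed_idx] = True
        traj = [(int(graph.N - active.sum()), int(active.sum()))]
        step = 0
        while step < cfg.max_steps:
            m = adj @ active.astype(np.float64)
            new = (
                ~active
                & (m >= 1)
                & (graph.degrees > 0)
                & (m / k >= xi)
            )
            if not new.any():
                break
            step += 1
            active |= new
            traj.append((int(graph.N - active.sum()), int(active.sum())))
        results.append(
            RepResult(
                final_counts={
                    "inactive": int(graph.N - active.sum()),
                    "active": int(active.sum()),
                },
                steps=step,
                trajectory=traj,
            )
        )
    return DiffusionOutcome("lt", graph.N, results)


_SIMULATORS = {
    "si": simulate_si,
    "sir": simulate_sir,
    "ic": simulate_ic,
    "lt": simulate_lt,
}


def simulate(graph: Graph, seeds, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Dispatch on ``cfg.model``."""
    try:
        fn = _SIMULATORS[cfg.model.lower()]
    except KeyError:
        raise ValueError(f"unknown model {cfg.model!r}") from None
    return fn(graph, seeds, cfg)
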