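# Methods

## Scope and data model

`commdiff` studies how well community-aware centrality measures select
seed nodes for spreading processes.  All networks are simple, undirected
and unweighted.  Node labels are opaque strings; internally they map to
contiguous indices through a lexicographically sorted label→index table,
so every result is independent of file line order.  Duplicate edges and
self-loops in input files are dropped (public network files commonly
contain them) and counted in a load report rather than treated as errors.

A partition assigns every node to exactly one non-empty community.  From a
(graph, partition) pair the package derives per-node profiles — total
degree k, intra-community degree k_intra, inter-community degree k_inter,
per-community link counts k_{i,c}, and the number of distinct neighboring
communities (NNC) — which feed every centrality measure.

The mixing parameter of a partitioned network is reported by default as
the edge-weighted global fraction μ̂ = Σ_i k_i^inter / Σ_i k_i.  This
matches the constraint the LFR generator imposes in expectation and is a
partition-level quantity.  The unweighted per-node mean of k_inter/k is
exposed as an alternative (`method="nodes"`); the two coincide on degree-
regular graphs (and, curiously, on stars) but diverge whenever degrees are
heterogeneous, so the convention in use is always stated.

## Synthetic benchmark generator

`generate_lfr` implements the classic two-phase LFR construction:

1. Degrees are drawn from a truncated power law with exponent γ on
   [k_min, k_max], where the lower cutoff is tuned (by mixing the two
   adjacent integer cutoffs) so the expected mean degree equals ⟨k⟩.
   Community sizes come from a power law with exponent θ on
   [c_min, c_max], redrawn until they sum exactly to N.
2. Each node's degree is split into an internal part — *stochastic*
   rounding of (1−μ)·k, so the expected internal fraction is exactly
   1−μ — and an external remainder.  Nodes are assigned randomly to
   communities that can host their internal degree (capacity n_c − 1),
   hardest nodes first.  Intra-community edges are realized per community
   by configuration-model stub matching, inter-community edges by a global
   stub matching that forbids within-community pairs; invalid pairs are
   repaired by bounded edge swaps and irreparable leftover stubs dropped.

A realization is rejected and redrawn (bounded, deterministic retry
sequence derived from the seed) if it leaves isolated nodes or its
realized μ̂ falls outside ±0.05 of the target.  In practice realized
mixing concentrates within ±0.01 of the target for all three study
conditions μ ∈ {0.05, 0.2, 0.7}; stochastic rounding is what removes the
small-degree rounding bias that plagues deterministic (1−μ)·k rounding at
small μ.  Infeasible parameter combinations — most importantly
k_max·(1−μ) > c_max − 1, a node whose internal degree cannot fit in the
largest community — are rejected before any sampling.

Default sizes are desk-scale study conditions: N = 1000, ⟨k⟩ = 10,
k_max = 50, community sizes in [10, 100].  `validate_realization` reports
realized mixing, realized mean degree, a Clauset-style continuous-
approximation MLE of the degree-tail exponent (the tail cutoff defaults to
⟨k⟩; the estimate is upward-biased on max-degree-truncated sequences and
is informational), and community-size statistics with pass/fail flags.

## Community detection and the map equation

Louvain is implemented natively: greedy single-node moves over a seeded
permutation (ties between equally improving moves go to the lowest
community id), aggregation into super-nodes, repeat; a final node-level
refinement pass then removes any improving single-node move that
aggregation left behind, so the returned partition is a genuine local
optimum of modularity at node granularity, and deterministic under a fixed
seed.

Infomap is delegated to the igraph implementation of the Rosvall–Bergström
algorithm (two-level, undirected); igraph draws from Python's `random`
module, which is seeded locally for determinism.  The two-level
map-equation codelength itself is computed natively, because map-equation
centrality needs codelength arithmetic: with degree-proportional visit
rates p_i = k_i/2M and module exit rates q_m = (inter-community degree of
m)/2M,

    L = q↷·H(Q) + Σ_m p_m↻·H(P_m),

reported as index (inter-module) and module contributions whose sum is
always L.  No teleportation is used; zero-degree nodes and empty modules
contribute nothing.

## Centrality measures

All eight community-aware measures are deterministic functions of the
(graph, partition) pair, vectorized over nodes, and oriented so that
higher scores mean more influential seeds.  Choices worth noting:

- **Comm centrality** uses the community-level mixing μ_c = (inter-
  community endpoint count of c)/(total degree of c); zero-maximum
  normalizers contribute 0 by convention.  The scale constant R defaults
  to 1; it rescales the linear term against the quadratic one, and is
  configurable.
- **k-shell with community** combines the core indices of the intra-edge
  and inter-edge subgraphs with weight δ = 0.5 by default.
- **Community-based mediator** uses natural-log entropy; the base only
  rescales scores and never changes rankings.
- **Modularity vitality** v(i) = Q(G) − Q(G∖i) is computed by exact
  aggregate updates (community edge counts and degree totals change by
  closed-form amounts when a node is removed), which equals full
  recomputation to machine precision and is O(C) per node.  MV+ ranks by
  v (hubs: their removal hurts modularity), MV− by −v (bridges), |MV| by
  magnitude.  If removing a node empties the graph, Q(G∖i) ≡ 0.
- **Map-equation centrality** is the codelength vitality
  L(G) − L(G∖i) under the partition restricted to the remaining nodes,
  evaluated by a full recomputation of the two-level formula per removal
  (O(N) each, vectorized).  On strong-community benchmarks it correlates
  positively with intra-community degree, i.e. it prefers hub-like nodes.
- Rankings sort by descending score with ties broken by ascending node
  label, so they are total, stable and reproducible.  Degree-0 nodes are
  errors for the participation coefficient and the mediator (both are
  undefined at k = 0) and score 0 elsewhere.

## Diffusion engine

All four models run synchronously: state changes at step t+1 are computed
from the state at step t.  This makes "iterations" the shared time unit
and the linear threshold model a deterministic fixed-point iteration.
Within an SIR step, infection happens before recovery, from the step-start
infected set: a node can never be infected and recover in the same step,
and newly infected nodes first transmit one step later.  This ordering is
stated because it shifts outbreak sizes.

For scalar rates the per-step infection draw uses the binomial closure
P(infect) = 1 − (1−λ)^{m_v}, which is distributionally identical to
independent per-edge attempts; IC supports per-edge probabilities via
explicit edge draws.  LT activates an inactive node when it has at least
one active neighbor and m_v/k_v ≥ ξ_v (≥, not >); degree-0 nodes never
activate.  Per-repetition RNG streams derive from (master seed, repetition
index), so repetitions are independently reproducible and a fixed master
seed gives bitwise-identical outcomes.  Random per-repetition LT
thresholds are deliberately out of scope; thresholds are scalar or
per-node maps.

SI runs stop at the 50%-infection crossing by default (the crossing step
is the T50 statistic); runs that never cross are censored at the step cap
and contribute the cap to T50 rather than being dropped, which would bias
T50 downward for poor measures.

## Evaluation protocol

Seeds are the top n = max(1, round-half-up(f_o·N)) nodes of a measure's
ranking, f_o ∈ (0, 0.5].  For ΔR/ΔA the degree-baseline simulations at
each (model, budget) cell are computed once, with the same cell-derived
RNG seed as every candidate, and reused — so baseline noise is common
across candidates and the baseline against itself is exactly zero.  Cell
failures are recorded as failed rows and the sweep continues.  Default
repetitions per cell: 100 (the scaled-down study runs below use 15–20).

## Study conditions for the headline runs

The acceptance script and tests rerun the synthetic study at desk scale:
N = 1000, three network realizations per condition, 15–20 Monte-Carlo
repetitions per cell.  One sweep varies θ ∈ {2, 2.7, 3} at γ = 2.7, the
other γ ∈ {2, 2.7, 3} at θ = 2.7; anchoring both sweeps at a shared
(γ, θ) = (2.7, 2.7) middle condition keeps their reference points mutually
consistent.  Mixing is 0.05 (strong community structure) except where the
community-strength effect itself is studied.

Rates: SIR and IC run at λ = p = 1.5·λ_c with λ_c = ⟨k⟩/(⟨k²⟩−⟨k⟩)
computed per network, and full recovery ψ = 1 — above the mean-field
threshold so outbreaks are visible without saturating.  The SI experiments
measure *time* (iterations to reach half the network), which is only a
discriminative statistic when spreading is slow; at 1.5·λ_c half the
network is infected within about two iterations from a 10–20% seed set and
every measure ties, so the SI runs use the canonical small per-contact
rate λ = 0.01, placing T50 in the tens of iterations where seed placement
matters.  LT uses the uniform fractional threshold ξ = 0.5.

## What the generator does and does not emulate

The LFR benchmarks reproduce heavy-tailed degrees, heavy-tailed community
sizes and tunable mixing — the three structural factors the study varies —
but not degree correlations, clustering beyond what the configuration
model induces, overlapping communities, or the idiosyncrasies of real
networks (platform artifacts, sampling bias, temporal aggregation).
Passing the synthetic-study checks therefore demonstrates that the
pipeline reproduces the *regime structure* of community-aware seeding on
controlled topologies; it does not by itself validate conclusions on any
particular real-world network, where partitions must first be detected
and are themselves detector-dependent.

## Known limitations

- The exact rates, repetition counts and LFR sizes behind the original
  printed figures are not restated in the main text they accompany; the
  conditions above are this package's own frozen choices, so printed-value
  comparisons are order-of-magnitude reproductions, not digit-for-digit
  ones.  ΔR in particular is highly sensitive to λ (it compresses as
  outbreaks saturate) and to the network realization at small budgets.
- LT results at low budgets depend strongly on the threshold value; with
  ξ = 0.5 cascades barely leave the seed set at f_o ≤ 0.05 on strong
  communities, and hub-rich selections (CBC, CHB) edge out the
  map-equation centrality there.
- Louvain is single-objective (modularity) and inherits its resolution
  limit; Infomap is two-level only, by design.
- The IC per-edge probability path materializes per-entry draws and is
  noticeably slower than the scalar closure; use scalars when
  probabilities are uniform.
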