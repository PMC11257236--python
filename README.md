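# commdiff

Community-aware centrality measures as seed-selection strategies for
diffusion dynamics on networks.

When information or infection spreads over a network with community
structure, the best nodes to seed depend on three things: how strong the
community structure is, how large the seeding budget is, and which
contagion mechanism is at work.  *Community-aware* centrality measures
score each node from its intra-community links (local, hub-like influence)
and its inter-community links (global, bridge-like influence), and
different measures weigh the two differently.  `commdiff` is a tested
pipeline for studying that interplay: it generates LFR benchmark networks
with planted communities, detects communities with Louvain or Infomap,
scores nodes with eight community-aware measures plus the degree baseline,
runs four diffusion models, and evaluates each measure under a budget
sweep.  It is aimed at network epidemiologists and computational social
scientists who need reproducible seed-selection experiments.

## What it computes

**Measures** (all map a graph and a partition to one score per node,
higher = more influential):

| id | measure | formula sketch |
|----|---------|----------------|
| `deg` | degree baseline | k_i |
| `pc` | participation coefficient | 1 − Σ_c (k_{i,c}/k_i)² |
| `cbc` | community-based centrality | Σ_c k_{i,c}·n_c/N |
| `comm` | Comm centrality | community-normalized intra/inter degrees, reweighted by the community's own mixing |
| `ks` | k-shell with community | δ·ks_intra + (1−δ)·ks_inter |
| `cbm` | community-based mediator | entropy of the intra/inter split × k_i/2M |
| `chb` | community hub-bridge | n_c·k_intra + NNC·k_inter |
| `mv+`, `mv-`, `mvabs` | modularity vitality | Q(G) − Q(G∖i), ranked for hubs / bridges / both |
| `mapeq` | map-equation centrality | two-level codelength change on node removal |

**Models**: SI, SIR (simple epidemic contagion), independent cascade (IC,
one activation attempt per edge) and linear threshold (LT, complex
contagion: a node activates when a fraction ξ of its neighbors is active).
All run as synchronous discrete-time Monte-Carlo simulations.

**Evaluation**: seed the top fraction f_o of a measure's ranking
(f_o ∈ [1%, 50%]), run the model to its stable state, and score with T50
(SI iterations to infect half the network), ΔR / ΔA (final SIR outbreak /
IC activation relative to degree-baseline seeding), or Ar (LT activation
rate).

## Worked example

```python
from commdiff import (LFRParams, generate_lfr, empirical_mixing,
                      modularity, budget_sweep, SweepConfig)

graph, planted = generate_lfr(LFRParams(N=1000, mu=0.05, seed=1))
print(f"N={graph.N}  M={graph.M}  communities={planted.C}  "
      f"mixing={empirical_mixing(graph, planted):.3f}  Q={modularity(graph, planted):.3f}")

results = budget_sweep(
    graph, planted,
    measures=["deg", "comm", "pc", "mapeq"],
    models=["sir", "lt"],
    budgets=[0.05],
    cfg=SweepConfig(reps=20, seed=7),
)
sir = results[results.metric == "DeltaR"].set_index("measure")["mean"]
lt = results[results.metric == "Ar"].set_index("measure")["mean"]
for m in ("deg", "comm", "pc", "mapeq"):
    print(f"{m:>6}:  DeltaR = {100 * sir[m]:+6.1f}%   Ar = {lt[m]:.3f}")
```

prints

```
N=1000  M=4792  communities=42  mixing=0.049  Q=0.904
   deg:  DeltaR =   +0.0%   Ar = 0.339
  comm:  DeltaR =  +38.9%   Ar = 0.085
    pc:  DeltaR =  +17.3%   Ar = 0.050
 mapeq:  DeltaR =   -2.4%   Ar = 0.226
```

The LFR realization hits its target mixing (0.049 vs. 0.05) and has the
high modularity of a strong community structure.  Under SIR at a 5%
budget, bridge-oriented measures shine: Comm centrality's seeds produce a
39% larger outbreak than degree seeding, the participation coefficient
17%.  Under the complex-contagion LT model the ordering flips — the
bridge-heavy Comm seeds barely spread (Ar = 0.085) while the hub-oriented
map-equation centrality reaches more than a fifth of the network —
illustrating the central finding that simple and complex contagions reward
different kinds of seeds.

The same pipeline is scriptable from the shell:

```
commdiff generate-lfr --n 1000 --mu 0.05 --seed 1 --out-edges net.edges --out-partition net.part
commdiff detect --method infomap --in-edges net.edges --out-partition infomap.part
commdiff score --measure comm --in-edges net.edges --in-partition infomap.part --out scores.csv
commdiff sweep --config config.yaml --out results.csv
commdiff report --in results.csv --out summary.md
```

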