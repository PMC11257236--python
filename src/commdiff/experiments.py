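"""The synthetic-network study protocol: frozen conditions and experiments.

This module pins the conditions under which the package's headline
synthetic-network results are computed, and provides the experiment
drivers built on :func:`commdiff.evaluation.budget_sweep`.

Study conditions
----------------
Networks are LFR benchmarks at desk scale: N = 1000 nodes, mean degree 10,
maximum degree 50, community sizes in [10, 100], mixing mu = 0.05 (strong
community structure) unless swept.  One sweep varies the community-size
exponent theta over {2, 2.7, 3} with gamma fixed at 2.7; the other varies
the degree exponent gamma over {2, 2.7, 3} with theta fixed at 2.7, so the
two sweeps share their middle condition.

Diffusion rates: the SI experiments count iterations to infect half the
network and therefore run barely above threshold, with the canonical small
per-contact rate lambda = 0.01; SIR and IC use the per-network rate
lambda = p = 1.5 x lambda_c (above the mean-field epidemic threshold, so
outbreaks are visible but not saturating) with full recovery psi = 1; LT
uses the uniform fractional threshold xi = 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lfr import LFRParams, generate_lfr
from .evaluation import SweepConfig, budget_sweep

__all__ = [
    "SI_LAMBDA",
    "THETA_VALUES",
    "GAMMA_VALUES",
    "FIXED_EXPONENT",
    "MEASURE_FAMILY",
    "COMMUNITY_MEASURES",
    "make_network",
    "si_iterations",
    "sir_relative_outbreak",
    "ic_max_activation",
    "family_means",
]

#: per-contact infection rate for the SI iteration-count experiments
SI_LAMBDA = 0.01
#: community-size exponent sweep (degree exponent held at FIXED_EXPONENT)
THETA_VALUES = (2.0, 2.7, 3.0)
#: degree exponent sweep (community-size exponent held at FIXED_EXPONENT)
GAMMA_VALUES = (2.0, 2.7, 3.0)
FIXED_EXPONENT = 2.7

#: the ten rankings grouped into the eight measure families
MEASURE_FAMILY = {
    "pc": "PC",
    "cbc": "CBC",
    "comm": "Comm",
    "ks": "ks",
    "cbm": "CBM",
    "chb": "CHB",
    "mv+": "MV",
    "mv-": "MV",
    "mvabs": "MV",
    "mapeq": "MapEq",
}
COMMUNITY_MEASURES = tuple(MEASURE_FAMILY)


def make_network(axis: str, value: float, seed: int, mu: float = 0.05):
    """LFR network for one sweep condition ('theta' or 'gamma' axis)."""
    if axis == "theta":
        params = LFRParams(gamma=FIXED_EXPONENT, theta=value, mu=mu, seed=seed)
    elif axis == "gamma":
        params = LFRParams(gamma=value, theta=FIXED_EXPONENT, mu=mu, seed=seed)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return generate_lfr(params)


def si_iterations(
    axis: str,
    value: float,
    f_o: float,
    net_seeds=(11, 12, 13),
    reps: int = 20,
    measure: str = "comm",
    master_seed: int = 5,
) -> tuple[float, float]:
    """Mean SI iterations to 50% infection for one sweep condition.

    Returns (mean over network realizations, standard error across them).
    """
    vals = []
    for seed in net_seeds:
        graph, partition = make_network(axis, value, seed)
        df = budget_sweep(
            graph, partition, [measure], ["si"], [f_o],
            SweepConfig(reps=reps, seed=master_seed + seed, lambda_=SI_LAMBDA),
        )
        vals.append(float(df[df.metric == "T50"]["mean"].iloc[0]))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def sir_relative_outbreak(
    axis: str,
    value: float,
    f_o: float,
    net_seeds=(11, 12, 13),
    reps: int = 20,
    measure: str = "comm",
    master_seed: int = 5,
) -> tuple[float, float]:
    """Mean DeltaR (in percent) of a measure against the degree baseline."""
    vals = []
    for seed in net_seeds:
        graph, partition = make_network(axis, value, seed)
        df = budget_sweep(
            graph, partition, [measure], ["sir"], [f_o],
            SweepConfig(reps=reps, seed=master_seed + seed),
        )
        sub = df[(df.metric == "DeltaR") & (df.measure == measure)]
        vals.append(100.0 * float(sub["mean"].iloc[0]))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


#: budget grid used when scanning for the peak IC relative activation
IC_BUDGET_GRID = (0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)


def ic_max_activation(
    axis: str,
    value: float,
    net_seeds=(11, 12, 13),
    reps: int = 15,
    master_seed: int = 5,
) -> tuple[float, float]:
    """Peak DeltaA (percent) over measures and the budget grid under IC."""
    vals = []
    for seed in net_seeds:
        graph, partition = make_network(axis, value, seed)
        df = budget_sweep(
            graph, partition, list(COMMUNITY_MEASURES), ["ic"],
            list(IC_BUDGET_GRID),
            SweepConfig(reps=reps, seed=master_seed + seed),
        )
        sub = df[(df.metric == "DeltaA") & (df.status == "ok")]
        vals.append(100.0 * float(sub["mean"].max()))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def family_means(df: pd.DataFrame, metric: str) -> pd.Series:
    """Collapse a sweep result to measure families (best variant per
    family), averaging the metric over whatever rows are present."""
    sub = df[(df.metric == metric) & (df.status == "ok")]
    per_measure = sub.groupby("measure")["mean"].mean()
    return per_measure.groupby(MEASURE_FAMILY.__getitem__).max()
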