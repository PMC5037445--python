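"""Temporal-knockout (TKO) scores.

TKO measures each agent-time node's influence on disease spread by a
two-level contingency analysis.  Level one: run the epidemic once with each
agent as the sole initially infected agent.  Level two: for every node
(agent, time) that is infectious in that run, remove it — the agent
disappears from the system from that time onward — rerun the *same*
dynamics on the same skeleton, and record the change in magnitude.  A
node's TKO score is the average of its marginal effect across all n
single-seed runs, duds included.

Two normalisations of the marginal effect M0 - Mko are computed:

* proportional: ``1 - Mko / M0`` — 1 means the removal stops the entire
  infection of that run, negative means removal *increased* spread;
* delta fraction: ``(M0 - Mko) / (n * (T + 1))`` — the change in the
  infected fraction of all temporal-web nodes.

Knockouts are evaluated only at the infectious nodes of a run and copied
to the other times of the same agent, which is exact: removing an agent at
a time when it is not infectious has the same effect as removing it at its
next infectious time (it neither transmits nor changes anyone else's state
in between), and zero effect if it is never infectious again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epidemic import I, propagate_batch
from .temporal_web import TemporalSkeleton, node_count

__all__ = [
    "NodeTKO",
    "AgentTKO",
    "marginal_scores",
    "tko_scores",
    "aggregate_agents",
    "count_seed_combinations",
    "node_tko_to_frame",
]


@dataclass
class NodeTKO:
    """Per-(agent, time) knockout scores.

    Each field is an ``(n_agents, T+1)`` array: ``proportional`` and
    ``delta_fraction`` as defined above, and ``marginal`` — the raw change
    in magnitude, in agent-times.  For a single run these are the run's
    contributions; after averaging they are the TKO scores proper.
    """

    proportional: np.ndarray
    delta_fraction: np.ndarray
    marginal: np.ndarray
    n_runs: int = 1


@dataclass
class AgentTKO:
    """Per-agent aggregates of node TKO scores: max and mean over time of
    each variant.  Held as a DataFrame with columns max_prop, max_delta,
    mean_prop, mean_delta indexed by agent."""

    table: pd.DataFrame

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def marginal_scores(skeleton: TemporalSkeleton, seed_agent: int) -> NodeTKO:
    """Marginal infection scores of every temporal-web node for the run
    seeded at ``seed_agent``.

    The knockouts at all infectious nodes of the base run are simulated in
    one batch; non-infectious times are filled from the agent's next
    infectious time (zero if none), and never-infected agents score zero
    everywhere.
    """
    n = skeleton.n_agents
    T = skeleton.horizon
    N = node_count(skeleton)

    init = np.zeros((1, n), dtype=bool)
    init[0, seed_agent] = True
    m0_arr, _, states = propagate_batch(skeleton, init, record_states=True)
    m0 = int(m0_arr[0])
    infected = states[0] == I  # (n, T+1)

    prop = np.zeros((n, T + 1), dtype=np.float64)
    delta = np.zeros((n, T + 1), dtype=np.float64)
    raw = np.zeros((n, T + 1), dtype=np.float64)

    ko_agents, ko_times = np.nonzero(infected)
    if len(ko_agents):
        K = len(ko_agents)
        init_b = np.zeros((K, n), dtype=bool)
        init_b[:, seed_agent] = True
        mko, _, _ = propagate_batch(skeleton, init_b, ko_agents, ko_times)
        change = m0 - mko.astype(np.float64)
        raw[ko_agents, ko_times] = change
        # proportional score guards the (practically unreachable) M0 = 0
        prop[ko_agents, ko_times] = 0.0 if m0 == 0 else change / m0
        delta[ko_agents, ko_times] = change / N

        # backward fill: a non-infectious node inherits the score of the
        # agent's next infectious time; nothing after the last one
        carry_p = np.zeros(n)
        carry_d = np.zeros(n)
        carry_r = np.zeros(n)
        has = np.zeros(n, dtype=bool)
        for t in range(T, -1, -1):
            col = infected[:, t]
            carry_p[col] = prop[col, t]
            carry_d[col] = delta[col, t]
            carry_r[col] = raw[col, t]
            has |= col
            fill = ~col & has
            if fill.any():
                prop[fill, t] = carry_p[fill]
                delta[fill, t] = carry_d[fill]
                raw[fill, t] = carry_r[fill]
    return NodeTKO(proportional=prop, delta_fraction=delta, marginal=raw, n_runs=1)


def tko_scores(skeleton: TemporalSkeleton) -> NodeTKO:
    """TKO scores of every temporal-web node: the arithmetic mean of the
    per-run marginal scores over all n single-seed runs (duds included)."""
    n = skeleton.n_agents
    T = skeleton.horizon
    prop = np.zeros((n, T + 1))
    delta = np.zeros((n, T + 1))
    raw = np.zeros((n, T + 1))
    for seed_agent in range(n):
        contrib = marginal_scores(skeleton, seed_agent)
        prop += contrib.proportional
        delta += contrib.delta_fraction
        raw += contrib.marginal
    return NodeTKO(
        proportional=prop / n,
        delta_fraction=delta / n,
        marginal=raw / n,
        n_runs=n,
    )


def aggregate_agents(node_tko: NodeTKO) -> AgentTKO:
    """Aggregate node scores to agents: the maximum and the mean over time
    0..T of each score variant."""
    table = pd.DataFrame(
        {
            "max_prop": node_tko.proportional.max(axis=1),
            "max_delta": node_tko.delta_fraction.max(axis=1),
            "mean_prop": node_tko.proportional.mean(axis=1),
            "mean_delta": node_tko.delta_fraction.mean(axis=1),
        },
        index=pd.RangeIndex(node_tko.proportional.shape[0], name="agent"),
    )
    return AgentTKO(table=table)


def count_seed_combinations(n: int, r: int) -> int:
    """Number of runs needed to exhaust all r-agent initial conditions on
    n agents: the binomial coefficient C(n, r).

    With one initial agent a network needs n runs; already for three it is
    C(200, 3) = 1,313,400 — the combinatorial wall that makes post-hoc
    combinability of single-seed TKO scores attractive.
    """
    if r < 0 or n < 0:
        raise ValueError("n and r must be nonnegative")
    if r > n:
        raise ValueError(f"r={r} exceeds n={n}")
    return math.comb(n, r)


def plot_scores_over_time(node_tko: NodeTKO, agents=None, score: str = "marginal",
                          ax=None):
    """Plot agents' knockout scores across time (one line per agent).

    ``score`` selects the array: ``marginal`` (raw agent-times saved, the
    natural unit for eyeballing bottleneck agent-times), ``proportional``
    or ``delta_fraction``.  Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    arr = getattr(node_tko, score)
    if agents is None:
        # the five agents with the largest peak effect
        agents = np.argsort(arr.max(axis=1))[::-1][:5]
    if ax is None:
        _, ax = plt.subplots()
    for a in agents:
        ax.plot(arr[a], label=f"agent {a}")
    ax.set_xlabel("iteration")
    ax.set_ylabel(f"{score} TKO score")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize="small")
    return ax


def node_tko_to_frame(node_tko: NodeTKO) -> pd.DataFrame:
    """Long-form dump: one row per (agent, time) with both score variants."""
    n, tp1 = node_tko.proportional.shape
    agents, times = np.meshgrid(np.arange(n), np.arange(tp1), indexing="ij")
    return pd.DataFrame(
        {
            "agent": agents.ravel(),
            "time": times.ravel(),
            "proportional": node_tko.proportional.ravel(),
            "delta_fraction": node_tko.delta_fraction.ravel(),
            "marginal": node_tko.marginal.ravel(),
        }
    )
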