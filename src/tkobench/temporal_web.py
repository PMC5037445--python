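"""Temporal-web skeletons: all randomness of an outbreak pre-sampled.

A *temporal web* views an agent-based epidemic as one acyclic digraph across
time: each (agent, time) pair is a node, interaction edges run from agents at
``t`` to other agents at ``t+1``, and inheritance edges connect each agent to
its next-period self.  The *skeleton* fixes every stochastic draw up front —
which contacts activate at each iteration, the uniform draw deciding whether
each contact would transmit, and the uniform draw deciding whether an
infectious agent recovers.  Propagation over a skeleton is then a pure
function of the initial condition (and of an optional knockout), which is
exactly what knockout contingency analysis requires: rerunning "the same
infection dynamics" with one node removed.

Contact model
-------------
At every iteration each agent ``i`` activates the link to neighbour ``j``
independently with probability ``k_j / sum_{m in K_i} k_m`` (``k_j`` the
degree of ``j``, ``K_i`` the neighbour set of ``i``): contacts are biased
toward well-connected neighbours, and each agent initiates one contact per
iteration in expectation.  A variant where each agent draws *exactly* one
neighbour per iteration from the same distribution is available as
``contact_mode="single"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "TemporalSkeleton",
    "activation_probability",
    "build_skeleton",
    "node_count",
    "skeleton_to_frames",
    "skeleton_from_frames",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Disease and simulation parameters for one scenario.

    Parameters
    ----------
    model:
        ``"SIR"`` (recovered agents are immune) or ``"SIS"`` (recovered
        agents return to susceptible).
    infection_prob:
        Per-contact transmission probability beta.
    recovery_prob:
        Per-iteration probability that an infectious agent leaves the
        infectious state; the default 1/15 gives a mean infectious period
        of 15 iterations.
    horizon:
        Number of iterations T; states exist at times 0..T.
    dud_threshold:
        Runs with magnitude below this many agent-times count as duds;
        the epidemic flag is magnitude > threshold.
    contact_mode:
        ``"independent"`` (each link activates independently, default) or
        ``"single"`` (exactly one outgoing contact per agent per iteration).
    bidirectional_transmission:
        If True a single activation event could carry infection in either
        direction.  Kept for completeness; default (False) requires each
        direction to have its own event.
    """

    model: str = "SIR"
    infection_prob: float = 0.10
    recovery_prob: float = 1.0 / 15.0
    horizon: int = 200
    dud_threshold: int = 50
    contact_mode: str = "independent"
    bidirectional_transmission: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("SIR", "SIS"):
            raise ValueError(f"model must be 'SIR' or 'SIS', got {self.model!r}")
        if not (0.0 < self.infection_prob <= 1.0):
            raise ValueError(f"infection_prob out of (0, 1]: {self.infection_prob}")
        if not (0.0 < self.recovery_prob <= 1.0):
            raise ValueError(f"recovery_prob out of (0, 1]: {self.recovery_prob}")
        if self.horizon < 0:
            raise ValueError(f"horizon must be >= 0, got {self.horizon}")
        if self.contact_mode not in ("independent", "single"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


def activation_probability(graph: nx.Graph, i: int, j: int) -> float:
    """Probability that agent ``i`` activates its link to neighbour ``j``.

    Degree-biased: ``k_j / sum_{m in K_i} k_m``.  Summed over the neighbours
    of ``i`` this is exactly 1, so each agent initiates one contact per
    iteration in expectation.
    """
    if not graph.has_edge(i, j):
        raise ValueError(f"({i}, {j}) is not an edge of the base graph")
    denom = sum(graph.degree(m) for m in graph[i])
    return graph.degree(j) / denom


@dataclass
class TemporalSkeleton:
    """All pre-sampled randomness for one scenario on one base graph.

    Activation events are stored as parallel flat arrays sorted by time,
    with ``time_ptr`` giving the CSR-style slice of events at each
    iteration ``t`` (events at ``t`` affect states at ``t+1``).  Recovery
    draws are an ``(n_agents, T)`` array of uniforms.
    """

    graph: nx.Graph
    config: ScenarioConfig
    seed: int
    act_t: np.ndarray  # (n_events,) int32, sorted ascending
    act_src: np.ndarray  # (n_events,) int32
    act_dst: np.ndarray  # (n_events,) int32
    act_u: np.ndarray  # (n_events,) float64 transmission draw in [0, 1)
    recovery: np.ndarray  # (n_agents, T) float64 uniforms
    time_ptr: np.ndarray = field(default=None, repr=False)  # (T+1,) int64
    _trans_by_t: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.time_ptr is None:
            self.time_ptr = np.searchsorted(
                self.act_t, np.arange(self.horizon + 1)
            ).astype(np.int64)

    # -- basic shape -------------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def horizon(self) -> int:
        return self.config.horizon

    def n_events(self) -> int:
        return len(self.act_t)

    def events_at(self, t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, u) arrays of activation events at iteration ``t``."""
        lo, hi = self.time_ptr[t], self.time_ptr[t + 1]
        return self.act_src[lo:hi], self.act_dst[lo:hi], self.act_u[lo:hi]

    def transmitting_events(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-iteration (src, dst) arrays of events whose transmission draw
        falls below beta — the only events that can carry infection."""
        if self._trans_by_t is None:
            beta = self.config.infection_prob
            ok = self.act_u < beta
            out = []
            for t in range(self.horizon):
                lo, hi = self.time_ptr[t], self.time_ptr[t + 1]
                m = ok[lo:hi]
                out.append(
                    (
                        np.ascontiguousarray(self.act_src[lo:hi][m]),
                        np.ascontiguousarray(self.act_dst[lo:hi][m]),
                    )
                )
            self._trans_by_t = out
        return self._trans_by_t

    def recovery_fires(self) -> np.ndarray:
        """(n_agents, T) bool: does the recovery draw fire at (agent, t)?"""
        return self.recovery < self.config.recovery_prob

    def with_model(self, model: str) -> "TemporalSkeleton":
        """Same skeleton (shared draw arrays) under SIR or SIS dynamics.

        SIR and SIS versions of a scenario deliberately share one skeleton
        so that both use the same link activations at each time step.
        """
        if model == self.config.model:
            return self
        cfg = dataclasses.replace(self.config, model=model)
        return TemporalSkeleton(
            graph=self.graph,
            config=cfg,
            seed=self.seed,
            act_t=self.act_t,
            act_src=self.act_src,
            act_dst=self.act_dst,
            act_u=self.act_u,
            recovery=self.recovery,
            time_ptr=self.time_ptr,
        )

    # -- fixture constructor ----------------------------------------------
    @classmethod
    def from_events(
        cls,
        graph: nx.Graph,
        config: ScenarioConfig,
        events: Iterable[tuple[int, int, int, float]],
        recoveries: Mapping[tuple[int, int], float] | None = None,
        seed: int = 0,
    ) -> "TemporalSkeleton":
        """Build a skeleton from an explicit event list (for fixtures/audit).

        ``events`` is an iterable of ``(t, i, j, u)``; ``recoveries`` maps
        ``(agent, t)`` to a draw, all unspecified draws default to 1.0
        (never fire).
        """
        n = graph.number_of_nodes()
        T = config.horizon
        ev = sorted(events, key=lambda e: (e[0], e[1], e[2]))
        seen: set[tuple[int, int, int]] = set()
        for t, i, j, u in ev:
            if not (0 <= t < T):
                raise ValueError(f"event time {t} outside [0, {T})")
            if not graph.has_edge(i, j):
                raise ValueError(f"event ({i}->{j}) is not a base-graph edge")
            if (t, i, j) in seen:
                raise ValueError(f"duplicate event ({i}->{j}) at t={t}")
            seen.add((t, i, j))
        rec = np.ones((n, T), dtype=np.float64)
        for (agent, t), r in (recoveries or {}).items():
            rec[agent, t] = r
        return cls(
            graph=graph,
            config=config,
            seed=seed,
            act_t=np.array([e[0] for e in ev], dtype=np.int32),
            act_src=np.array([e[1] for e in ev], dtype=np.int32),
            act_dst=np.array([e[2] for e in ev], dtype=np.int32),
            act_u=np.array([e[3] for e in ev], dtype=np.float64),
            recovery=rec,
        )


def build_skeleton(
    graph: nx.Graph, config: ScenarioConfig, seed: int
) -> TemporalSkeleton:
    """Sample a full temporal-web skeleton.

    For every iteration ``t < T`` and every ordered neighbour pair ``(i, j)``
    an activation event is created independently with probability
    ``activation_probability(graph, i, j)`` and carries a fresh uniform
    transmission draw; a recovery draw is sampled for every ``(agent, t)``.

    The sampling depends only on the graph, the horizon, the contact mode
    and the seed — not on ``model``, ``infection_prob`` or
    ``recovery_prob`` — so SIR/SIS (and different-beta) configs that share
    these inputs share identical draws.
    """
    n = graph.number_of_nodes()
    T = config.horizon
    rng = np.random.default_rng(seed)

    degrees = np.array([graph.degree(v) for v in range(n)], dtype=np.float64)
    # ordered pairs sorted by (source, target) for a canonical draw order
    src_list: list[int] = []
    dst_list: list[int] = []
    for i in range(n):
        for j in sorted(graph[i]):
            src_list.append(i)
            dst_list.append(j)
    src = np.array(src_list, dtype=np.int32)
    dst = np.array(dst_list, dtype=np.int32)

    if config.contact_mode == "independent":
        neigh_deg_sum = np.zeros(n, dtype=np.float64)
        np.add.at(neigh_deg_sum, src, degrees[dst])
        p_act = degrees[dst] / neigh_deg_sum[src]
        occur = rng.random((T, len(src))) < p_act[None, :]
        udraw = rng.random((T, len(src)))
        t_idx, pair_idx = np.nonzero(occur)  # row-major: sorted by t
        act_t = t_idx.astype(np.int32)
        act_src = src[pair_idx]
        act_dst = dst[pair_idx]
        act_u = udraw[t_idx, pair_idx]
    else:  # "single": exactly one outgoing contact per agent per iteration
        act_t_l, act_src_l, act_dst_l = [], [], []
        # per-agent cumulative neighbour distribution
        cum: list[np.ndarray] = []
        targets: list[np.ndarray] = []
        for i in range(n):
            nb = np.array(sorted(graph[i]), dtype=np.int32)
            w = degrees[nb]
            cum.append(np.cumsum(w / w.sum()))
            targets.append(nb)
        pick = rng.random((T, n))
        udraw = rng.random((T, n))
        for t in range(T):
            for i in range(n):
                j = targets[i][np.searchsorted(cum[i], pick[t, i], side="right")
                               .clip(0, len(targets[i]) - 1)]
                act_t_l.append(t)
                act_src_l.append(i)
                act_dst_l.append(int(j))
        act_t = np.array(act_t_l, dtype=np.int32)
        act_src = np.array(act_src_l, dtype=np.int32)
        act_dst = np.array(act_dst_l, dtype=np.int32)
        act_u = udraw.reshape(-1)

    recovery = rng.random((n, T))
    return TemporalSkeleton(
        graph=graph,
        config=config,
        seed=seed,
        act_t=act_t,
        act_src=act_src,
        act_dst=act_dst,
        act_u=act_u,
        recovery=recovery,
    )


def node_count(skeleton: TemporalSkeleton) -> int:
    """Number of agent-time nodes in the temporal web: n * (T + 1).

    This is the denominator of the delta-fraction knockout score.
    """
    return skeleton.n_agents * (skeleton.horizon + 1)


# ---------------------------------------------------------------------------
# Columnar serialization for audit and fixture construction
# ---------------------------------------------------------------------------

def skeleton_to_frames(skel: TemporalSkeleton) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dump a skeleton as (activations, recoveries) DataFrames.

    Activations: columns t, i, j, u.  Recoveries: columns t, agent, r.
    """
    act = pd.DataFrame(
        {"t": skel.act_t, "i": skel.act_src, "j": skel.act_dst, "u": skel.act_u}
    )
    agents, times = np.meshgrid(
        np.arange(skel.n_agents), np.arange(skel.horizon), indexing="ij"
    )
    rec = pd.DataFrame(
        {"t": times.ravel(), "agent": agents.ravel(), "r": skel.recovery.ravel()}
    )
    return act, rec


def skeleton_from_frames(
    graph: nx.Graph,
    config: ScenarioConfig,
    activations: pd.DataFrame,
    recoveries: pd.DataFrame,
    seed: int = 0,
) -> TemporalSkeleton:
    """Rebuild a skeleton from its columnar dump (inverse of
    :func:`skeleton_to_frames`)."""
    events = list(
        zip(activations["t"], activations["i"], activations["j"], activations["u"])
    )
    rec = {
        (int(a), int(t)): float(r)
        for t, a, r in zip(recoveries["t"], recoveries["agent"], recoveries["r"])
    }
    return TemporalSkeleton.from_events(graph, config, events, rec, seed=seed)
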