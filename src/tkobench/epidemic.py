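"""Deterministic SIR/SIS propagation over a temporal-web skeleton.

Because every stochastic draw lives in the skeleton, a run is a pure
function of (skeleton, initial infected set, optional knockout).  Updating
is simultaneous: an agent's state at ``t+1`` depends only on states at
``t`` and the activation events of iteration ``t``:

* an agent infectious at ``t`` transmits along each of its activation
  events ``(t, i, j, u)`` with ``u < beta`` to ``j``, provided ``j`` is
  susceptible at ``t`` and not removed at ``t+1``;
* an agent infectious at ``t`` whose recovery draw fires becomes R (SIR)
  or S (SIS) at ``t+1``, so the minimum infectious duration is one period
  and transmission and recovery can co-occur in a step;
* a knockout ``(agent, tau)`` deletes the agent from all states and
  interactions at ``t >= tau``.

Transmission is directional: the activating side carries infection to the
target, and the reverse direction needs its own event (unless the config
opts into ``bidirectional_transmission``).

The module-level functions :func:`run`, :func:`magnitude`,
:func:`cumulative_cases` and :func:`is_epidemic` are the public surface;
``propagate_batch`` is the vectorised core shared with the knockout scorer,
which simulates many initial-condition/knockout variants of one skeleton in
lockstep.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .temporal_web import TemporalSkeleton

__all__ = [
    "S", "I", "R", "REMOVED",
    "STATE_NAMES",
    "Knockout",
    "PropagationRecord",
    "run",
    "run_all_seeds",
    "propagate_batch",
    "magnitude",
    "cumulative_cases",
    "is_epidemic",
    "record_to_frame",
    "record_summary",
]

# state codes in the (agent, time) matrix
S, I, R, REMOVED = 0, 1, 2, 3
STATE_NAMES = {S: "S", I: "I", R: "R", REMOVED: "removed"}


@dataclass(frozen=True)
class Knockout:
    """Removal of ``agent`` from the system at all times >= ``time``."""

    agent: int
    time: int


@dataclass
class PropagationRecord:
    """Full outcome of one run: the (agent, 0..T) state matrix plus the
    magnitude family of summary statistics."""

    states: np.ndarray  # (n_agents, T+1) int8
    magnitude: int  # number of infectious agent-time nodes
    cumulative_cases: int  # number of agents ever infectious
    epidemic: bool  # magnitude > dud threshold
    seed_agents: tuple[int, ...]
    knockout: Knockout | None
    model: str
    dud_threshold: int


def propagate_batch(
    skeleton: TemporalSkeleton,
    init: np.ndarray,
    ko_agent: np.ndarray | None = None,
    ko_time: np.ndarray | None = None,
    record_states: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Run ``K`` propagation variants of one skeleton in lockstep.

    Parameters
    ----------
    init:
        (K, n) boolean matrix of initially infected agents per variant.
    ko_agent, ko_time:
        Optional (K,) arrays; variant ``k`` removes ``ko_agent[k]`` from
        time ``ko_time[k]`` onward (``ko_agent[k] = -1`` for no knockout).
    record_states:
        If True, also return the (K, n, T+1) int8 state tensor.

    Returns
    -------
    magnitudes (K,), cumulative case counts (K,), and the state tensor
    (or None).
    """
    n = skeleton.n_agents
    T = skeleton.horizon
    cfg = skeleton.config
    K = init.shape[0]
    if init.shape != (K, n):
        raise ValueError(f"init must be (K, {n}), got {init.shape}")
    if not init.any(axis=1).all():
        raise ValueError("every variant needs a nonempty initial infected set")

    cur = np.zeros((K, n), dtype=np.int8)
    cur[init] = I
    if ko_agent is None:
        ko_agent = np.full(K, -1, dtype=np.int64)
        ko_time = np.zeros(K, dtype=np.int64)
    else:
        ko_agent = np.asarray(ko_agent, dtype=np.int64)
        ko_time = np.asarray(ko_time, dtype=np.int64)

    trans = skeleton.transmitting_events()
    rec_fires = skeleton.recovery_fires()  # (n, T) bool
    to_state = R if cfg.model == "SIR" else S
    bidir = cfg.bidirectional_transmission

    mag = np.zeros(K, dtype=np.int64)
    ever = np.zeros((K, n), dtype=bool)
    states = np.empty((K, n, T + 1), dtype=np.int8) if record_states else None
    rows = np.arange(K)

    for t in range(T + 1):
        hit_now = ko_agent >= 0
        hit_now &= ko_time == t
        if hit_now.any():
            cur[rows[hit_now], ko_agent[hit_now]] = REMOVED
        inf = cur == I
        mag += inf.sum(axis=1)
        ever |= inf
        if record_states:
            states[:, :, t] = cur
        if t == T:
            break

        esrc, edst = trans[t]
        nxt = cur.copy()
        if len(esrc):
            # few events per iteration (~n*beta), so loop events and
            # vectorise over the K variants
            pressed = np.zeros((K, n), dtype=bool)
            for s_, d_ in zip(esrc.tolist(), edst.tolist()):
                pressed[:, d_] |= inf[:, s_]
                if bidir:
                    pressed[:, s_] |= inf[:, d_]
            new_inf = pressed & (cur == S)
            nxt[new_inf] = I
        recovering = inf & rec_fires[:, t][None, :]
        nxt[recovering] = to_state
        cur = nxt

    return mag, ever.sum(axis=1), states


def run(
    skeleton: TemporalSkeleton,
    initial_agents: Iterable[int],
    knockout: Knockout | None = None,
) -> PropagationRecord:
    """Propagate the disease once and return the full record."""
    n = skeleton.n_agents
    seeds = tuple(sorted(set(int(a) for a in initial_agents)))
    if not seeds:
        raise ValueError("initial infected set must be nonempty")
    if any(a < 0 or a >= n for a in seeds):
        raise ValueError(f"initial agents must be in 0..{n - 1}: {seeds}")
    if knockout is not None and not (0 <= knockout.time <= skeleton.horizon):
        raise ValueError(f"knockout time outside 0..{skeleton.horizon}")

    init = np.zeros((1, n), dtype=bool)
    init[0, list(seeds)] = True
    ko_agent = ko_time = None
    if knockout is not None:
        ko_agent = np.array([knockout.agent])
        ko_time = np.array([knockout.time])
    mag, cum, states = propagate_batch(
        skeleton, init, ko_agent, ko_time, record_states=True
    )
    return PropagationRecord(
        states=states[0],
        magnitude=int(mag[0]),
        cumulative_cases=int(cum[0]),
        epidemic=int(mag[0]) > skeleton.config.dud_threshold,
        seed_agents=seeds,
        knockout=knockout,
        model=skeleton.config.model,
        dud_threshold=skeleton.config.dud_threshold,
    )


def run_all_seeds(
    skeleton: TemporalSkeleton,
) -> pd.DataFrame:
    """One run per agent as the sole initially infected agent.

    Returns a DataFrame indexed by seed agent with columns ``magnitude``,
    ``cumulative_cases`` and ``epidemic`` — the per-agent outcome grid the
    benchmark tables aggregate.
    """
    n = skeleton.n_agents
    mag, cum, _ = propagate_batch(skeleton, np.eye(n, dtype=bool))
    return pd.DataFrame(
        {
            "magnitude": mag,
            "cumulative_cases": cum,
            "epidemic": mag > skeleton.config.dud_threshold,
        },
        index=pd.RangeIndex(n, name="seed_agent"),
    )


def magnitude(record: PropagationRecord) -> int:
    """Number of infectious agent-time nodes in the temporal web.

    Counted as I cells of the state matrix; identical to the cumulative sum
    of the number of infectious agents across iterations.
    """
    return int((record.states == I).sum())


def cumulative_cases(record: PropagationRecord) -> int:
    """Number of distinct agents that are ever infectious (reinfections under
    SIS count once)."""
    return int((record.states == I).any(axis=1).sum())


def is_epidemic(record: PropagationRecord, threshold: int = 50) -> bool:
    """True when the run's magnitude strictly exceeds ``threshold``; the
    complement is a dud."""
    return record.magnitude > threshold


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def record_to_frame(record: PropagationRecord) -> pd.DataFrame:
    """Long-form (agent, time, state) dump of the state matrix."""
    n, tp1 = record.states.shape
    agents, times = np.meshgrid(np.arange(n), np.arange(tp1), indexing="ij")
    return pd.DataFrame(
        {
            "agent": agents.ravel(),
            "time": times.ravel(),
            "state": [STATE_NAMES[s] for s in record.states.ravel()],
        }
    )


def record_summary(record: PropagationRecord) -> dict:
    """JSON-ready summary of a run."""
    return {
        "model": record.model,
        "seed_agents": list(record.seed_agents),
        "knockout": (
            None
            if record.knockout is None
            else {"agent": record.knockout.agent, "time": record.knockout.time}
        ),
        "magnitude": record.magnitude,
        "cumulative_cases": record.cumulative_cases,
        "epidemic": record.epidemic,
        "dud_threshold": record.dud_threshold,
    }


def write_record(record: PropagationRecord, csv_path: str | os.PathLike,
                 json_path: str | os.PathLike | None = None) -> None:
    record_to_frame(record).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(record_summary(record), fh, indent=2)
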