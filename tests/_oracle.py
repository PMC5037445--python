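"""Independent brute-force reference implementations used as test oracles.

Everything here is written in plain dict/set style, deliberately sharing no
code with the package: a step-by-step state-machine simulator for SIR/SIS
propagation over an explicit event list, a knockout scorer that re-simulates
every (agent, time) removal (including non-infected nodes, with no
backfill shortcut), and an exhaustive two-transmission cluster enumerator
for expected force.
"""

from __future__ import annotations

import math


def oracle_run(graph, config, events, recoveries, initial, knockout=None):
    """Simulate one run; returns (state history dict, magnitude, cases).

    ``events``: iterable of (t, i, j, u); ``recoveries``: dict
    (agent, t) -> draw; ``knockout``: optional (agent, time).
    """
    T = config.horizon
    beta = config.infection_prob
    gamma = config.recovery_prob
    agents = sorted(graph.nodes())
    ev_by_t = {}
    for t, i, j, u in events:
        ev_by_t.setdefault(t, []).append((i, j, u))

    def removed(a, t):
        return knockout is not None and a == knockout[0] and t >= knockout[1]

    state = {a: ("I" if a in initial else "S") for a in agents}
    history = {}
    for t in range(T + 1):
        for a in agents:
            if removed(a, t):
                state[a] = "X"
        history.update({(a, t): state[a] for a in agents})
        if t == T:
            break
        nxt = dict(state)
        for i, j, u in ev_by_t.get(t, ()):
            if state[i] == "I" and u < beta and state[j] == "S":
                nxt[j] = "I"
        for a in agents:
            if state[a] == "I" and recoveries.get((a, t), 1.0) < gamma:
                nxt[a] = "R" if config.model == "SIR" else "S"
        state = nxt
    magnitude = sum(1 for v in history.values() if v == "I")
    cases = len({a for (a, _), v in history.items() if v == "I"})
    return history, magnitude, cases


def oracle_tko(graph, config, events, recoveries):
    """TKO of every (agent, time) node by full re-simulation of every
    (seed, knockout) pair — no infected-subset shortcut, no backfill."""
    T = config.horizon
    agents = sorted(graph.nodes())
    n = len(agents)
    ncount = n * (T + 1)
    prop = {(a, t): 0.0 for a in agents for t in range(T + 1)}
    delta = {(a, t): 0.0 for a in agents for t in range(T + 1)}
    for seed in agents:
        _, m0, _ = oracle_run(graph, config, events, recoveries, {seed})
        for a in agents:
            for t in range(T + 1):
                _, mko, _ = oracle_run(
                    graph, config, events, recoveries, {seed}, knockout=(a, t)
                )
                prop[(a, t)] += (0.0 if m0 == 0 else 1.0 - mko / m0) / n
                delta[(a, t)] += (m0 - mko) / ncount / n
    return prop, delta


def oracle_expected_force(graph, seed):
    """Expected force by explicit enumeration of ordered two-transmission
    sequences: (first edge from seed, then any edge from the infected pair
    to a third node)."""
    entries = []
    for j in graph[seed]:
        for s in (seed, j):
            for l in graph[s]:
                if l in (seed, j):
                    continue
                cluster = {seed, j, l}
                out = sum(
                    1 for v in cluster for u in graph[v] if u not in cluster
                )
                entries.append(out)
    tot = sum(entries)
    if tot == 0:
        return 0.0
    return -sum(
        (d / tot) * math.log(d / tot) for d in entries if d > 0
    )
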