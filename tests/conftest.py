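"""Shared fixtures: the hand-checkable path fixture and a generator of small
random skeletons with explicit event lists (usable by both the package and
the brute-force oracle)."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from tkobench.temporal_web import ScenarioConfig, TemporalSkeleton


@pytest.fixture
def f1():
    """Path A(0)-B(1)-C(2); T=3; activations 0->1 at t0 and 1->2 at t1 with
    transmission draws 0; no recovery; beta=1; SIR.  Seeded at A the run is
    fully infectious: magnitude 9 (A: t0-t3, B: t1-t3, C: t2-t3)."""
    graph = nx.path_graph(3)
    config = ScenarioConfig(model="SIR", infection_prob=1.0, horizon=3)
    events = [(0, 0, 1, 0.0), (1, 1, 2, 0.0)]
    skel = TemporalSkeleton.from_events(graph, config, events)
    return skel, events


def random_small_case(rng, model="SIR"):
    """A random connected graph on 3-5 agents with a random event list and
    recovery draws over <=6 steps; returns (graph, config, events,
    recoveries, skeleton)."""
    n = int(rng.integers(3, 6))
    while True:
        g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    T = int(rng.integers(2, 7))
    beta = float(rng.uniform(0.3, 1.0))
    config = ScenarioConfig(
        model=model, infection_prob=beta, recovery_prob=float(rng.uniform(0.1, 0.9)),
        horizon=T,
    )
    events = []
    for t in range(T):
        for i, j in g.edges():
            for a, b in ((i, j), (j, i)):
                if rng.random() < 0.5:
                    events.append((t, a, b, float(rng.random())))
    recoveries = {
        (a, t): float(rng.random()) for a in range(n) for t in range(T)
    }
    skel = TemporalSkeleton.from_events(g, config, events, recoveries)
    return g, config, events, recoveries, skel


@pytest.fixture
def small_cases():
    """Deterministic battery of small random SIR and SIS cases."""
    rng = np.random.default_rng(20160927)
    cases = [random_small_case(rng, model="SIR") for _ in range(4)]
    cases += [random_small_case(rng, model="SIS") for _ in range(4)]
    return cases
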