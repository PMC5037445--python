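"""Generation and serialization of base potential-interaction networks.

The base network encodes who *could* interact with whom: an undirected,
connected simple graph over ``n`` agents labelled ``0..n-1``.  Two standard
generators are supported — Watts–Strogatz small-world graphs and
Barabási–Albert scale-free graphs — plus plain-text edge-list I/O for
user-supplied networks.  The flattened graph of a simulation (which contacts
actually fired, and how often) also lives here.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .temporal_web import TemporalSkeleton

__all__ = [
    "make_small_world",
    "make_scale_free",
    "flatten_observed",
    "unweighted_view",
    "read_edge_list",
    "write_edge_list",
    "write_flat_graph",
    "read_flat_graph",
]

#: Attempts at drawing a connected Watts–Strogatz graph before giving up.
MAX_CONNECT_TRIES = 100


def _relabel_dense(g: nx.Graph) -> nx.Graph:
    """Force dense integer labels 0..n-1 (sorted by original label)."""
    mapping = {v: i for i, v in enumerate(sorted(g.nodes()))}
    return nx.relabel_nodes(g, mapping)


def make_small_world(n: int, k: int, p_rewire: float, seed: int) -> nx.Graph:
    """Connected Watts–Strogatz graph with ``n`` agents, each wired to ``k``
    ring neighbours, rewired with probability ``p_rewire``.

    Always has exactly ``n*k/2`` edges (rewiring preserves the edge count).
    Disconnected draws are rejected and regenerated with an incremented
    sub-seed so that a given ``seed`` maps to one reproducible graph.
    """
    if k % 2 != 0:
        raise ValueError(f"k must be even, got {k}")
    if not (2 <= k < n):
        raise ValueError(f"need n > k >= 2, got n={n}, k={k}")
    if not (0.0 <= p_rewire <= 1.0):
        raise ValueError(f"p_rewire must be a probability, got {p_rewire}")
    for attempt in range(MAX_CONNECT_TRIES):
        g = nx.watts_strogatz_graph(n, k, p_rewire, seed=seed + attempt)
        if nx.is_connected(g):
            return _relabel_dense(g)
    raise RuntimeError(
        f"no connected Watts-Strogatz draw in {MAX_CONNECT_TRIES} attempts"
    )


def make_scale_free(n: int, m: int, seed: int) -> nx.Graph:
    """Barabási–Albert preferential-attachment graph: ``(n-m)*m`` edges,
    connected by construction."""
    if not (1 <= m < n):
        raise ValueError(f"need 1 <= m < n, got n={n}, m={m}")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return _relabel_dense(g)


def flatten_observed(skeleton: "TemporalSkeleton") -> nx.Graph:
    """Flatten a temporal skeleton into the static graph of observed contacts.

    The weight of the undirected pair ``{i, j}`` is the number of activation
    events ``i->j`` or ``j->i`` across all iterations.  Pairs that never
    activated are absent, so the flat edge set is a subset of the base edges.
    """
    flat = nx.Graph()
    flat.add_nodes_from(range(skeleton.n_agents))
    for i, j in zip(skeleton.act_src.tolist(), skeleton.act_dst.tolist()):
        a, b = (i, j) if i < j else (j, i)
        if flat.has_edge(a, b):
            flat[a][b]["weight"] += 1
        else:
            flat.add_edge(a, b, weight=1)
    return flat


def unweighted_view(flat: nx.Graph) -> nx.Graph:
    """Binary (weight > 0 -> 1) view of a flattened graph."""
    g = nx.Graph()
    g.add_nodes_from(flat.nodes())
    g.add_edges_from(flat.edges())
    return g


# ---------------------------------------------------------------------------
# Plain-text I/O.  Dialect: one "i j" (or "i j weight") pair per line,
# whitespace-separated, undirected, '#' starts a comment.
# ---------------------------------------------------------------------------

def read_edge_list(path: str | os.PathLike) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {raw!r}")
            i, j = int(parts[0]), int(parts[1])
            if i == j:
                raise ValueError(f"self-loop not allowed: {raw!r}")
            g.add_edge(i, j)
    g.add_nodes_from(range(max(g.nodes(), default=-1) + 1))
    return g


def write_edge_list(g: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# undirected edge list, {g.number_of_nodes()} agents\n")
        for i, j in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{i} {j}\n")


def write_flat_graph(flat: nx.Graph, path: str | os.PathLike) -> None:
    """Write "i j weight" triples for a flattened observed-interaction graph."""
    with open(path, "w") as fh:
        fh.write(f"# flattened interactions, {flat.number_of_nodes()} agents\n")
        for i, j in sorted(tuple(sorted(e)) for e in flat.edges()):
            fh.write(f"{i} {j} {flat[i][j].get('weight', 1)}\n")


def read_flat_graph(path: str | os.PathLike) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            i, j, w = line.split()
            g.add_edge(int(i), int(j), weight=int(w))
    g.add_nodes_from(range(max(g.nodes(), default=-1) + 1))
    return g
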