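"""Benchmark harness: outbreak summaries, TKO-vs-magnitude and
TKO-vs-centrality correlation tables, and top-k overlaps.

The experiment grid crosses network family (Watts–Strogatz small-world,
Barabási–Albert scale-free), disease model (SIR, SIS) and per-contact
infection probability (0.10, 0.15, 0.20), with 25 independent base
networks per (family, infection-probability) combination and one run per
agent per network.  SIR and SIS variants of a combination share network
instances and skeletons, so both see the same link activations.

Three report tables mirror the analysis:

* outbreak summary — mean and stdev of magnitude and the dud fraction per
  scenario;
* TKO vs seed-magnitude — per network, the correlation between the
  magnitude of the run seeded at each agent and that agent's aggregated
  TKO scores, averaged over networks (an epidemic-probability twin uses
  the binary epidemic flag instead of magnitude);
* TKO vs centrality — per network, the correlation between mean
  proportional TKO and each flat-graph measure, averaged over networks,
  plus the overlap of the top-ten agent sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import flat_measures, netgen
from .epidemic import run_all_seeds
from .temporal_web import ScenarioConfig, TemporalSkeleton, build_skeleton
from .tko import AgentTKO, aggregate_agents, tko_scores

__all__ = [
    "ExperimentConfig",
    "UndefinedCorrelationError",
    "derive_seed",
    "base_network",
    "scenario_skeleton",
    "run_scenario",
    "summarize_scenario",
    "outbreak_summary_table",
    "correlate",
    "top_k_overlap",
    "network_tko",
    "run_tko_scenario",
    "tko_vs_seed_magnitude",
    "tko_vs_centrality",
    "TKO_VARIANTS",
    "BENCHMARK_MEASURES",
]

logger = logging.getLogger("tkobench")

#: AgentTKO columns in report order.
TKO_VARIANTS = ("max_prop", "max_delta", "mean_prop", "mean_delta")

#: Measures reported by default: the registry minus k-core, whose values
#: are too undifferentiated on these networks to rank agents.
BENCHMARK_MEASURES = tuple(m for m in flat_measures.MEASURES if m != "kcore")


class UndefinedCorrelationError(ValueError):
    """A correlation was requested for a constant (or too short) vector."""


@dataclass(frozen=True)
class ExperimentConfig:
    """One scenario of the experiment grid.

    ``scale`` divides ``n_networks`` and ``n_agents`` for scaled-down
    replication; every sub-seed is a pure function of ``master_seed``, the
    scenario coordinates and the network index.
    """

    network_type: str = "smallworld"  # or "scalefree"
    model: str = "SIR"
    infection_prob: float = 0.10
    n_networks: int = 25
    n_agents: int = 200
    horizon: int = 200
    recovery_prob: float = 1.0 / 15.0
    dud_threshold: int = 50
    master_seed: int = 0
    scale: int = 1
    ws_k: int = 8
    ws_p_rewire: float = 0.025
    ba_m: int = 4

    def __post_init__(self) -> None:
        if self.network_type not in ("smallworld", "scalefree"):
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    @property
    def eff_n_networks(self) -> int:
        return max(1, self.n_networks // self.scale)

    @property
    def eff_n_agents(self) -> int:
        return max(self.ws_k + 1, self.n_agents // self.scale)

    def disease_config(self) -> ScenarioConfig:
        return ScenarioConfig(
            model=self.model,
            infection_prob=self.infection_prob,
            recovery_prob=self.recovery_prob,
            horizon=self.horizon,
            dud_threshold=self.dud_threshold,
        )


def derive_seed(master_seed: int, *keys) -> int:
    """Stable sub-seed in [0, 2^31) from a master seed and a role key.

    Uses SHA-256 of the repr of the key tuple, so the derivation is
    reproducible across processes and platforms.
    """
    digest = hashlib.sha256(repr((master_seed,) + keys).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def base_network(cfg: ExperimentConfig, index: int) -> nx.Graph:
    """Base network ``index`` of a scenario.  The seed key includes the
    infection probability (each combination has its own 25 instantiations)
    but not the model, so SIR and SIS share instances."""
    seed = derive_seed(
        cfg.master_seed, "network", cfg.network_type,
        round(cfg.infection_prob * 1000), cfg.eff_n_agents, index,
    )
    if cfg.network_type == "smallworld":
        return netgen.make_small_world(cfg.eff_n_agents, cfg.ws_k,
                                       cfg.ws_p_rewire, seed)
    return netgen.make_scale_free(cfg.eff_n_agents, cfg.ba_m, seed)


def scenario_skeleton(cfg: ExperimentConfig, index: int) -> TemporalSkeleton:
    """Skeleton for network ``index``; the draw seed is model-independent so
    SIR/SIS variants share activations and recovery draws."""
    graph = base_network(cfg, index)
    seed = derive_seed(
        cfg.master_seed, "skeleton", cfg.network_type,
        round(cfg.infection_prob * 1000), cfg.eff_n_agents, cfg.horizon, index,
    )
    return build_skeleton(graph, cfg.disease_config(), seed)


def run_scenario(cfg: ExperimentConfig) -> pd.DataFrame:
    """All single-seed runs of a scenario: one row per (network, seed agent)
    with magnitude, cumulative cases and the epidemic flag."""
    frames = []
    for idx in range(cfg.eff_n_networks):
        skel = scenario_skeleton(cfg, idx)
        df = run_all_seeds(skel).reset_index()
        df.insert(0, "network", idx)
        frames.append(df)
        logger.debug("scenario %s net %d done", cfg, idx)
    return pd.concat(frames, ignore_index=True)


def summarize_scenario(runs: pd.DataFrame, dud_threshold: int = 50) -> dict:
    """Outbreak-summary row: mean and stdev of raw magnitude and the dud
    fraction (magnitude < threshold)."""
    mag = runs["magnitude"].to_numpy(dtype=float)
    return {
        "mean_magnitude": float(mag.mean()),
        "magnitude_stdev": float(mag.std(ddof=1)) if len(mag) > 1 else 0.0,
        "percent_duds": float((mag < dud_threshold).mean()),
        "n_runs": int(len(mag)),
    }


def outbreak_summary_table(
    master_seed: int,
    models: tuple[str, ...] = ("SIR", "SIS"),
    network_types: tuple[str, ...] = ("scalefree", "smallworld"),
    infection_probs: tuple[float, ...] = (0.10, 0.15, 0.20),
    scale: int = 1,
    **cfg_kwargs,
) -> pd.DataFrame:
    """Outbreak summary over the scenario grid (one row per scenario).

    SIR and SIS rows of a combination reuse the same skeletons (the draws
    are model-independent), matching the shared-instantiation design.
    """
    rows = []
    for network_type in network_types:
        for beta in infection_probs:
            for model in models:
                cfg = ExperimentConfig(
                    network_type=network_type, model=model,
                    infection_prob=beta, master_seed=master_seed,
                    scale=scale, **cfg_kwargs,
                )
                row = summarize_scenario(run_scenario(cfg), cfg.dud_threshold)
                rows.append(
                    {"model": model, "network_type": network_type,
                     "infection_prob": beta, **row}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations and overlaps
# ---------------------------------------------------------------------------

def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; raises
    :class:`UndefinedCorrelationError` on constant or too-short input so
    degenerate networks can be excluded (and counted) upstream."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedCorrelationError(
            f"need two equal-length vectors of >= 3 values, got {len(x)}, {len(y)}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def top_k_overlap(a, b, k: int = 10) -> float:
    """Fraction of agents shared by the top-k sets of two score vectors.

    Ties break by (score descending, agent id ascending) so the result is
    deterministic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if k > len(a) or len(a) != len(b):
        raise ValueError("need k <= n and equal-length score vectors")
    ids = np.arange(len(a))
    top_a = set(ids[np.lexsort((ids, -a))][:k])
    top_b = set(ids[np.lexsort((ids, -b))][:k])
    return len(top_a & top_b) / k


def _mean_defined(values: list[float], label: str) -> float:
    """Mean excluding undefined (NaN) entries, logging the exclusion count."""
    arr = np.asarray(values, dtype=float)
    bad = np.isnan(arr)
    if bad.any():
        logger.info("%s: excluded %d undefined correlation(s) of %d",
                    label, int(bad.sum()), len(arr))
    if bad.all():
        return float("nan")
    return float(arr[~bad].mean())


# ---------------------------------------------------------------------------
# TKO sweeps
# ---------------------------------------------------------------------------

def network_tko(
    skeleton: TemporalSkeleton,
) -> tuple[AgentTKO, pd.DataFrame]:
    """Agent-aggregated TKO scores plus the per-seed outcome grid for one
    network (the expensive step: n base runs and one knockout per
    infectious agent-time of each)."""
    agent = aggregate_agents(tko_scores(skeleton))
    outcomes = run_all_seeds(skeleton)
    return agent, outcomes


@dataclass
class TKOScenarioResult:
    """Per-network TKO sweeps of one scenario."""

    cfg: ExperimentConfig
    agent_tko: list[AgentTKO] = field(default_factory=list)
    outcomes: list[pd.DataFrame] = field(default_factory=list)
    graphs: list[nx.Graph] = field(default_factory=list)


def run_tko_scenario(
    cfg: ExperimentConfig, n_networks: int | None = None
) -> TKOScenarioResult:
    """TKO sweep over the first ``n_networks`` networks of a scenario."""
    n_nets = cfg.eff_n_networks if n_networks is None else n_networks
    result = TKOScenarioResult(cfg=cfg)
    for idx in range(n_nets):
        skel = scenario_skeleton(cfg, idx)
        agent, outcomes = network_tko(skel)
        result.agent_tko.append(agent)
        result.outcomes.append(outcomes)
        result.graphs.append(skel.graph)
        logger.info("TKO sweep %s/%s/%.2f: network %d/%d done",
                    cfg.model, cfg.network_type, cfg.infection_prob,
                    idx + 1, n_nets)
    return result


def tko_vs_seed_magnitude(
    result: TKOScenarioResult,
    method: str = "pearson",
    outcome: str = "magnitude",
) -> dict[str, float]:
    """Mean (over networks) correlation between the per-seed outcome —
    magnitude, or the binary epidemic flag — and each agent-TKO variant."""
    out: dict[str, float] = {}
    for variant in TKO_VARIANTS:
        vals = []
        for agent, runs in zip(result.agent_tko, result.outcomes):
            y = runs[outcome].to_numpy(dtype=float)
            try:
                vals.append(correlate(agent[variant].to_numpy(), y, method))
            except UndefinedCorrelationError:
                vals.append(float("nan"))
        out[variant] = _mean_defined(
            vals, f"{outcome} vs {variant} ({method})"
        )
    return out


def tko_vs_centrality(
    result: TKOScenarioResult,
    measures: tuple[str, ...] = BENCHMARK_MEASURES,
    variant: str = "mean_prop",
    k: int = 10,
) -> pd.DataFrame:
    """Correlations (Pearson and Spearman) and mean top-k overlap between
    the ``variant`` TKO aggregate and each flat measure on the base
    networks, averaged over the scenario's networks."""
    rows = []
    tables = [
        {m: flat_measures.centrality(g, m) for m in measures}
        for g in result.graphs
    ]
    for m in measures:
        pear, spear, over = [], [], []
        for agent, mt in zip(result.agent_tko, tables):
            tko_v = agent[variant].to_numpy()
            mv = mt[m].to_numpy()
            for acc, method in ((pear, "pearson"), (spear, "spearman")):
                try:
                    acc.append(correlate(tko_v, mv, method))
                except UndefinedCorrelationError:
                    acc.append(float("nan"))
            over.append(top_k_overlap(tko_v, mv, k=min(k, len(tko_v))))
        rows.append(
            {
                "measure": m,
                "pearson": _mean_defined(pear, f"tko vs {m} (pearson)"),
                "spearman": _mean_defined(spear, f"tko vs {m} (spearman)"),
                "top_k_overlap": float(np.mean(over)),
            }
        )
    return pd.DataFrame(rows)


def manifest(cfg: ExperimentConfig) -> dict:
    """Config, derived sub-seeds and versions for the run manifest."""
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "config": dataclasses.asdict(cfg),
        "network_seeds": [
            derive_seed(cfg.master_seed, "network", cfg.network_type,
                        round(cfg.infection_prob * 1000), cfg.eff_n_agents, i)
            for i in range(cfg.eff_n_networks)
        ],
        "skeleton_seeds": [
            derive_seed(cfg.master_seed, "skeleton", cfg.network_type,
                        round(cfg.infection_prob * 1000), cfg.eff_n_agents,
                        cfg.horizon, i)
            for i in range(cfg.eff_n_networks)
        ],
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
    }
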