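import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tkobench import benchmark, cli
from tkobench.benchmark import (
    ExperimentConfig,
    UndefinedCorrelationError,
    correlate,
    derive_seed,
    run_scenario,
    run_tko_scenario,
    scenario_skeleton,
    summarize_scenario,
    tko_vs_centrality,
    tko_vs_seed_magnitude,
    top_k_overlap,
)


class TestCorrelate:
    def test_identity_is_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert correlate(x, x) == pytest.approx(1.0)

    def test_reversed_ranks_spearman(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, x[::-1], "spearman") == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # r = 5 / sqrt(2 * 38/3) for x=(1,2,3), y=(2,4,7)
        r = correlate([1, 2, 3], [2, 4, 7])
        assert r == pytest.approx(5 / np.sqrt(2 * 38 / 3), rel=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            correlate([1, 2], [1, 2])

    def test_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r = correlate(rng.normal(size=10), rng.normal(size=10))
            assert -1.0 <= r <= 1.0


class TestTopKOverlap:
    def test_identical_and_disjoint(self):
        a = np.arange(20.0)
        assert top_k_overlap(a, a, k=5) == 1.0
        assert top_k_overlap(a, -a, k=5) == 0.0

    def test_enumerated_example(self):
        # ranks a: agent0 best... a=(3,1,2,0), b=(3,2,1,0), k=2
        assert top_k_overlap([3, 1, 2, 0], [3, 2, 1, 0], k=2) == 0.5

    def test_tie_break_deterministic(self):
        a = np.ones(6)
        b = np.ones(6)
        # all tied: lowest ids win on both sides
        assert top_k_overlap(a, b, k=3) == 1.0

    def test_k_validation(self):
        with pytest.raises(ValueError):
            top_k_overlap([1.0, 2.0], [1.0, 2.0], k=3)


class TestSeeds:
    def test_derive_seed_stable_and_bounded(self):
        s1 = derive_seed(7, "network", "smallworld", 100, 200, 0)
        s2 = derive_seed(7, "network", "smallworld", 100, 200, 0)
        assert s1 == s2
        assert 0 <= s1 < 2**31
        assert s1 != derive_seed(7, "network", "smallworld", 100, 200, 1)
        assert s1 != derive_seed(8, "network", "smallworld", 100, 200, 0)

    def test_sir_sis_share_networks_and_skeletons(self):
        kw = dict(network_type="smallworld", infection_prob=0.1,
                  n_networks=2, n_agents=30, horizon=20, master_seed=5)
        sir = scenario_skeleton(ExperimentConfig(model="SIR", **kw), 0)
        sis = scenario_skeleton(ExperimentConfig(model="SIS", **kw), 0)
        assert set(sir.graph.edges()) == set(sis.graph.edges())
        assert np.array_equal(sir.act_u, sis.act_u)
        assert np.array_equal(sir.recovery, sis.recovery)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(network_type="lattice")
        with pytest.raises(ValueError):
            ExperimentConfig(scale=0)


class TestScenarioRuns:
    def test_bit_reproducible(self):
        cfg = ExperimentConfig(network_type="scalefree", model="SIR",
                               infection_prob=0.15, n_networks=2,
                               n_agents=40, horizon=40, master_seed=3)
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_summarize_examples(self):
        zeros = pd.DataFrame({"magnitude": [0, 0, 0]})
        row = summarize_scenario(zeros)
        assert row == {"mean_magnitude": 0.0, "magnitude_stdev": 0.0,
                       "percent_duds": 1.0, "n_runs": 3}
        straddle = summarize_scenario(pd.DataFrame({"magnitude": [40, 60]}))
        assert straddle["mean_magnitude"] == 50.0
        assert straddle["percent_duds"] == 0.5

    def test_scale_factor(self):
        cfg = ExperimentConfig(scale=5)
        assert cfg.eff_n_networks == 5
        assert cfg.eff_n_agents == 40

    def test_run_grid_shape(self):
        cfg = ExperimentConfig(network_type="smallworld", model="SIS",
                               infection_prob=0.2, n_networks=2,
                               n_agents=30, horizon=25, master_seed=1)
        runs = run_scenario(cfg)
        assert len(runs) == 2 * 30
        assert set(runs.columns) == {"network", "seed_agent", "magnitude",
                                     "cumulative_cases", "epidemic"}
        assert (runs["magnitude"] >= runs["cumulative_cases"]).all()


@pytest.fixture(scope="module")
def small_sweep():
    cfg = ExperimentConfig(network_type="smallworld", model="SIR",
                           infection_prob=0.15, n_networks=3,
                           n_agents=30, horizon=40, master_seed=2)
    return run_tko_scenario(cfg)


class TestTKOTables:

    def test_seed_magnitude_row(self, small_sweep):
        row = tko_vs_seed_magnitude(small_sweep)
        assert set(row) == set(benchmark.TKO_VARIANTS)
        for v in row.values():
            assert np.isnan(v) or -1.0 <= v <= 1.0

    def test_self_correlation_is_one(self, small_sweep):
        agent = small_sweep.agent_tko[0]
        assert correlate(agent["mean_prop"], agent["mean_prop"]) == 1.0

    def test_epidemic_probability_variant(self, small_sweep):
        row = tko_vs_seed_magnitude(small_sweep, outcome="epidemic")
        for v in row.values():
            assert np.isnan(v) or -1.0 <= v <= 1.0

    def test_centrality_table(self, small_sweep):
        t3 = tko_vs_centrality(small_sweep, k=5)
        assert list(t3["measure"]) == list(benchmark.BENCHMARK_MEASURES)
        assert "kcore" not in set(t3["measure"])
        assert t3["pearson"].dropna().between(-1, 1).all()
        assert t3["top_k_overlap"].between(0, 1).all()

    def test_correlation_declines_with_infection_rate(self):
        """The TKO-vs-seed-magnitude match degrades as the infection
        probability (and hence magnitude) rises."""
        rows = {}
        for beta in (0.10, 0.30):
            cfg = ExperimentConfig(network_type="smallworld", model="SIR",
                                   infection_prob=beta, n_networks=10,
                                   n_agents=50, horizon=100, master_seed=4,
                                   ws_k=6)
            rows[beta] = tko_vs_seed_magnitude(run_tko_scenario(cfg))
        assert rows[0.10]["max_delta"] > rows[0.30]["max_delta"] - 0.05


class TestCLI:
    def test_run_and_tables(self, tmp_path):
        cfg = {"models": ["SIR"], "network_types": ["smallworld"],
               "infection_probs": [0.15], "n_networks": 2, "n_agents": 30,
               "horizon": 25, "master_seed": 1, "tko": True}
        cfg_path = tmp_path / "cfg.yaml"
        import yaml
        cfg_path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "out"
        runner = CliRunner()
        res = runner.invoke(cli.main, ["run", "--config", str(cfg_path),
                                       "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "table1.csv").exists()
        assert (out / "table2.csv").exists()
        assert (out / "table3.csv").exists()
        assert (out / "overlaps.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["grid"]["n_agents"] == 30
        assert len(manifest["scenarios"]) == 1
        t1 = pd.read_csv(out / "table1.csv")
        assert len(t1) == 1 and t1.loc[0, "n_runs"] == 60
        # tables regenerates identically from the raw dumps
        before = (out / "table1.csv").read_text()
        res2 = runner.invoke(cli.main, ["tables", "--out", str(out)])
        assert res2.exit_code == 0, res2.output
        assert (out / "table1.csv").read_text() == before

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("bogus: 1\n")
        runner = CliRunner()
        res = runner.invoke(cli.main, ["run", "--config", str(p),
                                       "--out", str(tmp_path / "o")])
        assert res.exit_code != 0
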