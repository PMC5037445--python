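# tkobench — a temporal-knockout benchmark for network propagation influence

Who are the key agents in the spread of a disease (or an idea) over a
contact network?  Practitioners usually answer with a centrality measure on
a static graph, but influence is a property of how the dynamics unfold
through time: an agent infected on day 3 can be responsible for far more of
the eventual outbreak than the index case, and removing an agent early can
even *increase* the final spread.  `tkobench` implements a ground-truth
measure of per-agent, per-time influence — the **temporal knockout (TKO)
score** — and a benchmarking harness that asks how well static network
measures predict it.

## The model

An SIR or SIS epidemic runs on a **temporal web**: a time-extruded network
whose nodes are agent-times $(i, t)$, $t = 0 \dots T$, with interaction
edges from $i@t$ to $j@{t+1}$ and inheritance edges $i@t \to i@{t+1}$.  At
every iteration agent $i$ activates the link to neighbour $j$ independently
with probability

$$p_{i \to j} \;=\; \frac{k_j}{\sum_{n \in K_i} k_n},$$

where $k_j$ is $j$'s degree and $K_i$ is $i$'s neighbour set (one outgoing
contact per agent per iteration in expectation, biased toward
well-connected partners).  An activated contact transmits with probability
$\beta$ from an infectious activator to a susceptible target; infectious
agents recover (SIR) or return to susceptible (SIS) with probability $1/15$
per iteration.  All of this randomness — activations, transmission draws,
recovery draws — is pre-sampled into a **skeleton**, so a run is a pure
function of the initial condition and any knockout.

The outcome of a run is its **magnitude**: the number of infectious
agent-time nodes, i.e. cumulative cases weighted by how long each infection
lasts.  Runs with magnitude below 50 are *duds*; the complement defines the
binary epidemic flag.

The **TKO score** of node $(i, t)$ is the change in magnitude when agent
$i$ is removed from time $t$ onward, rerun under the *same* skeleton,
averaged over all $n$ single-agent initialisations.  Two normalisations are
kept: proportional, $1 - M_{ko}/M_0$ (1 = removal stops the whole run,
negative = removal increases spread), and delta fraction,
$(M_0 - M_{ko})/\bigl(n(T{+}1)\bigr)$.  Scores aggregate to agents by the
max and the mean over time.  The benchmark correlates these aggregates with
eight static measures — degree, closeness, betweenness, eigenvector, Katz,
k-core, accessibility ($h = 2$) and expected force — on the base network or
on the flattened graph of observed contacts.

## Worked example

```python
import tkobench as tb
from tkobench.temporal_web import ScenarioConfig

graph = tb.make_small_world(n=50, k=6, p_rewire=0.05, seed=3)
config = ScenarioConfig(model="SIR", infection_prob=0.15, horizon=100)
skeleton = tb.build_skeleton(graph, config, seed=11)

record = tb.run(skeleton, initial_agents={0})
print(f"seed 0: magnitude={record.magnitude} agent-times, "
      f"cases={record.cumulative_cases}, epidemic={record.epidemic}")

scores = tb.tko_scores(skeleton)          # every (agent, time) node
agents = tb.aggregate_agents(scores)      # max / mean over time
print(agents.table.sort_values("max_prop", ascending=False).head(3).round(4))

outcomes = tb.run_all_seeds(skeleton)
r = tb.correlate(agents["max_prop"], outcomes["magnitude"])
print(f"max-proportional TKO vs seed magnitude: Pearson r = {r:.3f}")

deg = tb.centrality(graph, "degree")
print(f"TKO top-10 vs degree top-10 overlap: "
      f"{tb.top_k_overlap(agents['mean_prop'], deg, k=10):.2f}")
```

prints

```
seed 0: magnitude=82 agent-times, cases=7, epidemic=True
       max_prop  max_delta  mean_prop  mean_delta
agent
39       0.1254     0.0071     0.0318      0.0020
13       0.0844     0.0057     0.0268      0.0020
23       0.0725     0.0053     0.0211      0.0014
max-proportional TKO vs seed magnitude: Pearson r = 0.092
TKO top-10 vs degree top-10 overlap: 0.40
```

Agent 39 is the one whose best-timed removal saves the largest *fraction*
of an average outbreak (12.5% of the baseline magnitude); yet the weak
correlation with seed-initiated magnitude shows that "how much spread do
you cause when the disease starts at you" is a poor proxy for "how much
spread do you prevent when removed".

Full experiment grids (both network families, three infection rates, SIR
and SIS sharing skeletons) run from the CLI:

```sh
tko-bench run --out results/ --scale 5            # scaled-down grid
tko-bench run --out results/ --tko                # include TKO sweeps
tko-bench tables --out results/                   # rebuild the report CSVs
```

producing `table1.csv` (outbreak summaries), `table2.csv` (TKO vs
seed-magnitude correlations), `table3.csv`/`overlaps.csv` (TKO vs
centrality) and a JSON manifest of every derived sub-seed.

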