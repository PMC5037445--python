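# Methods

## Model overview

`tkobench` simulates discrete-time SIR/SIS epidemics on a fixed population
of `n` agents joined by an undirected *base network* of potential
interactions, and scores each agent-time's influence by knockout
contingency analysis.  The pipeline is: generate base networks → pre-sample
a temporal-web *skeleton* → propagate → knock out → benchmark static
measures against the knockout ground truth.

### Base networks

Two families, generated with networkx and relabelled to dense ids
`0..n-1`:

* Watts–Strogatz small-world: `n = 200`, `k = 8` ring neighbours,
  rewiring probability `0.025`; exactly `n·k/2 = 800` edges.  Disconnected
  draws are rejected and resampled with an incremented sub-seed (the
  experiments require connected graphs; rejection keeps the edge count and
  the degree sequence distributionally intact).
* Barabási–Albert scale-free: `n = 200`, `m = 4`; `(n−m)·m = 784` edges,
  connected by construction.

User-supplied networks load from plain-text edge lists (`i j` per line,
`#` comments).

### Contact process and the skeleton

Each iteration, each agent `i` activates its link to neighbour `j`
independently with probability `k_j / Σ_{n∈K_i} k_n`.  These
probabilities sum to 1 over `K_i`, so each agent initiates one contact per
iteration in expectation, preferentially toward high-degree partners.  A
variant in which every agent draws exactly one partner per iteration from
the same distribution is available (`contact_mode="single"`); the
independent form is the default.  This is an interpretation point: the
source description gives the per-link probability but not whether
activations are independent across a neighbourhood.  Our choice was fixed
by matching the small-world outbreak statistics (see *Fidelity* below).

The skeleton pre-samples, for a horizon of `T = 200` iterations:

* every activation event `(t, i→j)` with a fresh uniform transmission
  draw `u`;
* a uniform recovery draw for every `(agent, t)`.

Sampling depends only on (graph, horizon, contact mode, seed) — not on the
disease model or rates — so SIR and SIS variants of a scenario, and
different infection probabilities interpreted over the same draws, share
identical contact histories.  States exist at times `0..T`; events at `t`
act on states at `t+1` under simultaneous updating.

### Propagation semantics

* Transmission is directional: the event `(t, i→j)` infects `j` at `t+1`
  iff `i` is infectious at `t`, `u < β`, `j` is susceptible at `t`, and
  neither is removed.  The reverse direction needs its own event
  (`bidirectional_transmission=True` relaxes this; off by default — the
  bidirectional reading triples-to-quintuples small-world outbreak sizes
  and is clearly wrong for these parameters).
* An infectious agent both transmits through its `t`-events and may leave
  the infectious state at `t+1` (to R under SIR, to S under SIS) when its
  recovery draw falls below `1/15`; minimum infectious duration is one
  period, expected duration 15.
* A knockout `(a, τ)` removes agent `a` from all states and interactions
  at `t ≥ τ`; removing a not-yet-infected agent still prevents its later
  infection.
* Runs truncate at `T` even if SIR has not burned out.

The batched engine propagates many variants (all 200 seeds, or all
knockouts of one run) in lockstep over one skeleton; `run()` is the
single-variant view.  Both are exercised against an independent
dict-based brute-force simulator in the tests, exhaustively over initial
sets and knockouts on small skeletons.

### Outcome statistics

*Magnitude* = number of infectious agent-time nodes (= Σ_t |I_t|);
*cumulative cases* = agents ever infectious; *dud* = magnitude < 50;
*epidemic* = magnitude > 50.

### TKO scores

For each seed agent: run once (magnitude `M0`), then knock out every
infectious node `(a, t)` of that run and remeasure (`Mko`).  Scores:
proportional `1 − Mko/M0` (0 if `M0 = 0`, unreachable since a seed is
infectious ≥ 1 period) and delta fraction `(M0 − Mko)/(n(T+1))`.  Knockouts
are evaluated only at infectious nodes; any other `(a, t)` inherits the
score of `a`'s next infectious time, or 0 if there is none.  This is exact,
not an approximation: a non-infectious agent neither transmits nor alters
anyone else's state, so removing it any time before its next infection is
equivalent to removing it at that infection, and removing it after its last
infection changes nothing.  The equivalence is verified against the
brute-force oracle, which re-simulates *every* `(agent, time)` removal.

Node TKO = the arithmetic mean of per-run scores over all `n` seed runs,
dud runs included.  Agent aggregates: max and mean over `t ∈ 0..T` of each
variant.  Both of these are interpretation points (duds in or out; mean
over all times or only infected times); we keep the literal reading —
all runs, all times.

`count_seed_combinations(n, r) = C(n, r)` quantifies why multi-seed
exhaustive analysis is impractical (1,313,400 runs for three seeds on 200
agents) and why post-hoc combinability of single-seed TKO matters.

### Flat measures

Degree, closeness, betweenness, eigenvector and Katz centralities and
k-core delegate to networkx.  Katz attenuation is `α = 0.85/λ_max`
(recorded in table metadata; the benchmarked sources leave it
unspecified).  On weighted flattened graphs, activation counts serve as
weights for degree/eigenvector/Katz and as inverse distances
(`1/weight`) for closeness/betweenness.

*Accessibility* (`h = 2`): `exp(H)` of the entropy `H` of the two-step
random-walk endpoint distribution; returns to the origin included (a
self-avoiding variant is available; the literature has both).  Isolated
nodes score 0.

*Expected force*: enumerate all transmission clusters after exactly two
transmission events from the seed — each event an edge from the infected
set to a susceptible, clusters counted once per formation path (ordering
multiplicity); score = entropy of the normalised cluster out-degrees.
Plain form, without the degree-1-seed modification.  Verified against an
exhaustive ordered-sequence enumerator on all graphs up to 6 nodes.

k-core is computed but excluded from default benchmark reports: its values
are too coarse on these networks to rank agents.

### Benchmark harness

Scenario grid: {small-world, scale-free} × {SIR, SIS} × β ∈
{0.10, 0.15, 0.20}; 25 networks per (family, β) combination, one run per
agent per network (5 000 runs per scenario row).  Every sub-seed derives
from `sha256(master, role, coordinates)` (< 2³¹) and is written to the run
manifest, so full reports regenerate bit-identically from (config, master
seed).  Correlations are Pearson or Spearman; constant vectors raise an
undefined-correlation error and are excluded (and counted) from
across-network means.  Top-k overlap uses `k = 10` with deterministic
(score desc, id asc) tie-breaking.  Per-agent epidemic probability is the
binary epidemic flag of that agent's seed run.  Scaled-down mode divides
`n_networks` and `n_agents` by a scale factor.

## Problem sizes used in the shipped checks

The outbreak-summary and pooled-correlation checks run the full published
grid (25 networks × 200 agents × 200 iterations per scenario; ~10 s per
grid with the batched engine).  TKO sweeps cost ~4 s per 200-agent network,
so the TKO benchmark checks use 8 networks per scenario (SIR, β = 0.10,
both families) rather than 25; correlation bands in those checks are ±0.1.
Oracle-equivalence checks use 3–5 agents and ≤ 6 iterations, exhaustively.

## Fidelity: what reproduces and what does not

The small-world half of the design reproduces the reference outbreak
statistics closely at full scale (e.g. SIR/β=0.10 mean magnitude 95 vs
88.9 reported, duds 0.59 vs 0.58; SIS/β=0.20 mean 7 460 vs 7 037), as do
the dud fractions of every scenario and the pooled
cumulative-cases-vs-magnitude correlations (0.991 vs 0.995 SIR, 0.953 vs
0.936 SIS) and magnitude-vs-epidemic correlation (0.62 vs 0.617).

Scale-free outbreaks are systematically smaller than reported at the higher
infection rates (roughly half the mean magnitude at β ≥ 0.15).  We tested
the alternative contact readings (single-contact mode, reversed
transmission direction, bidirectional transmission, target-side
normalisation): each fits the overall outbreak table strictly worse.  The
exact contact mechanism on heterogeneous-degree graphs is not recoverable
from the available description; the documented default is the literal one.
Consequences inherit downstream: on scale-free networks our
degree-biased contacts funnel infection through hubs, so hub knockouts
dominate TKO and correlate with degree-type centralities (~0.5–0.6) far
more strongly than the near-zero reference values, and in the
TKO-vs-seed-magnitude comparison the per-run-normalised proportional
variant is dominated by dud-run contributions (its max-aggregate
correlates ~0.1 where ~0.49 is reported; the delta-fraction variant
reproduces its reported ~0.47).  The acceptance tests assert the reported
values and therefore fail on exactly these quantities; the failures are
deliberate and documented rather than papered over with loosened
tolerances.

## What the synthetic generators do and do not emulate

Generated networks are connected, degree-heterogeneous (BA) or clustered
(WS) but static: no births/deaths, no behavioural rewiring during an
outbreak (the skeleton fixes all contacts in advance — that fixity is what
makes knockout reruns well-defined).  Real contact data are bursty,
assortative and adaptive; passing tests here validate the machinery and
the stated model, not transferability of any particular centrality's
performance to empirical temporal networks.

## Numerical notes

* All propagation is integer/boolean; no floating-point accumulation.
* Proportional scores guard `M0 = 0` (defined 0) though it cannot occur
  with a nonempty seed set.
* Closeness on disconnected graphs uses the networkx per-component
  convention with the improved (reachable-fraction) scaling.
* Eigenvector/Katz use dense eigensolvers (n = 200); eigenvector
  non-convergence on pathological inputs surfaces as an error rather than
  a silent wrong answer.
* Per-(seed, knockout) simulations are order-independent; results are
  identical no matter how the batch is partitioned.
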