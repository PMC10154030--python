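# flockspread

Simulation of behavioural contagion on weighted animal social networks.

Many animals acquire novel behaviours by learning from others, and the
social network along which information can flow is built from everyday
associations — for fission–fusion foragers such as wintering songbirds, from
co-membership of feeding flocks. Whether sociable, well-connected
individuals actually adopt new behaviours *earlier* depends on the learning
rule: a behaviour that spreads like a disease favours hubs, while a
behaviour that requires reinforcement from the majority of one's associates
may not. `flockspread` is a pipeline for exploring exactly this question on
replicate, weekend-scale association networks: it generates (or ingests)
flock-membership event tables, builds simple-ratio-index (SRI) networks,
simulates order-of-acquisition diffusion under four social learning rules,
and quantifies how individual network position relates to adoption order.

It is aimed at behavioural ecologists and network scientists who want a
tested, reproducible reference implementation of these contagion rules on
realistic association data.

## The model

Associations are weighted by the simple ratio index: for a dyad (i, j),
`a_ij = n(events with both) / n(events with either)`, in [0, 1]. One
undirected network is built per location × sampling week; networks with
fewer than 10 individuals or with no variation in node metrics are
excluded. Each individual is summarised by three weighted metrics —
strength (weighted degree) `s_i = Σ_j a_ij`, the Barrat weighted clustering
coefficient, and weighted betweenness on inverse-weight shortest paths —
z-scored within each network.

A behaviour is seeded in a random demonstrator and spreads one adoption per
timestep. Naive individual *i* acquires it at rate
`λ_i = λ_0 (T_i + 1)`, where `x_i = Σ_j a_ij z_j` is its weighted
connection to informed individuals (`z_j` the informed status) and the
transmission function `T` encodes the learning rule:

| rule       | T(x)                                          | interpretation |
|------------|-----------------------------------------------|----------------|
| simple     | `s·x`                                         | rate ∝ connections to informed (disease-like) |
| threshold  | `c/(1−σ(−ab)) · (σ(b(x−a)) − σ(−ab))`         | sharp sigmoidal threshold at `x = a` (σ = logistic, sharpness `b`, max `c`) |
| proportion | `s·x / Σ_j a_ij`                              | rate ∝ informed *fraction* of connections |
| conformity | `s·x^f / (x^f + (Σ_j a_ij − x)^f)`            | disproportionate copying of the majority (`f ≥ 1`; reduces to proportion at `f = 1`) |

Because only the order of acquisition is simulated, the baseline rate λ_0
cancels: the next adopter is drawn with probability ∝ `T_i + 1`, and the
probability that an adoption event was social rather than asocial is
`p_social = T/(T+1)`. Per network × rule, Spearman's rank correlation
between each metric and adoption position (demonstrator excluded) is
averaged over 100 replicate diffusions, and a linear mixed-effects model
(random intercepts for location and for week nested in year) relates the
mean correlation to network size. Headline parameters: `s = a = f = 5`,
`b = 3`.

## Worked example

```python
import flockspread as fs
from flockspread.network_builder import build_networks, filter_networks
from flockspread.metrics import node_metrics
from flockspread.contagion import default_rule_grid, replicate_diffusions
from flockspread.analysis import aggregate_correlations

config = fs.FlockGenConfig(n_locations=4, n_periods=6, seed=42)
events = fs.generate_flock_events(config)
print(fs.emulation_report(events).round(2).to_string(index=False))

networks, excluded = filter_networks(build_networks(events))
metrics = {net.network_id: node_metrics(net) for net in networks}
runs = []
for net in networks:
    runs.extend(replicate_diffusions(net, default_rule_grid(),
                                     n_reps=100, master_seed=1))
records = aggregate_correlations(runs, metrics)
print(records.groupby(["rule", "metric_name"])["mean_rho"].mean()
             .unstack().round(3).to_string())
```

prints

```
 n_networks  size_mean  size_sd  size_min  size_max  strength_mean  edge_weight_mean
         24      25.38    11.11      10.0      60.0            2.5              0.19
metric_name  weighted_betweenness  weighted_clustering  weighted_degree
rule
conformity                  0.001                0.000            0.003
proportion                 -0.012                0.003           -0.023
simple                     -0.202                0.148           -0.267
threshold                   0.003               -0.002            0.005
```

The generated networks match their calibration targets (mean size ≈ 21.7
over large batches, mean strength ≈ 2.5). Under the simple rule, birds with
higher strength and betweenness adopt earlier (negative mean ρ) and more
clustered birds later (positive mean ρ); under the ratio-based proportion
and conformity rules individual network position barely predicts adoption
order; the threshold rule's correlations are small because, at threshold 5
and typical strength 2.5, social learning is starved in most networks.

A full pipeline run (generate → networks → metrics → simulate → analyse,
with CSV outputs and a manifest) is available from the CLI:

```sh
flockspread run --out results_dir --seed 1
flockspread generate --out events.csv --seed 3
flockspread validate edges.csv --nodes nodes.csv
```

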