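# Methods

## Scope and design

`flockspread` implements a complete simulation study of behavioural
contagion on weekend-scale, per-location association networks: a synthetic
flock-membership generator, SRI network construction with exclusion rules,
weighted node/global metrics, order-of-acquisition diffusion under four
social learning rules, and statistical summaries (metric–order
correlations, network-size effects, social-learning-probability curves).
The pipeline starts from flock membership tables; detecting flocking events
from raw antenna visit streams (e.g. Gaussian-mixture segmentation of RFID
data) is out of scope, as are times-of-acquisition (TADA) simulation,
reversion to the naive state, heterogeneous per-individual learning rules,
and dynamic network rewiring.

## Synthetic flock data

The generator emulates fission–fusion foraging data sampled at fixed
feeding sites on repeated weekends. Per site × weekend:

* **Pool size** ~ negative binomial(mean 18, dispersion 2.2) truncated to
  [10, 77] by rejection. Calibrated with `emulation_report` so that a
  200-network batch has mean size ≈ 22 (sd ≈ 12), matching a right-skewed
  size distribution with overall mean near 21.7 and hard bounds 10–77.
* **Attendance propensity** per bird ~ Beta(a, a) with
  `a = 1/(2η)` so the variance is η/4; the heterogeneity η (default 0.35)
  produces the heavy-tailed strength distributions typical of fission–fusion
  systems. η = 0 makes all birds exchangeable, a useful null.
* **Gathering events**: 25–40 per weekend; group size ~ truncated negative
  binomial(mean 3.95, dispersion 8), minimum 2, maximum the pool size. Group
  size controls mean node strength; 3.95 yields strength ≈ 2.5 in the
  derived networks.
* **Communities**: each bird belongs to one of 3 latent communities; each
  event has a "home" community whose members' sampling weights are
  multiplied by 4. This decouples clustering from strength: birds that
  bridge communities gain strength and betweenness but lose clustering. On
  calibrated batches the node-metric correlations have the signs expected
  of such data (clustering negative with strength and betweenness, strength
  positive with betweenness).
* Site rosters persist across weekends, so the same IDs recur; periods map
  to 13 weeks per year starting in 2012.

A closure pass adds any never-sampled pooled bird to one random event, so
realised network size equals pool size. All draws come from one
`numpy.random.Generator` seeded by `FlockGenConfig.seed`; identical configs
give byte-identical CSV output.

What the generator does **not** emulate: movement of birds between sites
within a weekend (rosters are site-exclusive), temporal autocorrelation of
group composition within a weekend, observation error in flock assignment,
and annual turnover. Passing tests on this generator therefore demonstrate
correctness and qualitative robustness of the contagion machinery on
realistically structured networks, not quantitative predictions for any
particular wild population.

## Networks and metrics

SRI uses the event-proportion form `a_ij = n(both) / n(either)`; the
null-flock corrections of some association-index variants are not applied.
Birds present in the period but never associated are retained as isolates
(they can only learn asocially); exclusions act on whole networks only:
size < 10, or zero variance in any node metric (on such networks a rank
correlation with adoption order is undefined — note that *any* complete
graph has Barrat clustering exactly 1 for every node).

Barrat clustering is computed from its defining formula (cross-checked
against python-igraph in the tests); nodes with binary degree < 2 are
undefined (NaN) and imputed as 0 before z-scoring so every bird remains
rankable. Betweenness and shortest paths use edge length `1/a_ij` via
networkx, raw (unnormalised) pair counts, equal splitting among tied
shortest paths. Standardization is the z-score with sample sd (ddof = 1).
Global measures (density, average inverse-weight path length over connected
pairs, mean nonzero edge weight, modularity of a greedy weighted partition)
are descriptive only; the modularity algorithm is exchangeable without
affecting any inference.

## Diffusion

Exactly one adoption per timestep; no reversion. The next adopter is drawn
among naive individuals with probability ∝ `T_i + 1`, evaluated on the
state *before* the event. This is the order-of-acquisition (OADA) logic
under `λ_i = λ_0 (T_i + 1)`: the baseline rate cancels from the selection
probabilities, so λ_0 never needs a value.

Numerical notes on the transmission functions:

* The threshold rule is implemented with `scipy.special.expit` so that
  `T(0)` is *exactly* zero (both sigmoid terms evaluate to the same float),
  `T` is nondecreasing, and `sup T = c`. By default `c = s` — the rule's
  stated maximum equals the transmission strength — with `c` exposed
  separately on `RuleSpec` for users who want them decoupled.
* Conformity at `f = 1` reduces to the proportion rule to ≤ 1e−12 (float
  associativity is the only source of discrepancy); ratio rules return 0
  for isolates (total strength 0).
* `p_social = T/(T+1)`, the social share of the total acquisition rate. It
  is 0 exactly for asocial events and approaches but never attains 1; the
  alternative reading "fraction of the rule's maximum", which does reach 1,
  is available as `social_learning_probability(T, t_max=...)` but is off by
  default.

Per replicate one demonstrator is drawn uniformly and shared across all
rules, pairing the rule comparison. Default 100 replicates per network:
across independent batches the Monte-Carlo sd of a network's mean
correlation is small relative to the between-rule differences of interest.
Seeds for every (network, replicate, rule) stream derive deterministically
from the master seed via `SeedSequence`, so single runs are reproducible in
isolation and results are independent of iteration order.

## Statistics

Spearman correlations (midrank ties) between adoption position 2..N and
each z-scored metric always exclude the demonstrator, whose position is a
design artefact. Replicates with an undefined correlation are dropped and
counted. Network means are arithmetic means of raw ρ; Fisher-z averaging is
available via `fisher=True` (it changes little at these |ρ| but is provided
for users who prefer it).

The size model is `mean_rho ~ network_size` with random intercepts for
location and for week nested in year, fitted by REML with statsmodels'
variance-components formulation (a single dummy group with crossed
components). Degenerate designs (constant size) raise; singular or
single-location fits are flagged but still report the slope, never silently
dropped. Intercept-only random effects are used; week-level random slopes
are not.

Probability curves report the mean and 2.5/97.5 percentile band of
`p_social` against the count of informed individuals, per rule × network
size bin; size bins are quantile-based (default 4) since no canonical bin
edges exist for such data. Acquisition profiles report the mean z-scored
metric of the adopter at each position, optionally on a standardized
(decile) position axis.

## Problem sizes

Default test and reproduction batches are sized for a single CPU:
the direction-reproduction check uses ~190 retained networks × 4 rules ×
100 replicates (≈77k diffusions, ~3 min including correlation
aggregation); `scripts/acceptance.py` uses 160 networks × 50 replicates
(~80 s). These sizes give Monte-Carlo error far below the effect sizes
being checked; they are choices of this package, and users can scale
`FlockGenConfig` and `n_reps` up freely.

## Known limitations

* The threshold rule's correlations are tiny on small networks because
  social learning is starved (mean strength ≈ 2.5 against threshold 5);
  conclusions about *its* metric–order relationship need larger or denser
  networks than the defaults produce.
* Mixed-model variance components are noisy with few locations; the slope
  is robust but random-effect variances should not be over-interpreted.
* `p_social` compares rules through a shared rate decomposition; it is not
  an estimate of social learning in any empirical dataset.
* The generator's community count and assortment are fixed per config, not
  drawn per network; between-network structural variation comes from pool
  size, event counts and propensity sampling.
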