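# Methods

## Model

`cultne` simulates a haploid Wright–Fisher process reinterpreted for
cultural transmission. A generation is a vector of N variant labels
(non-negative integers) plus a global innovation counter; labels are
allocated sequentially and never reused, so innovation follows the
infinite-alleles assumption and labels remain globally unique even across
coupled populations sharing a counter. Each generation, every learner
independently innovates with probability μ or copies a member of its
role-model pool; the copy target defines a parent–offspring link, and the
per-parent link counts ("cultural influence") are the raw material for all
effective-size estimation.

Innovating learners have no cultural parent: innovation is an alternative
to copying, so the mean influence is k̄ = (1 − μ) · offspring / pool. At
the default μ = 10⁻⁴ this is indistinguishable from 1.

## Estimators

With pool size N<sub>t−1</sub>, mean influence k̄ and
*population-convention* variance σ² (divisor = pool size, not pool − 1):

- N<sub>e</sub><sup>i</sup> = (N<sub>t−1</sub> k̄ − 1)/(k̄ − 1 + σ²/k̄),
  undefined (flagged NaN, excluded from averages) when the denominator is
  non-positive;
- N<sub>e</sub><sup>v</sup> = (N<sub>t−1</sub> − 1) k̄²/σ², undefined when
  σ² = 0;
- for constant sizes both reduce to (N − 1)/σ².

The population-convention variance is deliberate: under one-to-many
transmission with mu = 0 it makes the simulated variance match the closed
form (N − 1)/R exactly in expectation (e.g. R = 1, N = 4: counts
{4,0,0,0}, σ² = 3 = N − 1), which the sample convention would not.

**Aggregation across generations.** A replicate's point estimate pools the
moments first — k̄ and σ² are averaged over the recorded window, then the
formulas applied — rather than averaging per-generation N<sub>e</sub>
ratios. The mean of per-generation (N−1)/σ²<sub>t</sub> carries an upward
Jensen bias of order Var(σ²<sub>t</sub>)/E[σ²<sub>t</sub>]² (about +3.6%
for one-to-many with R = 10), while the pooled estimator is unbiased
enough to reproduce N<sub>e</sub> = R to three digits. Per-generation
values are still recorded for time-series analyses (transient dynamics
after a transmission-mode switch), where the ratio bias is small because
σ²<sub>t</sub> is near 1.

Across replicates, summaries report the mean and an empirical 90%
prediction interval (5th/95th percentiles, linear interpolation).

## Transmission modes

- **Unbiased**: each learner copies a uniformly random member of the
  parental generation (self included — the parent of one's slot is not
  special). Per-parent counts are Binomial(N, 1/N): mean exactly 1 with
  μ = 0, variance 1 − 1/N.
- **One-to-many**: R role models are redrawn uniformly *without*
  replacement each generation (no fixed elite). Influence counts cover all
  N parents, non-models scoring 0 — that pooling is what produces
  σ² = (N − 1)/R.
- **Frequency-dependent**: variant *i* is adopted with probability
  n<sub>i</sub><sup>θ</sup>/Σn<sub>m</sub><sup>θ</sup> · (1 − μ). The
  exponent acts on absolute counts; normalisation makes this identical to
  acting on relative frequencies, and θ = 1 reduces exactly to unbiased
  transmission. A learner adopting variant *i* is credited to a uniformly
  random carrier of *i* — the unique parent attribution that is symmetric
  among carriers, equivalent to choosing an individual role model with
  probability ∝ n<sub>v(j)</sub><sup>θ−1</sup>.
- **Migration**: X ~ Binomial(N, m) individuals ("an average of mN", each
  individual migrating independently) are swapped symmetrically between
  two equal populations, as disjoint sets chosen uniformly; census sizes
  stay exactly N. A deterministic round(mN) variant is available as a
  toggle. Both populations then take independent unbiased steps.
- **Cultural exchange**: X ~ Binomial(N, e) members of the other
  population are appended to each population's role-model pool for one
  generation only; influence counts span the enlarged pool (home members
  first). Borrowed individuals remain members — and potential parents —
  of their home population in the same generation. With binomial copying
  this yields N<sub>e</sub><sup>i</sup> ≈ (N − 1)(1 + e) while
  N<sub>e</sub><sup>v</sup> ≈ N: the inbreeding size follows the
  role-model pool, the variance size the learner count.
- **Influx**: a fixed number of immigrants per generation joins the focal
  parental pool, and the focal offspring generation grows by that number.
  The source census stays constant (it is treated as large and at its own
  equilibrium; migrants are drawn without replacement per generation) and
  advances one unbiased generation per step so its variant spectrum keeps
  turning over.
- **Networks**: the learner at node v copies a uniformly random neighbour
  of v (never itself), or innovates. Node positions are heritable slots:
  generation t's learner at v is generation t+1's parent at v. The graph
  is fixed for a replicate's lifetime; a fresh graph is drawn per
  replicate. An isolated node retains its variant unless it innovates and
  is credited as its own parent, preserving the conservation law
  Σcounts + innovators = N.

## Network generators

Erdős–Rényi G(N, p) and Watts–Strogatz graphs use networkx's standard
generators (the Watts–Strogatz lattice has K neighbours *per side*, i.e.
degree 2K and exactly N·K edges before and after rewiring). The
preferential-attachment generator is written here because the attachment
power π is tunable: growth starts from a two-node connected seed and each
arriving node attaches two edges to distinct existing nodes sampled
without replacement with probability ∝ degree<sup>π</sup>, giving exactly
2(N − 2) + 1 edges. Reading "nodes are added two at a time" as two edges
per arriving node (the standard m = 2 growth) is a modelling choice; π = 1
is linear preferential attachment, π = 0 uniform attachment, π ≳ 3
produces near-stars. Graphs import/export as two-column 0-based edge lists
(plus GraphML for interoperability).

## Experiment protocol

Every population starts from maximal diversity (all-distinct labels) and
burns in before recording. The default burn-in is 4N generations of
unbiased transmission: the variant spectrum relaxes toward
innovation-drift equilibrium on the coalescence timescale of N
generations, so 4N leaves ~e⁻⁴ of the initial excess diversity. A
diagnostic (`burn_in_series` + `stationarity_check`) verifies
trend-stationarity of the unique-variant count over the trailing quarter
of the burn-in, using block means to absorb autocorrelation. Network
modes burn in under the network dynamic itself (the network is the
population's permanent structure); two-population modes burn in as
isolated populations and are coupled only during the recorded window, so
generation t = 0 is the first generation under the coupled (or switched)
dynamic. For frequency-dependent runs the burn-in is unbiased (θ = 1) and
t = 0 is the first generation whose learners use the new θ.

Default recording is 300 generations. Replicate r of master seed s uses
`numpy.random.default_rng([s, r])`, making single replicates reproducible
in isolation and full tables byte-identical across runs.

## Problem sizes

Simulation experiments in the test suite and the acceptance script run at
the package's desk-scale defaults: N = 1000 with 30–100 replicates for
the headline comparisons (closed-form one-to-many checks use shortened
burn-ins, since influence moments under one-to-many and network
transmission do not depend on the variant state), N = 92–500 with 24
replicates × 500 recorded generations for the equilibrium variant-count
estimates, and N ≤ 300 for module-level statistical tests. The CLI sweep
presets default to 200 replicates; the full 1000 used for
publication-quality precision is a flag away.

## What the simulations do and do not show

The generator emulates neutral cultural transmission in closed or
pairwise-coupled populations with non-overlapping generations, a single
trait, and innovation as a constant per-learner hazard. It does not model
selection or payoff bias, continuous traits with copying error, overlapping
generations, more than two demes, directed or weighted networks, or
networks that rewire during a run. Passing tests therefore demonstrate the
internal consistency of the drift/effective-size theory under these
idealisations, not the realism of any particular empirical system.

Known quantitative behaviours worth flagging:

- At a high innovation rate (μ = 0.1) the equilibrium unique-variant count
  of the exact discrete process is ~10% below classical closed-form
  (diffusion/coalescent-based) approximations; the package reports the
  simulated value.
- The transient N<sub>e</sub> drop after a switch to conformist
  transmission (θ = 1.5) deepens with the innovation rate: with N = 1000
  the mean trough is only ~2% below N at μ = 10⁻⁴ (the equilibrium variant
  spectrum is nearly fixed, leaving conformity little variation to act
  on), ~11% at μ = 10⁻³ and ~20% at μ = 10⁻². Anti-conformity (θ = 0.5)
  produces much deeper immediate troughs and a permanently depressed
  equilibrium N<sub>e</sub> that decreases with μ.
- Per-generation effective sizes are undefined for generations with
  σ² = 0 or a non-positive inbreeding denominator; such generations are
  excluded from averages (they occur only in tiny or degenerate
  populations).
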