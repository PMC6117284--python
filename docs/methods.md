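# Methods

## The mixing model

Each network node is treated as an independent unmixing problem over its
immediate inputs: the stratified source groups sampled in that node's
sub-watershed, plus one pseudo-source per upstream node whose "source
samples" are that node's mixture samples. Mixture tracer values are modelled
as Gaussian around a convex combination of source signatures. The Gaussian
assumption for mixtures is reasonable even when individual sources are
skewed, because a mixture is a weighted combination of source means and the
central limit theorem applies.

Two error formulations are available:

- **residual only** (default): a per-tracer residual SD τ_j absorbs all
  scatter around the mixing mean. This is the right choice with few mixture
  samples and a factor (sediment type, season), the common situation at river
  nodes.
- **process only**: the likelihood SD is √(Σ_k p′²_kj σ²_kj), propagating
  source variance instead of estimating a residual scale.

Concentration dependence re-weights proportions per tracer,
p′_kj = p_k c_kj / Σ_l p_l c_lj, so that mass-space proportions are
consistent with tracer-space mixing when sources differ in tracer
concentration (relevant for δ¹³C fatty-acid tracers, where fatty-acid
content varies strongly between land uses). With equal concentrations the
weighting cancels exactly; the implementation reproduces this bitwise.

### Priors and parameters

| parameter | meaning | default | why |
|---|---|---|---|
| α (per source) | Dirichlet pseudo-counts over proportions | 1 (uninformative) | flat over the simplex; a small value (e.g. 0.01 on channel banks) encodes prior belief in a minor contribution |
| τ_j | residual SD, units of tracer j | sampled, Uniform(0, 10 × empirical mixture SD of tracer j) | vague but scale-aware; an explicit `tau_fixed` pins it for controlled analyses |
| μ_kj, σ_kj | source mean/SD | redrawn each iteration from the sources-only posterior | propagates source-sampling uncertainty |
| factor | one fixed factor | none (single level "all") | each level gets an independent simplex under the shared Dirichlet prior; source parameters and τ are shared across levels |

Source-parameter uncertainty uses the closed-form posterior under the
noninformative prior p(μ, σ²) ∝ 1/σ²: σ² ~ scaled-inv-χ²(n−1, s²), then
μ | σ² ~ N(x̄, σ²/n). Draws are refreshed every MCMC iteration and the
current state's log posterior is re-evaluated under the same draw before the
Metropolis comparison (Monte-Carlo-within-Metropolis). This propagates
source uncertainty while keeping the sampler simple and separately testable;
jointly updating source parameters against the mixture data is a documented
alternative backend, not implemented. The per-level-simplex treatment of the
factor is likewise a deliberate simplification of ILR fixed-effect
regression formulations: it reproduces per-level proportion outputs without
a prior on factor effects.

### Sampler

Adaptive random-walk Metropolis in unconstrained coordinates: each level's
simplex is mapped to ℝ^(K−1) by the isometric log-ratio transform (orthonormal
Helmert basis, implemented in `_sampler.py` and cross-checked against an
independent composition library in the tests), and τ is sampled on the log
scale. The target density in these coordinates includes the corresponding
Jacobians (Σ log p_k per level; Σ log τ). Proposals are blocked (one block
per level, one for the τ vector) with per-block scales adapted by
Robbins–Monro toward 0.3 acceptance **during burn-in only**, so the retained
draws come from a fixed kernel satisfying detailed balance. Per-chain seeds
derive from the master seed via `numpy.random.SeedSequence`. The hot loop is
JIT-compiled with numba; the first fit in a session pays a few seconds of
compilation.

Default MCMC settings are chain length 10⁶, burn-in 7×10⁵, thinning 300,
3 chains (1000 retained draws per chain). The test suite and examples use a
short profile — 50 000 / 25 000 / 25 / 3 — chosen because the desk-scale
problems here (K ≤ 4, J ≤ 8) mix quickly; the grid-integration test verifies
the short profile is already accurate at total-variation < 0.05.

### Convergence gating

All proportion components and sampled τ are monitored with the classical
Gelman–Rubin PSRF, R̂ = √(((n−1)/n·W + B/n)/W). A fit fails when more than
5% of monitored variables exceed 1.05; the network driver then retries once
with doubled chain length and otherwise raises (or returns a flagged
posterior under `force=True`). Exactly-agreeing chains give the formula's
floor √((n−1)/n) ≤ 1.

## Deconvolution

Nodes are fitted upstream-first (lexicographic topological order, so ties
are deterministic). Composite contributions of ultimate source classes are
obtained per retained draw by the recursion
composite(m) = Σ_inputs q_i·composite(i), with a local group contributing the
indicator of its class. Since independently fitted nodes have independent
posteriors, any draw pairing is valid; each node's pooled draws are permuted
with a seed derived from the pairing seed and paired index-wise, which
removes chain-order artifacts. The composite draw count is the minimum over
nodes (no resampling by default). The recursion conserves the simplex
exactly; tests assert it at 10⁻¹⁰.

Factor levels chain like-with-like when shared across nodes. When an
upstream node lacks the downstream level, its pseudo-source already pools
samples across levels, and composite chaining falls back to the upstream
"all" level or an explicit level map; an unalignable level without a map is
an error.

The **pooled baseline** merges same-class groups across sub-watersheds
(concatenating raw samples, or combining summaries by exact pooled moments)
and unmixes all node mixtures against the merged classes in one model, with
the node label as the factor unless the run config names one.

## Tracer screening

The range test pools all source samples at a node and checks containment of
each mixture value in [min, max]; a tracer passes when at least a threshold
fraction (default 0.5) of mixture samples are inside. The threshold
operationalises "mixture values largely outside the source range" and is a
policy parameter, as is the bound convention (raw min/max by default;
1.5×IQR whiskers optional, since whisker conventions vary; mean ± 2·SD as an
explicit opt-in for summary-only sources). ANOVA/Tukey quantify source
discrimination (scipy's implementations behind the module surface, verified
against hand sums-of-squares and a studentized-range oracle). Normality is
summarised (Shapiro–Wilk p, histograms) but never used as a hard filter.
Expert include/exclude overrides are applied after the automatic step and
flagged "manual" in the report. Screening is per node in deconvolutional
mode and on pooled sources in pooled mode, which is why the two modes can
legitimately retain different panels.

## Synthetic data

The generator mirrors field-study scale: 3–15 tracers, 10–30 source samples
per group, 3–9 mixture samples per node, Gaussian source scatter (SD 1 in
tracer units by default) and residual noise τ = 0.5. Mixture means are
chained through the network exactly as the model assumes, so the
data-generating process matches the fitted model when error and
concentration options agree — which is what makes posterior-consistency and
coverage tests meaningful. Consequently, passing tests demonstrate correct
inference *under the model*, not robustness to real-data pathologies:
non-Gaussian sources, non-conservative tracers, temporally varying
proportions and unrepresentative sampling are all outside what the generator
emulates (the screening module exists precisely because real tracers
misbehave).

Presets:

- `recovery_truth`: one node, K=3 well-separated sources, J=8, true
  p = (0.6, 0.3, 0.1), 30 source samples/group, 10 mixture samples.
- `pooling_hurts_truth`: two tributaries and a confluence where class A's
  signature is shifted in opposite directions in the two sub-watersheds
  (±6 tracer units against within-group SD 1, i.e. stratification carries
  real signal). Watershed-pooling collapses class A's signature toward class
  B's, so the pooled fit is confounded while the stratified fits are not —
  the mechanism by which pooling overestimates one source downstream.

All randomness flows from one master seed through named `SeedSequence`
substreams (sources / mixtures / node), so source and mixture noise are
independent and every table is reproducible.

## Numerical choices and degenerate inputs

- ILR is used (rather than sampling on the simplex) because it is an
  isometric bijection with a constant-free Jacobian Σ log p_k.
- Softmax inversion is max-shifted; proportions are positive by
  construction and sum to 1 to ~10⁻¹⁶.
- Source groups with zero empirical SD on a tracer are kept degenerate
  (μ = x̄, σ = 0) and allowed only with residual-only error; `process_only`
  requires nonzero source variance somewhere.
- K = 1 source is rejected (nothing to unmix); upstream nodes need ≥ 2
  mixture samples to serve as pseudo-sources (SD undefined otherwise);
  summary-mode source groups need n ≥ 2 per tracer.
- Missing mixture values are never imputed: incomplete rows are dropped with
  a warning, and an empty or sub-minimal result is an error.
- Report rendering rounds to two decimals ("0.52 ± 0.14") and always writes
  a machine-readable CSV twin; rounding is presentation-only.

## Known limitations

- No sediment-load weighting: apportionment is in proportion space under a
  mass-conservation assumption; combining with load estimates is left to the
  user.
- No trophic/transport fractionation offsets on tracers.
- No random-effect hierarchies or combined process×residual error.
- The pooled baseline with two factors is emulated by separate single-factor
  runs (marginal by node or by type), not a joint two-factor model.
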