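# riverunmix

Bayesian sediment source apportionment for hierarchical river networks.

Sediment fingerprinting asks what fraction of the sediment collected at a
point in a river came from each candidate source (land uses, channel banks,
sub-watersheds), using geochemical or compound-specific stable-isotope
tracers. Conventional mixing models pool source samples across the whole
watershed and unmix each mixture against the pooled signatures; when the same
source class carries different tracer values in different sub-watersheds,
pooling inflates source variance and biases the apportionment. `riverunmix`
instead stratifies sources by sub-watershed, unmixes each network node
against its *immediate* inputs — local source groups plus upstream nodes,
whose mixture samples act as pseudo-sources — and then *deconvolutes* the
node posteriors down the watershed DAG into ultimate-source contributions.
The pooled model is retained as a baseline for comparison.

It is written for catchment scientists doing source apportionment with
element concentrations (XRF) or δ¹³C fatty-acid tracers, but the machinery is
generic to any tracer mixture over a directed network.

## Model

At node *m* with sources *k = 1…K* and tracers *j = 1…J*, each mixture
sample *i* (with factor level ℓ(i): sediment type, season, …) is

```
Y_ij ~ Normal( Σ_k p′_kj^(ℓ(i)) · μ_kj ,  τ_j )          (residual-only error)
p′_kj = p_k c_kj / Σ_l p_l c_lj                           (concentration dependence)
p^(ℓ) ~ Dirichlet(α)           per factor level
μ_kj, σ_kj  ~ sources-only posterior given the source samples
τ_j ~ Uniform(0, 10 × empirical SD of tracer j)
```

Sampling is adaptive random-walk Metropolis on ILR-transformed proportions
and log τ, with source parameters redrawn from their closed-form posterior
every iteration; convergence is gated on the Gelman–Rubin R̂ (a fit is
rejected and retried with doubled chain length when more than 5% of monitored
variables exceed 1.05). Deconvolution chains the posterior proportions
draw-by-draw: the composite contribution of ultimate class *s* to node *m* is

```
composite_s(m) = Σ_i  q_i(m) · composite_s(i)
```

over the immediate inputs *i* of *m* (for a local group, the indicator of its
class) — e.g. with two tributaries, p(B→M2) = p_B1·p_M1 + p_B2 — so posterior
uncertainty propagates through the network. Tracer screening (range test,
one-way ANOVA with Tukey HSD, normality EDA) is included.

## Worked example

Fix each node's posterior at early-wet-season mean proportions for a
two-tributary confluence (M1, M2 → M3) and deconvolute:

```python
from riverunmix import WatershedGraph, deconvolute, summarize_composite, \
    render_apportionment_table, area_share
from riverunmix.mixing_model import PosteriorDraws

graph = WatershedGraph(
    nodes=["M1", "M2", "M3"],
    edges=[("M1", "M3"), ("M2", "M3")],
    local_sources={
        "M1": {"BLF": "BLF", "MF": "MF", "LL": "LL", "UP": "UP"},
        "M2": {"MF": "MF", "LL": "LL", "UP": "UP"},
        "M3": {},
    },
    classes=["BLF", "MF", "LL", "UP"],
    areas={"M1": 14.4, "M2": 1.00, "M3": 15.4},
)
posts = {
    "M1": PosteriorDraws.point_mass("M1", {"EW": {"BLF": 0.70, "MF": 0.19, "LL": 0.03, "UP": 0.08}}),
    "M2": PosteriorDraws.point_mass("M2", {"EW": {"MF": 0.75, "LL": 0.12, "UP": 0.13}}),
    "M3": PosteriorDraws.point_mass("M3", {"EW": {"M1": 0.74, "M2": 0.26}}),
}
comp = deconvolute(graph, posts, pairing_seed=1)
summary = summarize_composite(comp)
print(render_apportionment_table(summary[summary["node"] == "M3"]))
print(f"tributary share: {area_share(graph, 'M2', outlet='M3'):.1f}%")
```

prints

```
node      source        level     proportion
M3        BLF           EW        0.52 ± 0.00
M3        MF            EW        0.34 ± 0.00
M3        LL            EW        0.05 ± 0.00
M3        UP            EW        0.09 ± 0.00

tributary share: 6.5%
```

Broadleaf forest reaches the confluence only through the first tributary, so
its composite share is 0.70 × 0.74 = 0.518; mixed forest arrives through both
(0.19 × 0.74 + 0.75 × 0.26 = 0.3356, printed 0.34). The SDs are zero because
the inputs here are point masses; with full MCMC posteriors (see
`fit_network` → `deconvolute`) the composite draws carry the propagated
uncertainty. The 1.00 km² tributary is 6.5% of the 15.4 km² watershed —
the deconvolution shows a small area contributing a disproportionate ~26% of
the sediment.

For a full synthetic run from the shell:

```bash
unmix simulate --topology distributed --seed 1 --out bundle/
unmix run --mode deconv --network bundle/network.yaml --indir bundle/ \
    --seed 1 --test-profile --out results/
```

## Documentation

`docs/methods.md` describes the model assumptions, the sampler, the
synthetic-data generator and its limits, and the numerical choices.
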