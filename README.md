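# neighgrowth

Neighbourhood interactions shape how individual trees grow and how they
weather hot and dry years, but their net effect is hard to read off raw
census data: denser neighbourhoods crowd a tree, functionally *superior*
neighbours outcompete it, and functionally *dissimilar* neighbours may
partition resources with it. `neighgrowth` is a pipeline for
disentangling these channels in stem-mapped, repeatedly censused forest
plots, aimed at forest ecologists working with tropical census networks
(biennial censuses, all stems ≥ 10 cm DBH, species-level trait tables,
monthly climate series).

## What it computes

**Neighbourhood indices.** For each focal tree *i* at an interval start,
with neighbours *j* of species *k* within 10 m and w_j = DBH_j²/d_ij:

    NCI_i = Σ_j w_j                            (crowding, cm² m⁻¹)
    NIh_i = Σ_j w_j (trait_s − trait_k) / Σ_j w_j     (trait hierarchy)
    NId_i = Σ_j w_j |trait_s − trait_k| / Σ_j w_j     (trait dissimilarity)

NIh and NId are crowding-weighted *means* of trait differences, so they
measure neighbourhood composition independently of density. Unmeasured
neighbour species are gap-filled with plot-and-year community-weighted
mean traits; focal trees need ≥ 75% of their NCI from measured species.

**Climate anomalies.** Monthly T_max, VPD and CWD are z-scored against a
30-year monthly climatology and averaged over the 24 months before each
census (CA_t, in SD units; positive = more stress than usual).

**The growth model.** The z-scored log growth response y of tree *i*
(species *s*, plot *p*) is modelled as

    y ~ Normal(μ, σ²)
    μ = α_s + β1_s·size + β2_s·CA + β3_s·nci + β4_s·ni
      + β5_s·CA·nci + β6_s·CA·ni + γ_p + ε_i

with the species coefficient vectors (α_s, β1s..β6s) ~ MVN((α, β1..β6), S)
— correlated species-level responses around community means — and Gaussian
plot (γ_p) and individual (ε_i) intercepts. The posterior is drawn by a
blocked Gibbs sampler built for this conjugate hierarchy (4 chains × 3000
iterations, 1500 warmup, split-Rhat ≤ 1.05 gate). Effects are summarised
by posterior medians and 95%/90% highest posterior density intervals:
*clear* when the 95% HPDI excludes zero, a *trend* when only the 90% one
does. A full analysis crosses {hierarchy, dissimilarity} × {T_max, VPD,
CWD} × 9 traits = 54 models.

A synthetic-data module generates stem maps, trait tables and seasonal
climate, and forward-simulates growth from the same model with known
hyperparameters, so the entire pipeline is testable against ground truth.

## Worked example

Simulate the default synthetic conditions (two ~1.2 ha plots, 20 species,
five biennial intervals, ≈7 500 growth observations) and fit one model
configuration:

```python
import numpy as np
import neighgrowth as ng
from neighgrowth.experiments import simulate_and_fit
from neighgrowth.summary import bayes_r2, summarize_community

truth = ng.SimulationTruth()          # crowding hurts, dissimilarity helps
fit, data, _ = simulate_and_fit(truth, seed=1)
print(summarize_community(fit).round(3).to_string(index=False))
print("conditional R2:", round(float(np.median(bayes_r2(fit, data, "conditional"))), 3))
print("marginal    R2:", round(float(np.median(bayes_r2(fit, data, "marginal"))), 3))
```

```
parameter  median  hpdi95_lo  hpdi95_hi  hpdi90_lo  hpdi90_hi classification
    alpha  -0.117     -0.646      0.364     -0.498      0.315        unclear
    beta1   0.257      0.194      0.330      0.201      0.312 clear_positive
    beta2  -0.128     -0.213     -0.053     -0.191     -0.056 clear_negative
    beta3  -0.491     -0.552     -0.435     -0.546     -0.447 clear_negative
    beta4   0.130      0.058      0.200      0.068      0.189 clear_positive
    beta5   0.232      0.154      0.311      0.168      0.300 clear_positive
    beta6   0.039     -0.045      0.118     -0.033      0.104        unclear
conditional R2: 0.553
marginal    R2: 0.374
```

The fit reads the simulation back correctly: growth declines clearly with
crowding (β3 < 0) and with climate stress (β2 < 0), rises with size (β1)
and with trait dissimilarity (β4), crowding buffers the climate effect
(β5 > 0), and the intrinsic-growth intercept α is (as always with three
additive intercept layers) the least certain quantity. Conditional R²
(fixed + group terms) exceeds marginal R² (fixed terms only) because plot
and individual intercepts absorb real variance.

The same steps run from the shell via the `neighgrowth` CLI
(`simulate`, `growth`, `anomalies`, `indices`, `fit`, `summarize`,
`grid`); see `neighgrowth --help`.

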