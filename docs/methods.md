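# Methods

## Scope

`neighgrowth` implements an analysis pipeline for individual tree growth in
stem-mapped tropical forest plots: how neighbourhood crowding, trait
hierarchies and trait dissimilarities between a focal tree and its
neighbours modulate diameter growth and its response to climate anomalies.
Because the method is meant to be validated without field data, the package
ships a synthetic-stand generator that forward-simulates growth from the
very model the pipeline fits, so every stage can be checked against known
ground truth.

## Growth observations

Annualised absolute diameter growth is AGR = (DBH_t − DBH_{t−2}) / 2 in
cm yr⁻¹, computed per tree for consecutive biennial censuses where the tree
is alive at both ends. Quality control removes AGR outside a configurable
window, by default [−0.2, 4.0] cm yr⁻¹ — a conventional tropical-census
bound that tolerates shrinkage within tape-measurement error and rejects
implausible spurts; both bounds are plain configuration, not constants.

The model response is a z-score of log(AGR + a). The shift
a = max(0, −min AGR) + 0.1 is computed on the filtered data so the smallest
observation has log-argument exactly 0.1 cm yr⁻¹. We log first and then
centre/scale: centring before the logarithm could produce non-positive
arguments. The fitted shift, mean and SD are stored, making the transform
exactly invertible (the simulator relies on this). Zero-variance inputs
standardise with SD := 1 to keep the map total.

Tree size enters as the z-score (across all observations) of
within-species-centred log DBH at the interval start; a species observed
once centres to zero.

## Climate anomalies

Monthly series of T_max (°C), VPD (kPa) and CWD (mm; deficit-positive, so
larger anomaly = more water stress) are standardised per calendar month
against a baseline climatology (default 1991–2021, sample SD with n − 1).
The interval anomaly CA_t is the arithmetic mean of the 24 standardised
months preceding census t. Censuses are assigned to December of the census
year, so the window is Jan(t−1)–Dec(t); the census month is configurable
because field campaigns rarely fall exactly at year end. Biennial censuses
from 1991 to 2021 give 15 intervals ending 1993, …, 2021.

## Neighbourhood indices

For focal tree *i* with neighbours *j* (species *k*) inside a closed 10 m
ball in the same plot, with w_j = DBH_j²/d_ij:

* NCI_i = Σ_j w_j (cm² m⁻¹),
* NIh_i = Σ_j w_j λ_{s,k} / Σ_j w_j with λ_{s,k} = trait_s − trait_k,
* NId_i = Σ_j w_j |λ_{s,k}| / Σ_j w_j.

NIh and NId are crowding-weighted means, hence bounded by the trait range,
satisfy |NIh| ≤ NId, and are invariant to duplicating the neighbourhood —
they measure composition, not density. Distances are clamped below at
0.5 m before division (stem coordinates have 0.5 m precision and may
coincide). Focal trees within 10 m of a plot border are excluded (their
ball is censored, which would bias NCI downward) while border trees still
count as neighbours; neighbour searches never cross plot boundaries.

Species without trait measurements are gap-filled per plot and census with
the community-weighted mean trait of measured species' stems, weighted by
summed squared DBH (basal-area proxy; stem-count weighting is available).
Focal trees are retained only when measured species contribute at least
75% of their NCI and the focal species is itself measured; gap-filled
species never count toward coverage.

## The hierarchical growth model

The transformed response y_i of tree *i* (species *s*, plot *p*) is

    y_i ~ Normal(μ_i, σ²)
    μ_i = α_s + β1_s·size + β2_s·CA + β3_s·nci + β4_s·ni
        + β5_s·CA·nci + β6_s·CA·ni + γ_p + ε_tree(i)

where `nci` is the z-score of log(NCI + 1) (the +1 cm² m⁻¹ admits isolated
trees), `ni` the z-score of the chosen NIh/NId column (signed, so it is
standardised but not logged), CA is used raw (already in SD units), and
interactions are products of the standardised parents. The 7-vector
(α_s, β1s..β6s) is multivariate normal around community means with
covariance S, sharing information across species; γ_p and ε_i are Gaussian
plot and individual intercepts, ε_i being constant across a tree's
repeated intervals (which is what identifies it).

### Sampling

Every layer of this model is conditionally Gaussian, and the variance
components conditionally inverse-gamma / inverse-Wishart, so the posterior
is drawn with a **blocked Gibbs sampler** written for exactly this
structure: species coefficient vectors (7-dim Gaussian blocks), community
means, S (inverse-Wishart), plot and individual intercepts, and the three
variances, each from its exact full conditional. Priors are the conjugate
weakly-informative family for a standardised design: Normal(0, 1) on the
seven community coefficients, inverse-Wishart(df = 9, scale = 0.04·I₇) on
S (prior mean 0.2² per coefficient), inverse-gamma(2, 0.25) on σ², σ_plot²
and σ_indiv². All are constructor arguments.

The additive intercept layers (species intercepts, plot intercepts,
individual effects) leave near-flat directions that plain Gibbs traverses
slowly. The sampler therefore adds translation moves along those
directions — per-species shifts between a species' intercept and its
trees' individual effects, a global shift between plot intercepts and the
species-intercept layer plus its community mean, and per-plot shifts
between a plot's intercept and its trees' effects — each drawn from its
Gaussian full conditional, so the chain remains exact. These moves play
the role that non-centred parameterisations play for gradient-based
samplers.

Defaults follow the standard protocol: 4 chains × 3000 iterations (1500
warmup) from overdispersed starts, convergence gated at split-Rhat ≤ 1.05
(computed with arviz); fits failing the gate are flagged and excluded from
grid collation. Exact full-conditional draws cannot diverge, so the
divergence count in the diagnostics is structurally zero.

### Summaries

Parameters are summarised by the posterior median and highest posterior
density intervals computed by the sorted-window scan (shortest contiguous
interval holding ⌈mass·n⌉ draws). A slope is a *clear* effect when its
95% HPDI excludes zero, a *trend* when only its 90% HPDI does, otherwise
unclear. Finite-sample HPD windows at two masses are scanned
independently, so strict nesting of the 90% inside the 95% interval holds
only up to draw-level jitter.

Bayesian R² is computed per draw as var(pred)/(var(pred) + residual
terms): conditional predictions include γ_p and ε_i with only σ² in the
denominator; marginal predictions drop the group terms and add σ_plot² +
σ_indiv² to the denominator. Species deviations are draws of (species −
community) coefficients, flagged when the 95% HPDI excludes zero.
Diagnostic Pearson correlations cover NCI vs each NIh/NId, NId vs the
conspecific share of NCI, and focal-species trait values vs species-level
responses. Residual spatial structure is checked with Moran's I per plot
(inverse-distance weights within 30 m, two-sided permutation p-value with
999 seeded shuffles, plots under 10 locations skipped).

### The model grid

A full analysis crosses {hierarchy, dissimilarity} × {T_max, VPD, CWD} ×
9 traits = 54 configurations, enumerated in stable (family, climate,
trait) order with per-configuration seeds derived as base_seed + position.
Failed or non-converged cells are recorded and skipped, never fatal.

## Synthetic stands

The generator emulates a lowland tropical plot network. Defaults, chosen
once as the package's standard validation conditions: two square 110 m
plots (~1.2 ha each) at 625 stems ha⁻¹ (≈1 500 stems ≥ 10 cm DBH), 20
species with geometric rank-abundance (ratio 0.9), DBH truncated
log-normal (log-median ≈ 18 cm, σ = 0.5, inverse-CDF truncation at 10 cm),
positions i.i.d. uniform per plot. Trait tables are drawn from a latent
multivariate normal and back-transformed to each trait's support
(moment-matched log-normals for the positive traits, negated log-normal
for π_tlp, plain normal for δ13C) around field-realistic means. Climate is
a 12-month seasonal climatology (3-month dry season with elevated T_max,
VPD and CWD) plus stationary AR(1) standardised anomalies (lag-1
coefficient 0.6, unit stationary SD).

Growth is forward-simulated from the model above with default truth
α = −0.1, β = (0.3, −0.2, −0.4, 0.1, 0.15, 0.1), S = 0.15²·I₇, σ = 0.6,
σ_plot = 0.1, σ_indiv = 0.3 — a regime with negative crowding, positive
dissimilarity and negative climate effects. Each interval recomputes CA
and the indices with the package's own modules, standardises covariates
with reference constants frozen at the first census, draws the response,
inverts the fixed response transform (AGR = exp(response − 1.5) − 0.1) and
advances DBH by two years of growth, floored at zero so log-size stays
defined. The population is closed: no recruitment, mortality, or
intraspecific trait variation, and positions are unclustered — so passing
recovery tests demonstrates correctness of the machinery under the model's
own assumptions, not robustness to the spatial aggregation, demographic
turnover or measurement idiosyncrasies of real censuses. An optional
switch rounds DBH to the grid implied by 0.5 cm circumference precision.

## Validation experiments

* **Index oracle** — twenty seeded ~1000-tree stands; KD-tree indices
  equal a dense O(n²) recomputation to better than 1e−9 relative, with
  |NIh| ≤ NId everywhere.
* **Parameter recovery** — ten replicates of the default conditions
  (fresh stand, traits, climate, species coefficients and noise each
  time), fitted with 4 chains × 600 iterations (300 warmup) — a
  deliberately scaled-down protocol that the translation moves make
  adequate here — on the design recorded by the simulator, i.e. the
  covariates the true coefficients actually multiplied. Measured:
  empirical coverage of the 95% HPDIs for β1..β6 (expected in
  [0.85, 1.0]) and posterior-mean bias of the crowding slope β3
  (expected < 0.05 response-SD).
* **Null control** — same protocol with all community slopes zero and
  S = 0.05²·I₇: the rate of spurious "clear" classifications across
  replicates stays at or below 10%.

The recovery fit uses the stored design rather than re-deriving covariates
through the census pipeline because the pipeline re-standardises with its
own sample statistics — a slightly different affine map than the
simulator's frozen reference scaling; recovery is defined against the
design the truth multiplied. The end-to-end path is validated separately
by exactness tests (noise-free simulation reproduces α_s; recomputed NCI
matches the stored covariate).

One caveat surfaced by the recovery harness: tree size is a lagged outcome
(DBH accumulates past growth, which contains ε_i and the residuals), so
the size slope β1 is estimated under mild dynamic-panel feedback. Across
replicates this produces no systematic bias at the default conditions, but
individual replicates can show deviations larger than the posterior SD
suggests; coverage targets are therefore stated over replicates, not per
fit.

## Numerical choices

* Closed-ball neighbour inclusion (ties at exactly the radius are in).
* Sample SDs use ddof = 1 throughout; z-scores of zero-variance vectors
  use SD := 1.
* log(NCI + 1) rather than log(NCI) so isolated trees stay in the design;
  isolated trees get NIh = NId = 0 (neutral neighbourhood) in the
  simulator and missing values (with a logged count) in the index tables.
* Sigma draws use an eigenvalue square root, tolerating singular
  covariance truths.
* Per-chain RNG streams are spawned from a single seed; identical seeds
  give bit-identical draws.

## Known limitations

* With two plots the plot-variance σ_plot² is prior-dominated; it is a
  nuisance layer here, not an estimand.
* The Gibbs sampler is specific to the conjugate prior family; swapping
  in, say, half-t scale priors would require a different kernel for those
  blocks.
* Conditional R² requires the stored individual-effect draws
  (`store_epsilon=True`, the default); storage grows with trees × draws.
* The coverage rule counts only measured species; if gap-filled
  conspecifics should count as "available trait information" the coverage
  threshold must be reinterpreted by the caller.
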