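# Methods

## Model formulation

`coevodyn` simulates a discrete, non-overlapping-generation
host–parasitoid association in which ecology and evolution are
coupled. The ecological skeleton is a host map with Beverton–Holt
style self-limitation and a negative-binomial escape function, and a
parasitoid recruitment map; the evolutionary layer moves each
species' population-mean quantitative character up its own
log-fitness gradient each generation, scaled by a constant additive
genetic variance (AGV, Γ).

Host and single parasitoid:

    N[t+1] = λ_t N g{N} (α + (1−α) f{N,P})
    P[t+1] = c N g{N} (1−α) (1−f{N,P})

    g{N} = 1 / (1 + N (λ_t − 1)/K)
    f{N,P} = [1 + aP / (κ (1 + a N g (1−α)/η_t))]^(−κ)
    α = 1 − exp(−(n̄ − p̄)²)
    λ_t = max(λ* − C_n n̄, ε),   η_t = max(η* − C_p p̄, ε)

    n̄[t+1] = n̄ + Γ_n ∂lnW_n/∂n̄,   p̄[t+1] = p̄ + Γ_p ∂lnW_p/∂p̄,
    W_n = N[t+1]/N[t],  W_p = P[t+1]/P[t]

The escape function encodes spatially aggregated attacks (small κ =
clumped parasitism) with a type-II saturating per-female attack rate
capped by η. Resistance is a matching trait: only the squared gap
between host and parasitoid characters matters, so resistance is
symmetric in the sign of the gap and invariant under a joint shift of
both characters. Costs are linear deductions from the cost-free
intrinsic rates and are floored at `rate_floor` (default 1e−9) rather
than allowed to go negative.

With two parasitoids (characters p̄ and ȳ, escape functions f and h,
per-parasitoid resistant proportions α_p and α_y sharing the single
host character):

    N[t+1] = λ_t N g (α_p + (1−α_p) f)(α_y + (1−α_y) h)
    P[t+1] = c_p N g (1−α_p)(1−f) h
    Y[t+1] = c_y N g (1−α_y)(1−h) f

Parasitoids cannot multiparasitise: each recruits only from hosts the
competitor missed, so a parasitoid's realised parasitism rate —
reported as the proportion of *all* hosts it infects,
(1−α_i)(1−f_i)·∏_{j≠i} f_j — sums with its competitor's to the total
infected fraction.

Assumptions inherited from this model family: no explicit genetics
(no alleles, dominance or gene frequencies — only mean characters);
selection weak enough that each AGV is constant through time; no
spatial structure; no competitive hierarchy between parasitoids.

## Numerical scheme

**Synchronous update.** Densities and characters at t+1 are all
computed from the generation-t state; gradients are evaluated before
anything moves.

**Gradients.** Selection gradients are central finite differences
(default step h = 1e−5 character units) of the composed one-step
log-fitness. When a character is perturbed, the costs, the resistant
proportions and the escape functions are re-evaluated; the
density-dependence factor g{N} is held frozen as a property of the
current densities. This convention makes the parasitism-free host
gradient exactly the analytic −C_n/λ_t, and the test suite checks the
generic case against a symbolically derived gradient to 1e−6.
Central differences were chosen over a closed form because the
α-inside-f composition makes the analytic expression error-prone; the
closed form lives in the tests as an independent oracle instead.

**Extinction.** Densities below `extinction_threshold` (default 1e−6
m⁻², i.e. one individual per 10⁶ m²) are set to exactly 0 and an
event is recorded; an absent species' character is frozen. The
continuous map never reaches literal zero on its own, so some
threshold is required for "extinct" to be a reportable outcome.

**Character bounds.** By default the characters are unbounded reals.
This variant has a structural quirk worth documenting: because the
costs are linear, *lowering* a character is always profitable, so
once a host–parasitoid pair's gap flips sign the pair co-drifts
downward indefinitely (and at high λ* it first escalates upward until
the host's cost binds). All rates stay well-defined — they depend
only on the character *gap* — but there is no character equilibrium.
For the two-parasitoid introduction experiments this matters: a
resident pair that has drifted far from the introduction character
leaves any invader facing α numerically equal to 1 and therefore zero
recruitment. Setting `character_floor = 0` treats the characters as
non-negative investment traits (zero investment = no resistance
machinery); the floored variant has genuine character equilibria, and
the introduction experiments run it by default. The sweep,
sensitivity and prediction stages run the unbounded variant, whose
gap dynamics are unaffected by the common drift on their 300-generation
horizon.

**Introduction protocol.** A second parasitoid enters at its
`introduction_generation` with density P0. In the introduction
experiments it inherits the resident parasitoid's current mean
character (`inherit_character=True`): the scenario models releasing a
new *strain* of an established parasitoid species, which shares the
species' counter-adaptation machinery. For an asexual resident the
inherited value equals the original p0, so the distinction only
matters when the resident has been evolving.

## Parameters and the documented baseline

Life-history values for the two study systems — the Argentine stem
weevil with its thelytokous braconid parasitoid, and the lucerne
weevil with its sexually reproducing one — ship as a packaged CSV
(`coevodyn/data/system_parameters.csv`) together with the ranges used
for the sensitivity analysis. Unmeasured entries are handled as
follows: parasitoid larval survival c and searching efficiency a are
only measured in the first system (0.92 and 4.14 m²·generation⁻¹) and
are assumed shared; an unassigned cost coefficient is taken as 0 (for
the asexual parasitoid the character never moves, so C_p only shifts
η_t by a constant).

The sweep and introduction experiments need every parameter pinned.
The baseline fixes the first system's tabulated point values (K = 720,
η* = 42, c = 0.92, a = 4.14, C_n = C_p = 1, N₀ = K, P₀ = 10, n₀ = 1,
p₀ = 0.9, Γ_n = 0.01) and calibrates the two range-only parameters
inside their measured ranges: host growth rate λ* = 13 (range 1–18)
and parasitism aggregation κ. No single κ reproduces both published
experiment families, so each family documents its own value within
the measured range 0.23–0.87:

* κ = 0.30 for the AGV-ratio sweep: an asexual parasitoid ends near
  7% parasitism at generation 300 and any parasitoid with AGV above
  ~0.03 holds ~73%;
* κ = 0.42 for the introduction experiments: the asexual-then-sexual
  rescue stabilises at 0.48, the sexual-resident recovery after a
  failed asexual invasion reaches 0.82, and equal-AGV pairs coexist
  at 0.22 each.

The κ tension is itself informative: the plateau parasitism of a
well-matched parasitoid rises with κ, while the post-invasion
recovery level requires stronger aggregation; the published numbers
appear to come from separately pinned scripts. Two further outcomes
do not reproduce under any parameter set we scanned (λ ∈ 6–18,
κ ∈ 0.23–0.87, η ∈ 20–64): the scenario "asexual resident, strong
sexual invader (AGV 0.1)" is bistable between a ~0.48 and a ~0.82
final parasitism branch with nothing in between, and the doubled-η
asexual invader released against a strongly sexual resident (AGV 0.1)
coexists at low density rather than dying out. Both are reported as
the model computes them.

In the three-species runs an asexual line (Γ = 0) is credited with a
doubled intrinsic attack rate: an all-female clonal brood attacks
twice as effectively as a sexual line with a 1:1 sex ratio.

## Sensitivity analysis

`run_sensitivity` draws a Latin hypercube (scipy's sampler: exactly
one draw per equal-probability stratum per column, strata permuted
per column, deterministic under the seed) of 6000 parameter sets over
the 13 tabulated analysis ranges — searching efficiency a is held at
its measured 4.14 — runs the two-species model to generation 300 per
row with a vectorised kernel that is bit-for-bit identical to the
scalar simulator (asserted in the tests), and computes partial rank
correlation coefficients (PRCC) between each input and the resistant
proportion α at generation 300.

The PRCC is computed from the precision matrix of the rank
correlation matrix, which is algebraically the residual-regression
definition (correlate the rank residuals of parameter j and of the
response after removing all other ranked parameters); the tests pin
the equivalence to 1e−10 against an explicit residual-regression
oracle. A perfectly rank-correlated column makes the matrix singular,
in which case the residual route is used directly. P-values use the
partial-correlation t-transform, t = r √(df/(1−r²)) with
df = n − k − 1; confidence intervals are percentile bootstrap over 50
row-resamples (95% level), widened if needed to contain the
full-sample estimate. Rows whose host goes extinct before generation
300 keep the last defined α (characters freeze at extinction), so
they remain in the design rather than biasing the λ association.

The reproduced coefficients have the published sign pattern and
near-identical ranking (host AGV ≈ +0.77, parasitoid AGV ≈ −0.79,
κ ≈ +0.58, λ ≈ −0.28); the magnitudes run systematically ~0.05–0.09
above the published 0.73/−0.71/0.49/−0.20, consistent with a less
noisy response surface than the original implementation.

## System predictions and the field comparison

`system_prediction` parameterises the two-species model from one
study system's column: point values are used as-is, range-valued
parameters (λ, η, κ for the first system; λ for the second) get one
independent uniform draw per parameter per set, 20 sets by default.
Each set is simulated and the parasitism rate is read at year ×
generations-per-year (3 per year for the Argentine stem weevil, 1 for
the lucerne weevil). Predictions are distributions over parameter
uncertainty, not over demographic noise (the model is deterministic).
The asexual system declines toward a mean parasitism near 0.07–0.11
at 100 years depending on the draw (low-λ draws collapse the host
and contribute zeros); the sexual system holds a flat ~0.37 from
year 3 to year 100.

`compare_model_to_field` takes two vectors of parasitism proportions,
screens each for normality (Shapiro–Wilk, reported not enforced),
runs a two-sided F-test of variance equality, and then a two-sample
t-test — pooled-variance Student's by default, Welch's modification
to the degrees of freedom when the F-test rejects at the configured
level (0.05).

## Synthetic field data

No field dataset ships with the package; `generate_field_data`
produces a synthetic stand-in for site-by-year parasitism
observations. Site-level true rates are beta-distributed around a
chosen mean with intraclass correlation ρ (the fraction of
observed-proportion variance contributed by between-site spread), and
observed proportions are binomial draws over the number of dissected
hosts per site. This captures the overdispersion of real parasitism
surveys but none of their spatial or temporal autocorrelation,
observer effects, or year-to-year environmental covariance — so tests
built on it validate the comparison *machinery* (type-I error ≈ 0.05
on matched data, power > 0.8 at a 0.2 absolute separation with 20
sites per group), not conclusions about any real system.

## Problem sizes and determinism

Default problem sizes: 300 generations for two-species endpoints and
sensitivity responses, 500 + 1500 generations for introduction
experiments, 6000 Latin hypercube samples with 50 bootstrap
resamples, 20 parameter draws per system prediction. Every stochastic
stage (LHS, bootstrap, parameter draws, synthetic data) takes an
explicit seed and is reproducible bit-for-bit under it; the
simulators themselves are deterministic.

## Known limitations

* The unbounded-character variant has no character equilibrium (see
  above); long unbounded runs are meaningful only through gap-
  dependent observables.
* Mean-character dynamics only: no evolving variance, no mutation, no
  trait distributions, no demographic stochasticity.
* The model's asexual line is an extreme (Γ = 0); real thelytokous
  populations accrue some variation by mutation.
* The two-parasitoid model assumes strains identical up to Γ and η;
  it cannot speak to multi-species complexes with different searching
  behaviour.
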