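# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.

## Mixing model

**Likelihood.** For consumer j with diet p_j on the K-simplex and tracers
i ∈ {δ13C, δ15N},

    x_ij ~ Normal( Σ_k p_jk (μ_ik + λ_i),  Σ_k p_jk² (σ_ik² + τ_i²) ).

Source moments (μ_ik, σ_ik) are plug-in sample statistics from the prey
table; they are not hierarchically re-estimated.  TDF uncertainty enters
only through τ² in the variance.  This is the "process error only"
formulation: all residual scatter is attributed to source/TDF variability,
with no separate residual term and no elemental-concentration weighting of
sources.  Consequence worth knowing: the likelihood variance shrinks as p
approaches a vertex (Σ p² → 1 still leaves only one source's σ²), and grows
nowhere else; a consumer's analytical error (≈0.1‰) is not in the model, a
deliberate simplification that slightly understates variance.

**Structure and priors.** Diets are parameterised by ILR coordinates with a
fixed orthonormal Helmert basis in source-list order (basis choice is
unobservable; results are reported on the simplex).  Group g has
coordinates θ_g; the prior on θ_g is the Dirichlet(α) density times the ILR
Jacobian (log form Σ_k α_k log p_k), so the induced prior on the group diet
is exactly Dirichlet(α); α defaults to all ones (flat).  Individuals are
nested in groups: u_j ~ N(0, σ²I_{K−1}) in ILR space, with a half-normal
prior on σ (scale 2 ILR units by default — weakly informative: σ = 2 allows
order-of-magnitude part ratios between individuals of one group).  Repeated
individual ids share one deviation, which is how resampled individuals are
handled.

**Sampler.** Adaptive random-walk Metropolis in three blocks per iteration,
vectorised across chains:

1. all individual deviations in parallel (valid as a set of independent
   MH updates because, given θ and σ, both likelihood and prior factorise
   over individuals) — in the *non-centred* parameterisation u = σ·w,
   w ~ N(0,1), which avoids the funnel when the RE variance is small;
2. each group's θ_g jointly;
3. log σ, whose update re-evaluates the full likelihood since σ scales all
   deviations.

Step sizes adapt per block toward ~30% acceptance with a Robbins–Monro
schedule during burn-in only; the retained draws come from a fixed kernel.
Initial states are overdispersed (group diets drawn from the prior).
Defaults for desk-scale work: 3 chains × 20 000 iterations, burn-in 10 000,
thin 10 (3 000 retained draws).  A long `"extreme"` preset
(3 000 000/1 500 000/500) mirrors the longest conventional run length of
standard mixing-model software; nothing in the test suite needs it.

**Diagnostics.** Split-chain Gelman–Rubin R̂ per group-level proportion and
for σ, with the convergence gate R̂ < 1.1, plus per-chain Geweke z
(first 10% vs last 50%, spectral density at zero via a Bartlett lag window
of ⌊√n⌋ lags; |z| < 1.96 passes).  The R̂ estimator used is
R̂ = √((W + B/n)/W): its floor is exactly 1 when all split halves agree and
it is ≥ 1 by construction, at the cost of being (1/2n)-conservative
relative to the (n−1)/n-shrunk textbook variant — a difference far below
the 1.1 gate.  A constant parameter is degenerate and reports R̂ = 1;
non-convergence is flagged, never raised, and draws are always returned.

**Identifiability.** With two tracers, mixtures of K sources are point-
identified only for K ≤ 3; beyond that the posterior is the prior restricted
to a feasible polytope slice, and its mean sits near the slice centroid
rather than at any particular vertex of explanation.  Sources with
identical tracer distributions are detected and flagged (only their sum is
identifiable).  Parameter-recovery claims in the tests are therefore made
at K = 3; at K = 6 the package reports honest posterior spread (and the
posterior correlation matrix between sources) instead of false precision.

## Specialization index

Ɛ(p) = ‖p − g‖₂ / ‖v − g‖₂ with g the equal-proportion vector and v any
vertex; the normaliser √((K−1)/K) is the unique scaling that maps a
single-source diet to exactly 1 (computed through the same floating-point
path as the numerator so the vertex value is exact).  Ɛ is computed per
posterior draw and summarised (mean ± SD); Ɛ of the posterior-mean diet is
also reported — by convexity it is never larger than the per-draw mean, and
the gap grows with posterior spread, so the two together are a useful
dispersion diagnostic.  K is the number of sources entering that period's
model; Ɛ values computed at different K are not comparable.

Classification bands default to: generalist Ɛ ≤ 0.34,
specialist-generalist 0.34 < Ɛ ≤ 0.6, specialist Ɛ > 0.6, with boundary
values assigned to the lower-specialization class.  The literature is not
consistent about such cut-offs; the thresholds are plain configuration.

## Permutational statistics

PERMANOVA uses the squared-distance partition SS_total = (1/N)Σ_{i<j}d²,
SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d², pseudo-F = (SS_A/df_A)/(SS_W/df_W).
On 1-D Euclidean data this reduces exactly to the classical one-way ANOVA F
(used as a test oracle).  When the number of distinct relabelings is at
most the requested permutation count the permutation distribution is
enumerated exactly (p = #{F* ≥ F}/total); otherwise p = (1 + #{F* ≥ F})/(1 + B),
which cannot be zero.  The two-factor variant uses Gower-centred
inner products, sum-to-zero coding and partial (Type III-style) SS with
free permutation of raw observations — the simplest defensible scheme;
permutation of residuals is out of scope.

SIMPER defaults to the squared-difference decomposition (contribution of
variable v = mean over between-group pairs of (x_iv − x_jv)², which sums
exactly to the mean squared Euclidean distance), consistent with
Euclidean-distance PERMANOVA; classical Bray–Curtis decomposition is
available behind `mode="bray_curtis"`.  Benjamini–Yekutieli adjustment
delegates to statsmodels and is unit-tested against the step-up formula.

Prey merging: two (species, region) units merge iff their BY-adjusted
pairwise p exceeds α *and* they share an ecology guild tag; components are
formed by single linkage over this relation, and any transitive conflict is
logged.  Region splits survive automatically whenever the between-region
test is significant.

## Clustering

Ward linkage on z-standardised (δ13C, δ15N); k selected by the Dunn index
(min between-cluster point distance / max within-cluster diameter) over
k ∈ [2, 6], ties to the smallest k; all-singleton partitions (infinite
Dunn) are excluded.  A best Dunn below 1 flags the solution as weakly
separated rather than failing — overlapping groups are a property of the
data, and the flag propagates into the pipeline report.  Leave-one-out LDA
accuracy validates the chosen partition (skipped with a warning when a
cluster is a singleton).  The Dunn index is nearest-point based and is
genuinely unstable on overlapping Gaussian groups; this is reported, not
hidden (see Limitations).

## Tracer preparation

δX = (R_sample/R_standard − 1) × 1000.  Correction coefficients for
lipid-extraction (δ15N) and DMSO preservation (both tracers) are *not*
hard-coded: published values are tissue- and study-specific, so they are
config inputs (offset and optional slope per tracer per effect; both
additive and regression forms supported), defaulting to zero offsets with a
loud warning.  The fish lipid correction is conventionally reused for
zooplankton, whose C:N ratios are comparable.  Corrections are applied at
most once per effect (idempotence guard on a provenance flag).  The 39-name
extended-dietary FA list ships as an editable data file; FA subset
selection zero-fills missing FAs (counting them) and renormalises to 100,
preserving within-subset ratios.

## Synthetic data

The generators emulate exactly the structure the analysis assumes: prey
isotope values are per-source bivariate normals (tracers independent by
default — the reference prey table prints no covariances; a covariance slot
exists and defaults to 0); consumer values are exact mixture draws with
variance Σp²(σ²+τ²) + process² + analytical² (process noise additive on the
mixture variance, matching the fitted likelihood; analytical SDs default
0.11/0.12‰); FA profiles are Dirichlet draws scaled to mass percent.
Sampling dates are uniform within a June–November feeding-season window of
the record's period; no within-season trend is imposed.

The `regime_shift` scenario is parameterised from the published prey table
of the St. Lawrence system: ten (species, region) specs pooled by exact
moment pooling into the six functional groups the original study fixed
(Arctic krill + copepods; northern krill; capelin/herring Estuary;
capelin/herring Gulf; amphipods; sandlance).  The prey table is generated
at the functional-group level so that the data-driven aggregation stage
reproduces those six groups; this is deliberate, because the printed
species-level summaries place capelin and herring (Estuary) ~0.8‰ apart in
δ13C — far enough that any fresh two-sample test would separate them — so a
purely statistical re-merge at species level cannot reproduce the study's
grouping (which also leaned on ecological similarity).  Species-level specs
remain available (`table1_species_specs`).  Five planted diet groups sized
to a 99-consumer study (pre: 12/27/6, post: 22/32) mimic the published
group structure loosely: a pre-period krill-specialist group (89% Arctic
krill/copepods, Ɛ ≈ 0.87), a specialist-generalist majority (Ɛ ≈ 0.49), a
pelagic-fish group (Ɛ ≈ 0.64), and post-period zooplankton
specialist-generalist (Ɛ ≈ 0.53) and true-generalist (Ɛ ≈ 0.11) groups.
Additional process noise is 0.2‰ per tracer — a modest allowance for
tissue-level variation beyond source/TDF scatter.  The scenario is
illustrative of the study system, not ground truth for it.

What passing tests on these data do **not** show: robustness to skewed or
covarying source distributions, to seasonal tissue-turnover dynamics, to
preservation artefacts beyond additive/linear shifts, or to prey tables
whose printed summaries misstate the raw data.

## Pipeline

Stage order: corrections → prey aggregation → period split (boundary date
2002-01-01 by default; records on the boundary fall in the later period) →
Ward/Dunn clustering within period → mixing model per period with clusters
as the fixed effect and individuals as random effects (a `--joint` option
fits one model across periods) → Ɛ → report.  All stage seeds derive from
one run seed via `SeedSequence.spawn`; every artifact embeds a fingerprint
(SHA-256 prefix of the resolved config); reports regenerate byte-identically
from the same config and seed.  Row counts are reconciled (no silent
drops), and warnings (null corrections, low Dunn, skipped LDA,
non-convergence) surface in the report.  Posterior draws are written to
disk only on request (`write_posterior`) — they are bulky; summaries,
convergence and Ɛ tables are always persisted.

## Numerical choices and degenerate inputs

- Permutation p-values use the (1+count)/(1+B) estimator; exact enumeration
  includes the identity relabeling in both numerator and denominator.
- Zero mixture variance with an off-mean observation yields −∞ log
  likelihood with a warning; at the mean the tracer contributes 0.
- A single-source model returns the point posterior p = (1) for every draw.
- Constant data are rejected by PERMANOVA; singleton groups are rejected;
  all-singleton partitions are excluded from Dunn selection.
- ILR inverse uses a max-subtracted softmax; Dirichlet prior evaluation
  clips p at 1e-300 before logs.
- LDA falls back to a ridge-regularised solver (logged ε) on a singular
  within-class covariance.

## Problem sizes used by the test suite

Desk-scale sizes keep the full suite fast while preserving the statistical
content: the K=3 recovery run uses 30 consumers and 3 × 20 000 iterations;
interval-coverage calibration uses 100 replicates at 3 × 3 000 iterations;
type-I calibration uses 1 000 simulated null datasets at 499 permutations;
the end-to-end scenario runs the full 99-consumer design with the default
desk preset.  These sizes are the package's recommended defaults for
simulation studies of this kind; production analyses of real data should
scale chain lengths up (e.g. the `"extreme"` preset) and confirm R̂.

## Known limitations

- Two tracers identify at most three sources pointwise; six-source diets
  are reported with honest (large) posterior spread, and mid-simplex diets
  whose mixture lands near another source's signature (here: pooled
  sandlance lies almost exactly on the Arctic-krill/copepods ↔
  capelin/herring-Estuary segment after TDF shift) cannot be point-recovered
  from isotopes alone.
- Dunn-index k selection is unreliable when groups overlap at ~1–2 pooled
  SDs, which is exactly the regime the planted two-period design produces;
  the `low_dunn` flag marks this.
- The Geweke spectral estimator uses a simple Bartlett window; on strongly
  autocorrelated chains it is noisy and individual |z| excursions above
  1.96 occur; R̂ is the convergence gate.
- No QFASA-style quantitative FA diet estimation (calibration coefficients
  for blubber are not established); FA analyses here are comparative only.
- No seasonal/long-term smooth trend modelling, ordination graphics, or
  mixed-model covariate tests; those belong to general-purpose packages.
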