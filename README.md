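# trophoniche

Dietary-niche inference for large marine predators from two stable-isotope
tracers (δ13C, δ15N) and fatty-acid (FA) signatures.

The package is aimed at trophic ecologists who have consumer tissue tracer
values and a table of potential prey, and who want to go beyond a population
mean diet: which prey are statistically distinguishable and may be pooled
into functional groups, what diet-proportion vector each consumer (and each
natural group of consumers) plausibly has, and how specialized each
individual is.  It grew out of the analysis pattern of baleen-whale studies
in the St. Lawrence Estuary system — skin δ13C/δ15N, blubber FAs, seven
forage species, a regime shift splitting the series into two periods — and
ships a synthetic-data generator parameterised from that system's published
prey table, so the entire pipeline can be exercised (and tested) at desk
scale with no external data.

## The model at the core

For a consumer with diet proportions **p** = (p₁…p_K) over K prey sources,
each tracer i is modelled as

```
x_i | p  ~  Normal( Σ_k p_k (μ_ik + λ_i),   Σ_k p_k² (σ_ik² + τ_i²) )
```

with (μ_ik, σ_ik) the source mean/SD and (λ_i, τ_i) the trophic
discrimination factor (TDF) mean/SD — the "process error only" mixing
likelihood, in which source and TDF uncertainty make up all residual
variance.  Diets live in isometric log-ratio (ILR) coordinates: each
consumer group g (a fixed effect) has coordinates θ_g whose induced prior on
the simplex is Dirichlet(α) (flat by default), and each individual deviates
by u_j ~ N(0, σ²I) in ILR space (a random effect).  Sampling is by
blockwise adaptive random-walk Metropolis across multiple chains, with
split-chain Gelman–Rubin R̂ and Geweke diagnostics.

Around it:

- **PERMANOVA / SIMPER / Benjamini–Yekutieli** (`multivar_stats`) — Euclidean
  pseudo-F with exact enumeration on small designs, per-variable
  dissimilarity decomposition, and FDR-adjusted pairwise tests driving the
  merging of indistinguishable, ecologically compatible prey into functional
  groups.
- **Clustering** — Ward linkage on z-scored tracer values, number of
  clusters chosen by the Dunn index, validated by leave-one-out linear
  discriminant accuracy.
- **Specialization index Ɛ** (`specialization`) — normalised Euclidean
  distance of a diet vector from the equal-proportion "ultra-generalist"
  diet: Ɛ = ‖p − g‖ / √((K−1)/K), so 0 is an ultra-generalist and 1 a
  single-prey ultra-specialist; computed per posterior draw.
- **Tracer prep** (`tracer_prep`) — δ-notation conversion, configurable
  lipid-extraction/DMSO preservation corrections, FA subset selection and
  the essential-FA sum (20:5n3 + 22:6n3 + 20:4n6).
- **Synthetic data** (`synthetic_data`) — forward model of the mixing
  equation plus compositional FA profiles; the shipped `regime_shift`
  scenario plants a two-period, five-group diet structure over six prey
  functional groups.

## Worked example

```python
import numpy as np
from trophoniche import (MixingConfig, SourceSpec, Scenario,
                         fit_mixing_model, SourceDistribution)
from trophoniche.synthetic_data import GroupSpec, generate_consumers
from trophoniche.specialization import epsilon_posterior

specs = [SourceSpec("arctic_krill", -18.7, 0.3, 9.3, 0.6, 28),
         SourceSpec("herring",      -17.9, 0.9, 12.7, 0.6, 40),
         SourceSpec("northern_krill", -19.5, 0.5, 10.7, 0.4, 110)]
scenario = Scenario(sources=tuple(specs),
                    groups=(GroupSpec("g1", "pre", (0.7, 0.2, 0.1), 30),),
                    process_sd_extra=(0.0, 0.0), seed=7)
consumers, truth = generate_consumers(scenario)

sources = [SourceDistribution(s.name, (s.mu_c, s.mu_n), (s.sd_c, s.sd_n), s.n)
           for s in specs]
posterior, report = fit_mixing_model(
    consumers, sources,
    MixingConfig(chains=3, iterations=20_000, burn_in=10_000, thin=10, seed=11))

print(posterior.flat_group().mean(axis=0).round(3))
print({k: round(v, 3) for k, v in report.rhat.items()})
eps = epsilon_posterior(posterior)
print(eps.summary_by("individual").round(3))
```

prints (seed-exact):

```
[[0.748 0.168 0.084]]
{'p[g1,arctic_krill]': 1.003, 'p[g1,herring]': 1.002, 'p[g1,northern_krill]': 1.005, 'sigma_re': 1.002}
    by   mean    std    min    max  count
0  all  0.624  0.018  0.594  0.669     30
```

The 30 simulated whales were fed p = (0.70, 0.20, 0.10); the posterior group
means land within ±0.05 of that and every R̂ is below 1.01 (converged).  The
per-individual per-draw Ɛ averages 0.62, a little above Ɛ(truth) = 0.56
because posterior draws scatter around the true diet and Ɛ is convex — the
package therefore also reports Ɛ of the posterior-mean diet, which is the
lower of the two (see `eps.per_unit`).

The full pipeline (simulate → correct → aggregate prey → split periods →
cluster → fit → Ɛ → report) runs from a single call or the CLI:

```sh
trophoniche run --seed 3 --out results/regime_shift
```

which writes `prey.csv`, `consumers.csv`, `truth.csv`, `clusters.csv`,
`groups.json`, `convergence.json` and a fingerprinted `report.json` /
`report.md`.  Reports regenerate byte-identically for the same config and
seed.

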