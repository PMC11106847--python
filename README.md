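# rtscr — random-thinning spatial capture-recapture for river surveys

`rtscr` estimates the density of a territorial, hard-to-observe animal (the
motivating case is the Eurasian otter *Lutra lutra* in a drying Mediterranean
river pool) from **genetic non-invasive sampling**: feces ("spraints")
collected along linear transects, genotyped at microsatellite loci, and — when
genotyping succeeds — assigned to an individual. Samples whose genotype fails
lose their identity but still carry information. The package implements the
full inference chain for that design, for ecologists and applied statisticians
working with spatially referenced count data of partially identified
individuals.

## The model

Transects are discretized into a hexagonal grid of 1-ha cells; each cell
centroid acts as a "detector" `j` with effort `L_j` (km of transect inside the
cell, single collapsed occasion `K = 1`). Each individual `i` of an augmented
super-population `i = 1..M` (inclusion `z_i ~ Bernoulli(ψ)`, abundance
`N = Σ z_i`) has a latent activity center `s_i ~ Uniform(S)` on a rasterized
habitat mask `S` (the flooded area). Encounters follow

```
y_true[i,j] ~ Poisson(z_i · λ_ij),      λ_ij = λ0_j · exp(−d_ij² / 2σ²)
log λ0_j    = β · L_j + ε_j,            ε_j ~ Normal(μ0, σ_p²)
```

and identities are retained by a **random thinning** with probability θ:

```
y_id[i,j] ~ Binomial(y_true[i,j], θ),   nnid_j = Σ_i (y_true − y_id)[i,j]
```

Only `y_id` (for the `n` identified individuals) and the per-detector non-ID
totals `nnid_j` are observed. The bespoke MCMC sampler integrates over the
latent allocation of the non-ID counts with a constrained Metropolis move that
preserves `Σ_i y_noid[i,j] = nnid_j` by construction. Densities follow as
`D_s = N / area` and `D_L = N / river length`, and the movement radius
containing 95% of locations is `r95 = σ·√5.99`.

Around the core model the package provides: survey geometry (hex grids,
effort clipping, habitat masks, sample aggregation), consensus genotyping
from replicated PCRs with probability-of-identity statistics, diet FO/RFO
tables, WAIC model comparison, split Gelman–Rubin diagnostics,
posterior-predictive goodness-of-fit, activity-center kernel maps, the
Clark–Evans nearest-neighbor dispersion test, and a synthetic-scenario
generator with known truth.

## Worked example

```python
import numpy as np
from rtscr import ScenarioConfig, generate_scenario, RandomThinningSCR

cfg = ScenarioConfig(seed=1)           # study-scale defaults: 13 otters,
design, enc, truth = generate_scenario(cfg)   # σ=1087 m, θ=0.6, ~176 cells
model = RandomThinningSCR.from_design(design, enc)
res = model.fit(iterations=20_000, burn_in=5_000, thin=5, chains=3, seed=2)
print(res.summary().round(3))
```

```
           mean     sd    q2.5     q50   q97.5
N        12.444  0.709  12.000  12.000  14.000
psi       0.268  0.063   0.155   0.266   0.399
sigma     1.248  0.186   0.954   1.225   1.688
theta     0.490  0.049   0.395   0.488   0.586
beta      2.449  0.621   1.284   2.432   3.797
mu0      -5.302  0.664  -6.775  -5.249  -4.153
sigma_p   1.845  0.310   1.307   1.817   2.521
```

This synthetic survey was generated with `N = 13` (12 detected), `σ = 1.087`
km and `θ = 0.6`; it realized 49 identified and 51 unidentified samples, so
the thinning posterior correctly centers on the realized retention 49/100.
Derived quantities and diagnostics hang off the results object:

```python
dd = res.derived_density(area_km2=design.mask.habitable_area_km2, river_km=7.8)
# D_s = 3.92 ind/km^2  [3.78, 4.41]      D_L = 1.60 ind/km  [1.54, 1.79]
res.movement_radius()              # r95 mean 3.06 km
res.gof(n_reps=400, seed=0).p_values
# {'total_detections': 0.51, 'individuals_detected': 0.71, 'detectors_visited': 0.54}
res.waic()["waic"]                 # 629.9 (compare nested detection models)
res.convergence().passed           # True (worst split R-hat 1.008)
```

`N` draws, activity-center draws (`res.ac_map("SIM03")`), and per-detector
pointwise log-likelihoods are all retained. A thin CLI mirrors the stages:
`rtscr simulate`, `rtscr discretize`, `rtscr fit`, `rtscr summarize`,
`rtscr genotypes consensus|pid`, `rtscr diet`.

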