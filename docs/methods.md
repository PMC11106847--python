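# Methods

## Model

`rtscr` fits a single-occasion spatial capture-recapture (SCR) model with
Poisson encounters, a half-normal detection function, and a binomial
random-thinning layer for loss of individual identity during genotyping.

**State space.** Activity centers are uniform over a habitat mask: a raster
whose pixels are habitable iff their center falls inside the habitat polygon
(default pixel 25 m, configurable). The sampler represents centers as
continuous coordinates and rejects proposals landing on non-habitable pixels;
in the fine-pixel limit this is the same model as a pixel-lookup habitat
matrix, and it keeps the distance computations exact.

**Detectors.** Linear transects are clipped into a flat-top hexagonal tiling
(1-ha cells by default; adjacent centroids √(2A/√3) ≈ 107.46 m apart, below
the 110 m guideline of ~1.5σ for aggregated detectors). Cells with positive
effort are retained as detectors even when they recorded nothing — absences
are informative; cells with zero effort are dropped. Grid origin is the
lower-left corner of the extent, so a tiling is deterministic for a given
extent; totals such as Σ L_j are invariant to the origin. Point-in-cell
membership is nearest-centroid (the hexagonal Voronoi partition), which
resolves boundary ties deterministically.

**Detection submodel.** λ_ij = λ0_j exp(−d²_ij/2σ²) with
log λ0_j = β·L_j + ε_j. Effort enters in km of transect per cell. Three nested
variants are exposed: null (constant log λ0 = μ0), effort covariate
(μ0 + β L_j), and effort plus a per-trap normal random effect
ε_j ~ N(μ0, σ_p²) (default). The random effect absorbs trap-level
heterogeneity (shoreline vs open water, foot vs boat search) that effort alone
does not explain; WAIC (pointwise unit = detector, i.e. the sum of that
detector's Poisson and thinning terms) compares the variants.

**Random thinning.** Every true encounter keeps its identity independently
with probability θ. Identified histories y_id enter per individual; failed
genotypes enter only through per-detector totals nnid_j. The same individual
may appear in both data types at the same detector, and individuals never
identified anywhere still contribute non-ID counts.

**Data augmentation.** The population is embedded in M pseudo-individuals
with z_i ~ Bern(ψ); N = Σ z_i. Default M = 4n (n = individuals identified);
the fit warns when posterior mass approaches M.

## Priors (defaults, all configurable)

| parameter | prior | rationale |
|---|---|---|
| ψ | Beta(1, 1) | uniform inclusion probability |
| θ | Beta(1, 1) | uniform identity retention |
| σ | Uniform(0, half mask diagonal) | weakly informative on the survey scale |
| β | Normal(0, 10²) | effort effect, log scale per km |
| μ0 | Normal(0, 10²) | log-scale baseline mean |
| σ_p | Uniform(0, 5) | trap heterogeneity SD, log scale |

## Sampler

Hand-written Metropolis-within-Gibbs; per sweep:

1. **Activity centers** — joint random-walk proposal for all M rows (rows are
   conditionally independent), off-mask proposals rejected; inactive
   individuals move freely on the mask (their conditional is the uniform
   prior), which keeps the z-updates well mixed.
2. **σ** — random walk on log σ (Jacobian included), rejected above the prior
   bound.
3. **β, μ0, σ_p, ε** — random-walk Metropolis; all J trap effects are updated
   in one vectorized pass (columns are conditionally independent). Because
   β and the trap effects are nearly confounded (log λ0 = βL + ε), an extra
   joint translation move (β+δ, ε−δL̄, μ0−δL̄) walks along the ridge; without
   it β mixes an order of magnitude slower.
4. **θ** — conjugate Beta draw. Note its full conditional
   Beta(a + Σy_id, b + Σnnid) is the same every sweep: the thinning constraint
   fixes Σ y_noid = Σ nnid, so θ is conditionally independent of the latent
   allocation. This is a property of the model, not a shortcut.
5. **Latent non-ID allocation** — for each detector with nnid_j > 0, a
   constrained Metropolis move takes one unit of y_noid from a random current
   holder and offers it to a random active individual; the acceptance ratio
   reduces to (λ_bj/λ_aj) · y_noid[a,j]/(y_noid[b,j]+1) times a
   donor-count proposal correction, and the totals constraint can never be
   violated. Two moves per detector per sweep by default.
6. **z, ψ** — exact Bernoulli full-conditional draws for augmented individuals
   whose current counts are all zero (others are forced active); conjugate
   Beta draw for ψ.

Proposal scales adapt toward ~38% acceptance during burn-in and are frozen
afterwards, so the retained draws come from a fixed-kernel chain. Chains are
seeded by spawning independent streams from one root seed. Default desk-scale
settings are 3 chains × 20,000 iterations (burn-in 5,000, thin 5);
`full_settings=True` (the full-length production run) switches to 3 × 250,000 / 10,000 / 5.

Scalar parameters can be pinned (`fixed=...`), and σ/θ can instead be drawn
exactly over a discrete grid — used by the test suite to compare the sampler
against exhaustive enumeration on a tiny instance.

**Convergence.** Split Gelman–Rubin R-hat (plain, not rank-normalized) per
scalar parameter with the 1.1 threshold, plus Geyer initial-positive-sequence
effective sample sizes. A single-chain fit reports convergence as *not
assessed* rather than passing silently.

## Derived quantities and diagnostics

- **Densities**: D_s = N/area and D_L = N/river-length are computed per draw
  and then summarized, so quantiles are quantiles of the density.
- **Movement radius**: r_q = σ·√(χ²₂(q)); at q = 0.95, σ = 1.087 km gives
  2.66 km.
- **AC maps**: per-individual product-Gaussian KDE of the posterior
  activity-center draws on a grid clipped to the mask and renormalized;
  per-axis normal-reference bandwidth (sd · n^(−1/6)); the argmax is the AC
  point estimate.
- **Dispersion**: Clark–Evans average nearest-neighbor ratio without edge
  correction (observed mean NN distance over 0.5/√(n/A), z-score via
  SE = 0.26136/√(n²/A)). Uncorrected CSR calibration shows a small upward
  bias (~+3% at n = 200 in a square), which is why the test tolerance is ±5%.
  The reference area defaults to the flooded (mask) area.
- **Goodness of fit**: posterior-predictive replicates of the full observation
  model for all M individuals at retained draws; statistics are total
  detections, individuals detected (identified at least once), and detectors
  visited (≥1 sample of either kind). Bayesian p = P(T_rep ≥ T_obs), ties
  counted as exceedance.

## Synthetic scenarios

`generate_scenario` emulates the motivating survey: ~13 individuals on a
~3.2 km² sinuous river corridor (a buffered ~7.6 km centerline), ~176 one-ha
detector cells in a narrower surveyed band, per-cell effort drawn from a
normal truncated at zero with mean 439 and SD 443 m/ha (the field effort is
reported by its moments only), trap effects N(−4.632, 1.939²), β = 1.649,
σ = 1087 m, θ = 0.6. One seed drives stage-split generator streams
(effort → activity centers → trap effects → encounters → thinning), so adding
a stage never perturbs the others. Unidentified samples arise by uniform
random thinning of the same spatial process — exactly the rt-SCR assumption;
if identity loss were spatially structured (e.g. older samples farther from
water degrade more), both the generator and the model would be misspecified
together, and passing recovery tests cannot detect that. Other features of
real data the generator does not emulate: GPS error, sample aging and
detectability differences within a cell, genotyping error correlated across
samples of the same individual.

The genotype-panel simulator applies per-replicate allelic dropout, false
alleles and missingness to Hardy–Weinberg source genotypes; it feeds the
consensus/matching tests with known truth.

## Numerical and design choices

- Internal length unit is meters; σ is *reported* in km. Effort is passed to
  the model in km so the effort coefficient is on the printed scale.
- Consensus calling: heterozygote needs the identical pair in ≥2 replicates,
  homozygote in ≥3; "more than 14 loci" is read strictly (≥15 called loci
  accepted). A 2× heterozygote and a 3× homozygote cannot coexist within four
  replicates (asserted); two distinct 2× heterozygotes leave the locus
  missing. The consensus-referenced dropout estimator conditions on a
  heterozygous consensus call, which shrinks it below the per-replicate
  dropout probability at four replicates; the tests check it against the
  exact conditional expectation rather than the raw simulation parameter.
- Individual matching is exact (tolerance 0) by default; with four replicates
  and realistic dropout an occasional false homozygous consensus call
  survives, so recovering true individuals from a noisy panel needs one-locus
  tolerance (exposed as an argument, demonstrated in the tests).
- PID formulas per locus: PID = 2(Σp²)² − Σp⁴ and
  PIDsibs = ¼ + ½Σp² + ½(Σp²)² − ¼Σp⁴; multilocus values are products.
- Diet: a category counts once per spraint for FO/RFO regardless of its
  minimum prey count, so RFO sums to 100%.
- Readers require planar metric coordinates and reject inputs that look like
  lon/lat degrees (override available) rather than silently projecting.

## Limitations

- No sex- or covariate-structured σ, no open-population dynamics.
- The allocation move updates one unit at a time; with very large nnid per
  detector more moves per sweep (`allocation_moves`) may be needed.
- WAIC uses the detector as the pointwise unit; other partitions (individual,
  cell×individual) would give different absolute values, so compare only
  within a fixed choice.
- R-hat is the plain split statistic; heavy-tailed posteriors would warrant
  the rank-normalized variant.
- The Clark–Evans test ignores edge effects and duplicate-coordinate ties are
  kept at distance zero.
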