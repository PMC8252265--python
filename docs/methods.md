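# Methods

This note records the models, the numerical choices, and the synthetic
study conditions behind `slopescan`, and what the passing tests do and do
not establish about real data.

## Phenology model and processing

A trait (bud burst, leaf shed, autumn coloring, bud set) is scored on an
ordinal stage scale at visits a few days apart. The processing model
assumes each individual's true stage-onset days are monotone in stage and
that departures in the records are observation noise: observers disagree by
one stage, or shed yellow leaves make a tree look greener. The
running-maximum rule dates stage *k* ≥ 2 at the first visit whose running
maximum reaches *k* and ignores later reversals; stage 1 ("no change yet")
is dated at the last visit still there, since earlier stage-1 records carry
no information about progress.

Transitions crossed between two visits are imputed per individual by local
regression (LOESS) of day on stage — span 0.75, local-linear, the
`statsmodels` lowess — evaluated at the missing stages. With exactly two
dated stages the local fit degenerates to the straight line through them,
which is used directly; with fewer than two the cells stay missing. Because
an unconstrained local fit can break monotonicity that the truth has, a
pool-adjacent-violators pass (ties allowed) follows, with observed cells
weighted so heavily that only imputed cells move. Clone phenotypes are
arithmetic means over ramets.

Heritability: narrow-sense is a REML fit of ramet-level values with a
genetic effect whose covariance is σ²_g·K over clones (K the standardized
marker kinship), h² = λ̂/(1+λ̂) with λ profiled on a log grid plus bounded
refinement; broad-sense is the Cullis measure H² = 1 − v̄_Δ/(2σ̂²_g), with
v̄_Δ the mean prediction-error variance of a difference between two
genotype BLUPs from a genotype(+block) random-effects fit. A genetic
variance pinned at the zero boundary sets an `overfit` flag instead of
reporting a spurious positive h². On a balanced design with no blocks, the
Cullis measure reduces exactly to σ²_g/(σ²_g+σ²_e/r); the tests check this
to 1e-6. Estimates from stage-censored observations are mildly attenuated:
the 2–5-day visit grid adds uniform observation noise of about (gap²/12) to
the environmental variance, so pipeline h² estimates sit below the
generative target even when the estimator is unbiased for its own model.

## Association model

y = Wα + xβ + u + ε, u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I). One
eigendecomposition of K rotates the model to independent errors; the
restricted likelihood is profiled over log₁₀ λ on [−5, 5] (41-point grid,
then bounded scalar minimization). Per SNP the default re-optimizes λ in a
±2-decade window around the null estimate (13-point grid) — matching the
cited tool's behavior — with a shared-λ vectorized path for large scans
and a `fixed_lambda` escape hatch (λ=0 with K=I is exactly OLS, which the
tests verify to 1e-8). The reported test is a Wald t with n − rank(W) − 1
degrees of freedom, which matters at n ≈ 110; whether the original
analysis used Wald, LRT or score p-values is not stated anywhere, so Wald
is implemented and flagged as the choice. Missing dosages are mean-imputed
per marker; kinship flavors are the centered and standardized
cross-products over markers, GEMMA-style.

REML, unlike ML, is only asymptotically invariant to duplicating a
dataset; the corresponding test asserts agreement to 5% rather than
exactly.

## Lindley segmentation

Scores X_i = −log₁₀(p_i) − ξ; h_i = max(0, h_{i−1}+X_i) per chromosome,
computed by the running-minimum identity h = S − min(0, cummin S). ξ
defaults to 2 (the source method recommends tuning by the p-value
distribution; no published value exists for this analysis, so it is
config-exposed and logged). Thresholds: per chromosome, the lag-1
autocorrelation ρ̂ of −log₁₀ p is matched by Gaussian AR(1) null
sequences, mapped through the normal CDF to uniform p-values; the
(1−α) quantile of the null maxima (1000 replicates by default) is the
threshold. A single-marker chromosome admits the closed form
max(0, −log₁₀ α − ξ), used directly. A block-permutation alternative is
provided. Slopes are reported start → peak (leading edge), leftmost tie
wins, with a full-excursion flag. α = 0.05 per chromosome, uncorrected
across chromosomes, mirroring chromosome-specific thresholds.

## LD decay and selection statistics

Pairwise r² between dosages within non-overlapping 50-kbp windows (markers
thinned to 100k first if needed) is fitted over ρ by nonlinear least
squares to the drift expectation with sample-size correction; the reported
scale is the distance at which the fitted curve halves its d→0 value.

EHH around a core allele is the probability that two random carrier
haplotypes are identical from the core out to a position, computed by
partition refinement (a numba kernel with an identical pure-Python
fallback). iHH integrates the EHH decay over genetic distance
(trapezoid, both directions, stopping at the first marker below the 0.05
cutoff, which is included); iHS = ln(iHH_ancestral/iHH_derived) with the
reference allele treated as ancestral (polarization is unknowable here;
|iHS| makes downstream ranking insensitive). Standardization subtracts the
mean and divides by the SD within 50 derived-allele-frequency bins. Cores
with a zero integral — e.g. all surrounding genetic distances zero, as
happens inside missing-rate map intervals — yield no estimate. Cores whose
EHH is cut off by a chromosome end are dropped under the default
conservative policy; at desk scale, where chromosomes are only ~1 Mbp,
the `keep` policy plus a 100-kbp interior margin is used instead
(documented wherever it is), because edge truncation would otherwise
remove most cores including the selected ones. H12 uses 100-SNP windows
with step 50, assigned to the central SNP.

Genetic positions come from linear interpolation of cumulative cM between
map anchors; an anchored interval whose local rate is missing contributes
exactly zero genetic distance, and the map extends flat beyond its
outermost anchors.

## Integration

Extended intervals are closed, 1-based, clipped to the chromosome, merged
within a trait. Enrichment is the exact hypergeometric upper tail
P(X ≥ k) with the universe restricted to SNPs that have a finite selection
estimate — iHS and H12 legitimately have different universes, since iHS
drops zero-distance and truncated cores. Peaks are SNPs with no strictly
higher score within ±10 kbp (20,001-bp centered window; leftmost tie
wins), retained if in the global top 0.1 percentile. Term enrichment is a
one-sided Fisher exact test per term with at least two candidate genes,
BH-corrected, enriched at adjusted p < 0.05.

## Synthetic data: what it emulates, and the scaling

The generator emulates a small introduced breeding population: ~40
outbred founders, 34 full-sib families of 1–21 offspring (121 clones
total), clones replicated into 5 blocks, ordinal stages scored on a
2–5-day grid with low-frequency reversal errors and missed visits.
Founders are drawn from the coalescent at equilibrium (the burn-in
shortcut); swept chromosomes use the structured-coalescent sweep model,
which conditions on the sweep's start and end frequencies by construction
— a hard sweep starts from one copy, a soft sweep from standing variation
at frequency 0.05. Crosses are forward-time meioses with Poisson
crossovers placed uniformly on the genetic map. Genetic values are purely
additive; the environmental variance is scaled to hit the target h².
All randomness derives from one seed through labelled `SeedSequence`
splits, so every stage is independently reseedable and bit-reproducible.

Desk-scale genomes compress a tree genome roughly 100-fold: N_e = 100–500,
chromosomes of 0.5–1 Mbp, with per-bp mutation and recombination rates
raised so that SNP density and an LD half-decay of ~10–15 kbp match the
target population. Consistent rescaling raises the sweep selection
coefficient by the same factor: the sweep battery uses s = 1.0 at
N_e = 200, i.e. a population-scaled strength α = 2N_e·s = 400 — a strong
sweep in the natural-population sense, where weaker coefficients are
undetectable at any scale by these statistics. The sweep condition also
uses a higher recombination rate (1.6e-6/bp) than the LD/GWAS conditions
so the sweep footprint, roughly s/(r·ln α) ≈ 100 kbp, matches the
±50 kbp windows used to score localization; in that condition the
association signal around a QTL is much narrower than the sweep footprint,
so the integrated slope-vs-sweep test pads slopes by the footprint scale
(±50 kbp) rather than the LD scale. A second, neutral chromosome anchors
the iHS standardization bins: on a 1-Mbp swept chromosome most
high-frequency SNPs are hitchhikers, and without a neutral reference they
would standardize each other away.

What the generator does not model: ancestral range-wide population
structure among the founders, demography beyond the family design,
dominance and epistasis, gene conversion, background selection,
genotyping error and depth-dependent missingness. Passing tests therefore
show the chain is correct and calibrated under its own assumptions — they
do not certify power or false-positive rates under real ascertainment,
structure, or non-additive architecture.

## Test-suite problem sizes

Replicated checks use 20 seeds each at the sizes above: null calibration
on 2-chromosome, ~100-sample neutral panels (KS uniformity is evaluated on
markers thinned to ≥10 kbp spacing — the LD scale — because the KS test
needs approximately independent draws); QTL recovery on 121-clone,
34-family populations with a 20%-variance QTL; h² recovery at 200 clones
× 3 ramets under the standardized-kinship generative model; the sweep
battery on 2 × 1 Mbp genomes. The reproduction script runs 10 replicates
per battery. The iHS/H12 cross-check compares the vectorized
implementation against a literal-definition pure-Python oracle
(tuple-dictionary haplotype grouping, hand trapezoid) on a 50-haplotype,
500-SNP coalescent fixture to 1e-6.

## Known limitations

- Haplotype phase is taken as given (simulated data is intrinsically
  phased; real data must be pre-phased — the VCF reader enforces this on
  request). Statistical phasing is out of scope.
- Marker-based narrow-sense h² is attenuated for monogenic traits, whose
  genetic covariance a genome-wide kinship does not represent; the
  recovery test uses a polygenic trait for exactly this reason.
- The Lindley threshold is Monte-Carlo, exact only by construction at the
  simulated null; the published Gumbel approximation is a possible future
  addition.
- The depth-based site filters are optional and inactive when the VCF has
  no DP field, as in synthetic data.
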