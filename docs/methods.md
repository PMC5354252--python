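# Methods

## The question and the estimator chain

A quantitative trait measured across K populations can differ between them
because of drift alone; invoking divergent selection requires showing that
the between-population differentiation exceeds the neutral expectation.
The neutral benchmark is Fst at neutral markers: under drift the Qst of a
trait,

    Qst = σ²gb / (σ²gb + 2 σ²gw),

(σ²gb, σ²gw the between- and within-population additive genetic variances)
is expected to match the Fst distribution of neutral loci. Additive genetic
variances are not observable in humans, so the pipeline substitutes
phenotypic components scaled by the between- and within-population
heritabilities c and h²:

    Qst(r) = r σ²pb / (r σ²pb + 2 σ²pw),   r = c/h²,

computed at r = 1 by default and swept over a grid for sensitivity.

### Phenotypic variance components

`qst.variance_components` fits a fixed-effects linear model with the
population label as the effect of interest and sex, age and BMI as nuisance
covariates. MSB is the marginal (type-II) mean square for the population
effect — the drop in residual sum of squares when population dummies are
added to the covariate-only model, divided by a−1 — and MSW the residual
mean square of the full model. Then

    n0 = (Σnᵢ − Σnᵢ²/Σnᵢ)/(a−1),  σ²pw = MSW,  σ²pb = (MSB − MSW)/n0.

Design choices:

- *Marginal, not sequential, MSB.* Covariates are nuisance adjustment, so
  the population effect is assessed after them. A test cross-checks the
  components against statsmodels' type-II ANOVA to machine precision.
- *Negative σ²pb clamped to zero* (and flagged): a variance cannot be
  negative and clamping keeps Qst well-defined; the unclamped values are
  kept in the bootstrap draws and clamped per draw at evaluation time, so
  ratio rescaling stays consistent.
- *Rows with missing trait/covariates are dropped listwise* and counted.
- Pigmentation analyses default to the untransformed melanin index, with
  `morphometrics.inverse_melanin_index` available where the more normal
  1/MI scale is wanted for testing.

`qst.variance_components_from_cells` computes the same ANOVA exactly from
population × sex cell summaries (n, mean, SD): within-cell sums of squares
are (n−1)·SD² and the between-cell part comes from weighted least squares
on the cell means. Only sex can be adjusted this way; the packaged
published cell table for the study cohort therefore reproduces the fully
adjusted analysis only for traits whose age/BMI dependence is weak (height,
nasal height, ridge length, tip protrusion agree to ~0.01; the
age/BMI-sensitive traits deviate by up to 0.12 — which is why the strict
reproduction checks require the individual-level table; see the test
docstrings in `tests/test_acceptance.py`).

### Weir–Cockerham θ

`fst.wc_theta` computes, per biallelic SNP, the 1984 moment components
a (among populations), b (between individuals within populations) and
c (within individuals), using observed heterozygote frequencies — no
Hardy–Weinberg assumption — and missing genotypes excluded per SNP. The
multi-locus estimate is Σa / Σ(a+b+c) (ratio of sums). Per-SNP negative
values are retained: the divergence test resamples from the realized
distribution, and clamping would bias its lower tail. SNPs monomorphic
across all populations, or typed in fewer than two populations, are
dropped and counted. The unit suite checks the vectorized implementation
against an independent scalar transcription of the published component
formulas to six decimals; no installed third-party θ implementation exists
in this environment, so the transcription is the reference.

### The bootstrap divergence test

`divergence.bootstrap_qst` draws pseudo-samples by resampling individuals
with replacement *within population × sex strata* so every stratum keeps
its size, and recomputes the variance components per draw with the same
covariate model (a fast two-regression least-squares path; identical
algebra to the headline fit). `divergence.qst_fst_test` pairs each
pseudo-sample with one per-SNP θ drawn uniformly with replacement — the
literal reading of sampling from the genome-wide per-SNP distribution; a
multi-locus-resample alternative sits behind the `multilocus_resample`
flag — and reports the empirical p as the proportion of Qst − Fst draws
below zero. A proportion of exactly zero is reported as "< 1/n_boot"
rather than 0. Default n_boot is 10,000. Traits pass the multiple-testing
screen when p < α/n_tests with strict inequality (default 0.05/7 = 0.0071,
seven nose-shape traits).

Because Qst(r) is a deterministic function of the stored per-draw
(σ²pb, σ²pw), the sensitivity curve re-evaluates the same draws over the
ratio grid (default 0.01…1.00 in steps of 0.01) without re-resampling —
mathematically identical and ~100× cheaper. The critical ratio is the
smallest grid point where the 2.5% Qst quantile reaches the 97.5% quantile
of the same Fst draw distribution used in the test (keeping the two bands
internally consistent); if never reached it is flagged ">r_max". With
degenerate draws the grid answer matches the closed form
r* = 2 σ²pw F / (σ²pb (1−F)) within one grid step.

### Heritability

`heritability.grm` builds the standardized-genotype relationship matrix,
entries averaged over SNPs of (x−2p)(x′−2p)/(2p(1−p)) with p the pooled
sample frequency; monomorphic or zero-sample-variance SNPs are skipped and
missing dosages mean-imputed per SNP. The same construction on
local-ancestry dosages (`ancestry_grm`) gives the ancestry kinship whose
REML variance share, h_y², estimates the between-population heritability c:
local ancestry carries only the between-population component of genetic
variation, so in a randomly mating admixed cohort — where ancestry
segments segregate independently of environment — the phenotypic variance
it explains is the between-population genetic fraction.

`reml_h2` fits the one-component model y = Xβ + g + e, g ~ N(0, K σ²g),
by REML: after one eigendecomposition of K the likelihood is a smooth
scalar function of h² = σ²g/(σ²g+σ²e), maximized by bounded Brent search
(tolerance 1e-6) with the total variance profiled out. Negative K
eigenvalues are clipped at zero with a warning. The SE comes from a
numerical second difference of the profile REML log-likelihood (step
1e-4); estimates on the [0,1] boundary are flagged and use the one-sided
curvature. Only the single genetic component is supported — the analyses
this package serves use nothing richer. `top_pcs` returns
root-eigenvalue-scaled kinship eigenvectors with a deterministic sign
convention (largest-magnitude loading positive) for use as structure
covariates.

### Climate association

Relative and absolute humidity come from temperature T (°C) and vapor
pressure e (hPa): Magnus saturation vapor pressure
es = 6.1094·exp(17.625 T/(T+243.04)) hPa, RH = 100·e/es (capped at 100
with a warning), and AH = 216.7·e/(T+273.15) g/m³ (ideal-gas water-vapor
density, Rv = 461.5 J kg⁻¹ K⁻¹). These are the standard forms; the upstream
gridded-climate derivation is out of scope and climate arrives as tabular
per-individual values. Ancestral climate per individual is the mean of the
available parents' birthplace values (a single known parent passes
through).

`climate.kinship_lmm_slope` fits y = Xβ + ε with Var(ε) = σ²g K + σ²e I by
maximum likelihood (the same eigen-rotation machinery as the REML module).
ML, not REML, because the p-value is a likelihood-ratio test on a fixed
effect (the climate column dropped in the reduced model; χ²₁ reference),
and REML likelihoods are not comparable across fixed-effect structures.
The slope, SE and t come from generalized least squares at the ML variance
ratio. The one-term error model with covariance proportional to K alone is
available as `strict_gls=True` (with ridge stabilization when K is
singular); the two-component form is the default because a pure-K
covariance is typically singular and it is what mixed-model software fits
in practice. With K = I the slope reduces to OLS exactly. Sex is excluded
by the caller for single-sex cohorts rather than hard-coded.
`leave_one_population_out` refits after dropping each population (kinship
subset accordingly) and reports slope ± 1.96 SE with an overlaps-zero
flag; it refuses drops leaving fewer than 3 individuals or a constant
climate column.

## Morphometrics

Seven landmarks (n, prn, sn, al_l, al_r, ac_l, ac_r) define five distances
— nares width |al_l−al_r|, alar base width |ac_l−ac_r|, nasal height
|n−sn|, nasal ridge length |n−prn|, nasal tip protrusion |sn−prn| — and
meshes with region masks give the two areas (triangle area = half
cross-product norm; nostril area is the mean of the left and right
regions). Generalized Procrustes superimposition removes translation and
rotation by iterative alignment to the consensus (Kabsch rotations,
convergence when the consensus moves < 1e-10 RMS); **scale is kept** by
default because the traits are absolute millimetre measurements —
alignment only serves orientation and symmetry. Since rigid alignment
preserves distances, computing distances before or after alignment is
equivalent; the package computes them directly from coordinates. Bilateral
asymmetry is removed by averaging a configuration with its reflection
(x → −x followed by left/right label swap), which provably places midline
landmarks on the symmetry plane. Replicated placements are averaged within
each observer's replicates first, then across observers.

The melanin index is 100·log10(1/reflectance at 650 nm) with reflectance a
fraction in (0,1]; percent-scale input (>1) is auto-detected, divided by
100 and warned about — index values in the observed 26–60 range are only
consistent with the fraction convention. Observer reliability: the
two-way ANOVA with observer fixed and subject random gives
σ²subject = (MS_subject − MS_error)/k0 (k0 the effective replicates per
subject, an n0-style correction for imbalance), σ²error = MS_error, and
ICC = σ²subject/(σ²subject+σ²error), together with each observer's
within-subject SD 2.5%/97.5% quantiles.

## The synthetic-data generator

What it emulates:

- **Genotypes**: Balding–Nichols drift — ancestral frequency
  p ~ U(maf range, default 0.05–0.5), population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target Weir–Cockerham θ,
  Hardy–Weinberg binomial dosages within population. Defaults mirror the
  study conditions: four populations of (40, 236, 127, 73), drift level
  0.12 (the human continental scale).
- **Traits**: population effect + within-population polygenic score +
  noise + covariate effects (sex Bernoulli(½) with slope 1 trait unit, age
  U(18,40) × 0.02, BMI N(24,3) × 0.05 — arbitrary but fixed). The
  polygenic score is built from standardized genotypes and centered within
  population so it carries no between-population signal; noise is Gaussian
  and homoscedastic, sized so the within-population heritability is h².
  Between-population environmental offsets are sized so the
  between-population heritability is c (c > 0 is required whenever
  σ²gb > 0, and vice versa). h² = 0 is interpreted as "the σ²gw budget is
  pure noise". Two modes for the population effects:
  `exact_between_variance=True` (default) rescales them so the quantity
  the ANOVA estimates — Σnᵢαᵢ²/((a−1)n0) — is exactly σ²gb, treating the
  populations as fixed study entities (right for estimator-accuracy
  checks); `False` leaves them as raw normal draws, i.e. the drift
  randomness itself, which is what a neutrality null requires and what the
  type-I calibration uses.
- **Admixed cohorts**: per-individual global ancestry Beta-distributed
  (concentration 10) around the target mean (default 0.6, a two-way
  admixed population with majority ancestry from one parent population);
  each haplotype is a Markov chain along SNPs with geometric tract lengths
  (a desk-scale stand-in for recombination — no genetic map) and states
  drawn at the individual's ancestry fraction. Genotypes draw alleles from
  the parental frequency indicated by each haplotype's local ancestry
  (parental populations separated at F = 0.15 by default). The trait's
  ancestry-linked component is built from standardized local-ancestry
  dosages, residualized on global ancestry (which the estimator uses as a
  covariate) and rescaled so its realized variance share equals the h_y²
  target exactly.
- **Landmarks**: a template nose at adult-scale millimetre coordinates,
  subject-level perturbations (default SD 1.5 mm), optional per-population
  landmark offsets, and observer/replicate placement noise.
- **Climate**: population mean values plus within-population spread,
  joined to phenotypes by id.

What it does not emulate: linkage disequilibrium and coalescent genealogy,
mutation models, selection at individual loci, the X chromosome,
assortative mating, and measurement artifacts beyond iid placement noise.
Passing tests therefore demonstrate estimator correctness and calibration
under the generating model, not robustness to the full complexity of real
cohort data (array batch effects, relatedness, fine-scale structure).

## Numerical and reproducibility choices

- All generators and the bootstrap consume explicit integer seeds through
  `numpy.random.default_rng`; seeded runs are bit-reproducible and the
  pipeline writes the seed plus a config hash into every artifact.
- Degenerate inputs fail loudly: single population, empty stratum,
  all-monomorphic SNP sets, all-coincident landmark configurations,
  non-involution symmetry pairings, constant climate columns.
- Problem sizes in the test suite and acceptance script are desk-scale
  choices that keep each property measurable: 20,000 SNPs for θ
  convergence (±0.015), 50–200 replicate cohorts for recovery and
  calibration means, n = 1,000/M = 5,000 for genotype REML, n = 400 for
  the admixed cohort (the study's own admixed sample size), 1,000
  pseudo-samples per calibration replicate (10,000 in single headline
  runs).

## Known limitations

- The Qst model is univariate; shape-space (multivariate) Qst is out of
  scope, as are parametric Lewontin–Krakauer-style tests.
- The bootstrap propagates individual-sampling noise, not the evolutionary
  (drift) variance of the K realized population means; the paired per-SNP
  Fst draws serve as the neutral reference spread, and the type-I
  calibration shows the combination holds its nominal level under the
  generating model.
- REML is single-component; confounding between local ancestry and global
  environment in non-randomly-mating admixed cohorts is handled only
  through the global-ancestry covariate.
- Humidity formulas are the standard Magnus/ideal-gas forms; any upstream
  derivation that used different constants will differ in the third
  decimal.
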