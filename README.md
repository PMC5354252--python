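# qstfst

Quantitative-genetic divergence analysis for morphometric traits: did a
trait diverge across populations faster than genetic drift allows, and does
it track climate?

The package implements the full analysis pipeline around the Qst–Fst
comparison as applied to human nose-shape measurements across four
continental population groups, with a synthetic-data generator so every
stage is testable without access to the original cohort:

- **morphometrics** — seven nose-shape traits from 3D landmarks and meshes
  (five Euclidean distances, two surface areas), generalized Procrustes
  superimposition without scale removal, bilateral symmetrization, the
  melanin index `MI = 100·log10(1/reflectance)`, and observer-reliability
  statistics (ICC, intra-observer error quantiles);
- **qst** — phenotypic variance components from a fixed-effects model
  (population effect, sex/age/BMI covariates) with
  `n0 = (Σnᵢ − Σnᵢ²/Σnᵢ)/(a−1)`, `σ²pw = MSW`, `σ²pb = (MSB − MSW)/n0`, and

  ```
  Qst(r) = r·σ²pb / (r·σ²pb + 2·σ²pw),   r = c/h²
  ```

  where c and h² are the between- and within-population heritabilities;
- **fst** — per-SNP and multi-locus (ratio-of-sums) Weir–Cockerham θ;
- **divergence** — the stratified bootstrap Qst–Fst test (resampling
  individuals within population × sex strata, pairing each pseudo-sample
  with a draw from the realized per-SNP θ distribution; empirical
  p = proportion of Qst − Fst draws below zero), Bonferroni reporting, and
  c/h² sensitivity curves with the critical ratio at which the 95% lower
  Qst bound meets the 95% upper Fst bound;
- **heritability** — standardized genotype GRM and local-ancestry kinship,
  plus one-component REML for h_g² and h_y² (the local-ancestry analog that
  estimates c in an admixed cohort);
- **climate** — humidity derivation (Magnus saturation vapor pressure,
  ideal-gas absolute humidity), ancestral-climate assignment from parents'
  birthplace values, and a kinship-structured linear mixed model with
  likelihood-ratio p-values and leave-one-population-out robustness;
- **synthetic_data** — Balding–Nichols genotypes, polygenic traits with
  controlled (σ²gb, σ²gw, c, h²), admixed cohorts with geometric
  local-ancestry tracts, replicated landmark placements and
  population-linked climate.

## Worked example

```python
import numpy as np
from qstfst import synthetic_data as sim, fst, qst, divergence

cfg = sim.SimConfig(n_pops=4, n_per_pop=(40, 236, 127, 73), n_snps=10_000,
                    target_fst=0.12, sigma2_gb=32/9, sigma2_gw=1.0,
                    h2=0.6, c=0.6, seed=7)
genos = sim.simulate_genotypes(cfg)
pheno = sim.simulate_phenotype(genos, cfg)

dist = fst.wc_theta(genos)
vc = qst.variance_components(pheno, "trait")
draws = divergence.bootstrap_qst(pheno, "trait", n_boot=10_000, seed=7)
res = divergence.qst_fst_test(draws, dist, seed=8)
curve = divergence.sensitivity_curve(draws, res.fst_draws)
print(f"theta = {dist.theta_multilocus:.3f}")
print(f"Qst  = {res.observed_qst:.3f}  (true {pheno.attrs['truth']['true_qst']:.3f})")
print(f"empirical p = {res.p_label}, critical c/h2 = {curve.critical_label}")
```

prints

```
theta = 0.120
Qst  = 0.630  (true 0.640)
empirical p = 0.0003, critical c/h2 = 0.38
```

The realized multi-locus θ matches the generating drift level, and the
estimator recovers the trait's true Qst of 0.64. That is far above
θ = 0.12, so the bootstrap test flags accelerated divergence (p = 0.0003,
below the 0.05/7 = 0.0071 Bonferroni threshold used for seven nose-shape
traits). The critical ratio 0.38 says the conclusion would survive even if
the between-population heritability were only ~40% of the
within-population one.

The same stages are available from the shell:

```
qstfst simulate --seed 7 --out-dir cohort/
qstfst fst --genotypes cohort/genotypes.tsv --out cohort/theta.tsv
qstfst qstfst-test --pheno cohort/phenotypes.tsv --trait trait \
    --fst cohort/theta.tsv --n-boot 10000 --seed 7 --out cohort/test.json
```

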