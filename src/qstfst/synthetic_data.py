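"""Synthetic cohorts with known ground truth for every pipeline stage.

Genotypes follow the Balding-Nichols model: each SNP has an ancestral
frequency p drawn uniformly from the MAF range, population frequencies are
Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target Weir-Cockerham theta, and
dosages are binomial(2) within population (Hardy-Weinberg).

Polygenic traits decompose as

    trait = population effect + within-population additive deviation
            + environmental noise + covariate effects,

where the population effect combines a genetic part with sample variance
exactly sigma2_gb across populations and an environmental part sized so the
between-population heritability is c; the within-population additive
deviation is a polygenic score from the simulated genotypes (centered
within population, rescaled to pooled variance sigma2_gw) and the noise is
sized so the within-population heritability is h2.  Population effects are
rescaled to their exact target variances -- the populations are fixed study
entities, not random draws -- so the Eq-for-Qst value implied by
(sigma2_gb, sigma2_gw, c, h2) is the true parameter the estimator should
recover up to within-population sampling noise.

Admixed cohorts lay local-ancestry dosages down in geometric-length tracts
along the SNP axis (a desk-scale stand-in for recombination), with
per-individual global ancestry Beta-distributed around the target mean.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, LocalAncestryMatrix

__all__ = [
    "SimConfig",
    "AdmixSimConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_admixed_cohort",
    "simulate_landmarks",
    "simulate_climate",
    "TEMPLATE_LANDMARKS",
]


@dataclass
class SimConfig:
    """Study-style cohort: K discrete populations, drifted SNPs, one trait.

    Defaults mirror the study conditions: four continental populations with
    unbalanced sample sizes, a drift level around the human continental
    scale, and a moderately heritable trait.
    """

    n_pops: int = 4
    n_per_pop: tuple = (40, 236, 127, 73)
    n_snps: int = 10_000
    target_fst: float = 0.12
    maf_range: tuple = (0.05, 0.5)
    sigma2_gb: float = 1.0
    sigma2_gw: float = 1.0
    h2: float = 0.5
    c: float = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 1.0, "age": 0.02, "bmi": 0.05}
    )
    exact_between_variance: bool = True
    seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.n_per_pop):
            self.n_per_pop = (int(self.n_per_pop),) * self.n_pops
        self.n_per_pop = tuple(int(x) for x in self.n_per_pop)
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        if self.n_pops < 1 or min(self.n_per_pop) < 1 or self.n_snps < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0,1)")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5) or (lo == hi == 0):
            raise ValueError("maf_range must be a sub-interval of (0,0.5]")
        if not (0 <= self.h2 <= 1 and 0 <= self.c <= 1):
            raise ValueError("h2 and c must be in [0,1]")
        if self.c > 0 and self.sigma2_gb == 0:
            raise ValueError("c > 0 requires sigma2_gb > 0")
        if self.c == 0 and self.sigma2_gb > 0:
            raise ValueError("sigma2_gb > 0 requires c > 0")

    @property
    def population_names(self) -> list:
        return [f"pop{k + 1}" for k in range(self.n_pops)]


@dataclass
class AdmixSimConfig:
    """Two-way admixed cohort with local-ancestry tracts."""

    n_ind: int = 409
    n_snps: int = 5_000
    ancestry_mean: float = 0.6
    tract_mean_snps: int = 50
    h_y2_target: float = 0.22
    parental_fst: float = 0.15
    ancestry_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.ancestry_mean < 1:
            raise ValueError("ancestry_mean must be in (0,1)")
        if not 0 <= self.h_y2_target <= 1:
            raise ValueError("h_y2_target must be in [0,1]")
        if self.tract_mean_snps < 1:
            raise ValueError("tract_mean_snps must be >= 1")
        if self.n_ind < 2 or self.n_snps < 1:
            raise ValueError("all counts must be positive")


# ---------------------------------------------------------------- genotypes

def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Balding-Nichols genotypes for K labeled populations."""
    rng = np.random.default_rng(cfg.seed)
    F = cfg.target_fst
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    if F == 0:
        pop_freq = np.broadcast_to(p_anc, (cfg.n_pops, cfg.n_snps)).copy()
    else:
        shape = (1.0 - F) / F
        pop_freq = rng.beta(p_anc * shape, (1.0 - p_anc) * shape,
                            size=(cfg.n_pops, cfg.n_snps))

    blocks, pops = [], []
    for k, n_k in enumerate(cfg.n_per_pop):
        blocks.append(rng.binomial(2, pop_freq[k], size=(n_k, cfg.n_snps)))
        pops.extend([cfg.population_names[k]] * n_k)
    dosages = np.vstack(blocks).astype(float)
    ids = np.array([f"ind{i:05d}" for i in range(len(pops))])
    gm = GenotypeMatrix(dosages, ids, np.array(pops),
                        np.array([f"snp{j}" for j in range(cfg.n_snps)]))
    return gm


def _exact_variance(values: np.ndarray, target_var: float,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Center and rescale population effects so the quantity the one-way
    ANOVA estimates is exactly ``target_var``.

    With group sizes n_i the among-group mean square has expectation
    sigma2_w + sum(n_i * a_i^2)/(a-1), and sigma2_pb is that excess divided
    by n0 -- so the effects are centered at their n-weighted mean and scaled
    to sum(n_i * a_i^2) = (a-1) * n0 * target.  Unweighted input reduces to
    fixing the ordinary sample variance (ddof=1).
    """
    a = len(values)
    if target_var == 0 or a < 2:
        return np.zeros_like(values)
    w = np.ones(a) if weights is None else np.asarray(weights, dtype=float)
    v = values - (w @ values) / w.sum()
    if np.all(v == 0):
        v = np.linspace(-1, 1, a)
        v = v - (w @ v) / w.sum()
    n0 = (w.sum() - (w**2).sum() / w.sum()) / (a - 1)
    scale2 = (w @ v**2) / ((a - 1) * n0)
    return v * np.sqrt(target_var / scale2)


def simulate_phenotype(
    genos: GenotypeMatrix, cfg: SimConfig, trait_name: str = "trait"
) -> pd.DataFrame:
    """One polygenic trait plus sex/age/BMI covariates for a labeled cohort.

    Returns a phenotype table (id, population, sex, age, bmi, trait).  The
    generating parameters, including the implied true Qst at c/h2, are
    echoed in ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pops = genos.populations
    pop_names = list(dict.fromkeys(pops))
    K = len(pop_names)
    n = genos.n_individuals
    pop_idx = np.array([pop_names.index(p) for p in pops])

    # Between-population effects.  With exact_between_variance (the default,
    # for parameter-recovery studies) the genetic means are rescaled to
    # sample variance exactly sigma2_gb and the environmental offsets
    # (variance gb*(1-c)/c so the between-pop heritability is c) are
    # orthogonalized against them: the populations are treated as fixed
    # study entities.  With exact_between_variance=False the effects are raw
    # normal draws -- the drift randomness itself, as a neutrality null
    # requires.
    pop_sizes = np.bincount(pop_idx, minlength=K).astype(float)
    if cfg.sigma2_gb > 0 and K > 1:
        env_between_var = cfg.sigma2_gb * (1.0 - cfg.c) / cfg.c
        if cfg.exact_between_variance:
            g_mean = _exact_variance(rng.normal(size=K), cfg.sigma2_gb,
                                     pop_sizes)
            e_mean = rng.normal(size=K)
            if K >= 3 and env_between_var > 0:
                # orthogonal under the n-weighted inner product
                wg = pop_sizes * g_mean
                e_mean = e_mean - (e_mean @ wg) / (g_mean @ wg) * g_mean
            e_mean = _exact_variance(e_mean, env_between_var, pop_sizes)
        else:
            g_mean = rng.normal(0.0, np.sqrt(cfg.sigma2_gb), K)
            e_mean = (rng.normal(0.0, np.sqrt(env_between_var), K)
                      if env_between_var > 0 else np.zeros(K))
    else:
        g_mean = np.zeros(K)
        e_mean = np.zeros(K)

    # within-population additive deviation: polygenic score from genotypes,
    # centered within population so it carries no between-population signal
    if cfg.h2 > 0 and cfg.sigma2_gw > 0:
        p_hat = genos.allele_frequencies()
        keep = (p_hat > 0) & (p_hat < 1)
        z = genos.dosages[:, keep].copy()
        col_mean = np.nanmean(z, axis=0)
        z = np.where(np.isnan(z), col_mean, z)
        z = (z - 2 * p_hat[keep]) / np.sqrt(2 * p_hat[keep] * (1 - p_hat[keep]))
        u = z @ rng.normal(size=z.shape[1]) / np.sqrt(z.shape[1])
        for k in range(K):
            u[pop_idx == k] -= u[pop_idx == k].mean()
        pooled = np.sum(u**2) / (n - K)
        u = u * np.sqrt(cfg.sigma2_gw / pooled) if pooled > 0 else u
        env_within_var = cfg.sigma2_gw * (1.0 - cfg.h2) / cfg.h2
    else:
        # h2 = 0: the within-population variance budget is pure noise
        u = np.zeros(n)
        env_within_var = cfg.sigma2_gw
    e_within = rng.normal(0.0, np.sqrt(env_within_var), n) if env_within_var > 0 \
        else np.zeros(n)

    sex = rng.integers(0, 2, n)            # 0 = F, 1 = M
    age = rng.uniform(18, 40, n)
    bmi = rng.normal(24, 3, n)

    eff = cfg.covariate_effects or {}
    trait = (
        g_mean[pop_idx] + e_mean[pop_idx] + u + e_within
        + eff.get("sex", 0.0) * sex
        + eff.get("age", 0.0) * age
        + eff.get("bmi", 0.0) * bmi
    )

    df = pd.DataFrame(
        {
            "id": genos.individual_ids,
            "population": pops,
            "sex": np.where(sex == 1, "M", "F"),
            "age": age,
            "bmi": bmi,
            trait_name: trait,
        }
    )
    s_pb = cfg.sigma2_gb / cfg.c if cfg.c > 0 else 0.0
    s_pw = cfg.sigma2_gw / cfg.h2 if cfg.h2 > 0 else cfg.sigma2_gw
    r = cfg.c / cfg.h2 if cfg.h2 > 0 else 1.0
    true_qst = (
        cfg.sigma2_gb / (cfg.sigma2_gb + 2 * cfg.sigma2_gw)
        if (cfg.sigma2_gb + cfg.sigma2_gw) > 0
        else 0.0
    )
    df.attrs["truth"] = {
        "sigma2_gb": cfg.sigma2_gb,
        "sigma2_gw": cfg.sigma2_gw,
        "sigma2_pb": s_pb,
        "sigma2_pw": s_pw,
        "h2": cfg.h2,
        "c": cfg.c,
        "c_over_h2": r,
        "true_qst": true_qst,
        "covariate_effects": dict(eff),
        "seed": cfg.seed,
    }
    return df


# ------------------------------------------------------------ admixed cohort

def simulate_admixed_cohort(
    cfg: AdmixSimConfig, trait_name: str = "trait"
) -> tuple[LocalAncestryMatrix, GenotypeMatrix, pd.DataFrame]:
    """Two-way admixed individuals: ancestry tracts, genotypes, one trait.

    Per-individual global ancestry q is Beta-distributed with mean
    ``ancestry_mean``; each haplotype is a Markov chain along SNPs whose
    tracts have geometric length (mean ``tract_mean_snps``) and whose states
    are Bernoulli(q).  Genotype alleles are drawn from the parental
    population frequency indicated by the local ancestry of each haplotype.
    The trait's ancestry-linked genetic component is built from standardized
    local-ancestry dosages, residualized on global ancestry and rescaled so
    the variance it explains equals ``h_y2_target``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_ind, cfg.n_snps
    conc = cfg.ancestry_concentration
    q = rng.beta(cfg.ancestry_mean * conc, (1 - cfg.ancestry_mean) * conc, n)
    q = np.clip(q, 1e-3, 1 - 1e-3)

    # two haplotypes of geometric-tract ancestry per individual
    switch = rng.random((2, n, m)) < 1.0 / cfg.tract_mean_snps
    switch[:, :, 0] = True
    draws = (rng.random((2, n, m)) < q[None, :, None]).astype(np.int8)
    hap = np.empty((2, n, m), dtype=np.int8)
    for h in range(2):
        for i in range(n):
            idx = np.nonzero(switch[h, i])[0]
            states = draws[h, i, idx]
            hap[h, i] = np.repeat(states, np.diff(np.append(idx, m)))
    la = (hap[0] + hap[1]).astype(float)

    # parental allele frequencies from a two-population Balding-Nichols draw
    F = cfg.parental_fst
    p_anc = rng.uniform(0.05, 0.5, m)
    shape = (1.0 - F) / F
    pf = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(2, m))
    freqs = np.where(hap == 1, pf[1][None, None, :], pf[0][None, None, :])
    geno = (rng.random((2, n, m)) < freqs).sum(axis=0).astype(float)

    ids = np.array([f"adm{i:05d}" for i in range(n)])
    snps = np.array([f"snp{j}" for j in range(m)])
    la_mat = LocalAncestryMatrix(la, ids, snps)
    gm = GenotypeMatrix(geno, ids, np.array(["admixed"] * n), snps)

    # trait: ancestry-linked genetic component + noise
    sd = la.std(axis=0)
    keep = sd > 0
    z = (la[:, keep] - la[:, keep].mean(axis=0)) / sd[keep]
    g = z @ rng.normal(size=keep.sum()) / np.sqrt(keep.sum())
    # residualize on global ancestry (a covariate in the estimator)
    qc = q - q.mean()
    g = g - (g @ qc) / (qc @ qc) * qc
    if cfg.h_y2_target > 0 and g.std() > 0:
        g = g / g.std(ddof=1) * np.sqrt(cfg.h_y2_target)
    else:
        g = np.zeros(n)
    e = rng.normal(0, np.sqrt(max(1.0 - cfg.h_y2_target, 0.0)), n)

    sex = rng.integers(0, 2, n)
    age = rng.uniform(18, 40, n)
    bmi = rng.normal(24, 3, n)
    pheno = pd.DataFrame(
        {
            "id": ids,
            "population": "admixed",
            "sex": np.where(sex == 1, "M", "F"),
            "age": age,
            "bmi": bmi,
            "global_ancestry": q,
            trait_name: g + e,
        }
    )
    pheno.attrs["truth"] = {
        "h_y2": cfg.h_y2_target,
        "ancestry_mean": cfg.ancestry_mean,
        "seed": cfg.seed,
    }
    return la_mat, gm, pheno


# ------------------------------------------------------------------ landmarks

# template nose landmark coordinates (mm), origin near the subnasale;
# magnitudes chosen to give adult-scale linear distances
TEMPLATE_LANDMARKS = {
    "n": (0.0, 50.0, 0.0),
    "prn": (0.0, 16.0, 18.0),
    "sn": (0.0, 0.0, 8.0),
    "al_l": (-17.0, 8.0, 6.0),
    "al_r": (17.0, 8.0, 6.0),
    "ac_l": (-18.0, 4.0, 2.0),
    "ac_r": (18.0, 4.0, 2.0),
}


def simulate_landmarks(
    n_ind: int,
    pop_offsets: dict | None = None,
    noise_sd: float = 0.2,
    n_observers: int = 2,
    n_reps: int = 3,
    seed: int = 0,
    subject_sd: float = 1.5,
) -> pd.DataFrame:
    """Replicated 3D landmark placements for simulated subjects.

    ``pop_offsets`` maps population -> {landmark: (dx,dy,dz)}; ``n_ind``
    individuals are simulated per population (one unnamed population when
    None).  Each subject perturbs the template by iid N(0, subject_sd) per
    coordinate; each observer x replicate placement adds iid N(0, noise_sd).
    Long-format output: id, population, observer, replicate, landmark,
    x, y, z (mm).
    """
    if n_ind < 1 or n_observers < 1 or n_reps < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    pops = pop_offsets or {"pop1": {}}
    rows = []
    i = 0
    for pop, offsets in pops.items():
        base = {
            lm: np.asarray(TEMPLATE_LANDMARKS[lm]) + np.asarray(
                offsets.get(lm, (0.0, 0.0, 0.0))
            )
            for lm in TEMPLATE_LANDMARKS
        }
        for _ in range(n_ind):
            ind = f"lm{i:05d}"
            i += 1
            subj = {
                lm: base[lm] + rng.normal(0, subject_sd, 3) for lm in base
            }
            for obs in range(1, n_observers + 1):
                for rep in range(1, n_reps + 1):
                    for lm, xyz in subj.items():
                        placed = xyz + rng.normal(0, noise_sd, 3) \
                            if noise_sd > 0 else xyz
                        rows.append(
                            {
                                "id": ind,
                                "population": pop,
                                "observer": f"obs{obs}",
                                "replicate": rep,
                                "landmark": lm,
                                "x": placed[0],
                                "y": placed[1],
                                "z": placed[2],
                            }
                        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- climate

def simulate_climate(
    pheno: pd.DataFrame,
    pop_climate: dict,
    within_sd: dict | float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-individual climate values: population mean + within-pop noise.

    ``pop_climate`` maps population -> {variable: mean}; ``within_sd`` is a
    single spread or a {variable: sd} map.  Output joins to the phenotype
    table on ``id``.
    """
    rng = np.random.default_rng(seed)
    pops = pheno["population"].astype(str)
    missing = sorted(set(pops) - set(map(str, pop_climate)))
    if missing:
        raise ValueError(f"no climate means for populations: {missing}")
    variables = sorted({v for d in pop_climate.values() for v in d})
    out = {"id": pheno["id"].to_numpy()}
    for var in variables:
        mu = pops.map({str(k): d.get(var, np.nan) for k, d in
                       pop_climate.items()}).to_numpy(float)
        sd = within_sd.get(var, 0.0) if isinstance(within_sd, dict) else within_sd
        out[var] = mu + (rng.normal(0, sd, len(mu)) if sd > 0 else 0.0)
    return pd.DataFrame(out)
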