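"""Weir & Cockerham (1984) theta: per-SNP and multi-locus Fst.

The estimator decomposes allele-frequency variance at each biallelic locus
into among-population (a), between-individual-within-population (b) and
within-individual (c) components, using observed heterozygote frequencies
rather than assuming Hardy-Weinberg proportions.  Per-SNP theta is
a/(a+b+c); the multi-locus estimate is the ratio of summed components
(ratio-of-sums, the standard Weir & Cockerham combination), not the mean of
per-SNP ratios.  Negative per-SNP values are retained: the bootstrap in the
divergence test resamples from the realized distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

__all__ = ["FstDistribution", "wc_theta"]


@dataclass
class FstDistribution:
    """Per-SNP Weir-Cockerham theta values plus their a/(a+b+c) components.

    Attributes
    ----------
    snp_ids : array of SNP identifiers for the loci retained.
    theta : per-SNP theta (may be negative; NaN-free).
    a, bc : among-population component and the within (b+c) remainder per SNP.
    theta_multilocus : sum(a) / sum(a+b+c) over retained loci.
    n_snps_used : loci entering the distribution.
    n_snps_dropped : monomorphic / undefined loci excluded (logged count).
    """

    snp_ids: np.ndarray
    theta: np.ndarray
    a: np.ndarray
    bc: np.ndarray
    theta_multilocus: float
    n_snps_used: int
    n_snps_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "theta": self.theta,
                "a": self.a,
                "b_plus_c": self.bc,
            }
        )

    def summary(self) -> dict:
        return {
            "theta_multilocus": float(self.theta_multilocus),
            "n_snps_used": int(self.n_snps_used),
            "n_snps_dropped": int(self.n_snps_dropped),
            "theta_mean": float(np.mean(self.theta)),
            "theta_median": float(np.median(self.theta)),
        }


def wc_theta(genos: GenotypeMatrix) -> FstDistribution:
    """Weir-Cockerham theta across the labeled populations.

    Missing dosages (NaN) are excluded per SNP.  A SNP is dropped when it is
    monomorphic over all genotyped individuals, or when fewer than two
    populations have any genotyped individual, or when the a+b+c denominator
    is zero.  Raises ``ValueError`` if nothing survives.
    """
    dos = np.asarray(genos.dosages, dtype=float)
    pops = np.asarray(genos.populations)
    pop_names = np.unique(pops)
    r = len(pop_names)
    if r < 2:
        raise ValueError("need at least two populations for theta")

    n_ind, n_snp = dos.shape
    obs = ~np.isnan(dos)

    # per-population, per-SNP: sample size, allele frequency, het frequency
    n_i = np.zeros((r, n_snp))
    p_i = np.zeros((r, n_snp))
    h_i = np.zeros((r, n_snp))
    for k, name in enumerate(pop_names):
        rows = pops == name
        ob = obs[rows]
        d = dos[rows]
        cnt = ob.sum(axis=0)
        n_i[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(cnt > 0, np.nansum(d, axis=0) / (2 * cnt), np.nan)
            h_i[k] = np.where(cnt > 0, np.nansum(d == 1, axis=0) / cnt, np.nan)

    a, b, c = _wc_components(n_i, p_i, h_i)
    denom = a + b + c
    pbar_all = np.nansum(n_i * p_i, axis=0) / np.maximum(np.nansum(n_i, axis=0), 1)
    polymorphic = (pbar_all > 0) & (pbar_all < 1)
    enough_pops = (n_i > 0).sum(axis=0) >= 2
    keep = polymorphic & enough_pops & np.isfinite(denom) & (denom != 0)

    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("no polymorphic SNPs with >=2 genotyped populations")

    theta = a[keep] / denom[keep]
    theta_ml = float(a[keep].sum() / denom[keep].sum())
    return FstDistribution(
        snp_ids=np.asarray(genos.snp_ids)[keep],
        theta=theta,
        a=a[keep],
        bc=(b + c)[keep],
        theta_multilocus=theta_ml,
        n_snps_used=n_used,
        n_snps_dropped=int(n_snp - n_used),
    )


def _wc_components(n_i, p_i, h_i):
    """Vectorized a, b, c variance components per SNP.

    n_i, p_i, h_i are (n_pops, n_snps); populations with n_i == 0 at a SNP
    contribute nothing and reduce the effective number of populations r.
    """
    present = n_i > 0
    r_eff = present.sum(axis=0).astype(float)
    n_i = np.where(present, n_i, 0.0)
    p_i = np.where(present, p_i, 0.0)
    h_i = np.where(present, h_i, 0.0)

    n_tot = n_i.sum(axis=0)
    nbar = n_tot / np.maximum(r_eff, 1)
    # nc: the variance-corrected average sample size
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / np.maximum(r_eff - 1, 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / (np.maximum(r_eff - 1, 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot

        inner = pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar)
            - (r_eff - 1) / r_eff * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c
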