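"""Phenotypic variance components across populations and Qst.

Qst measures the fraction of additive genetic variance that lies between
populations, sigma2_gb / (sigma2_gb + 2 sigma2_gw).  With phenotypes only,
the genetic components are replaced by phenotypic ones scaled by the
between- and within-population heritabilities c and h2:

    Qst(r) = r * sigma2_pb / (r * sigma2_pb + 2 * sigma2_pw),  r = c / h2.

The phenotypic components come from a fixed-effects linear model with the
population label as the effect of interest and sex, age and BMI as nuisance
covariates.  MSB is the marginal (type-II) mean square for population, MSW
the residual mean square; sigma2_pw = MSW and sigma2_pb = (MSB - MSW) / n0
with n0 the effective per-group size

    n0 = (sum n_i - sum n_i^2 / sum n_i) / (a - 1).

Negative sigma2_pb estimates are clamped to zero (a variance cannot be
negative, and clamping keeps Qst well-defined); the clamp is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "QstEstimate",
    "variance_components",
    "variance_components_from_cells",
    "load_published_cells",
    "qst_value",
    "qst_from_components",
]

DEFAULT_COVARIATES = ("sex", "age", "bmi")


@dataclass
class VarianceComponents:
    a: int                  # number of populations
    n_i: np.ndarray         # per-population counts
    n0: float               # effective per-group size
    msb: float              # mean square among populations (marginal)
    msw: float              # residual mean square
    sigma2_pb: float        # among-population phenotypic variance (clamped >= 0)
    sigma2_pw: float        # within-population phenotypic variance
    f_stat: float
    p_value: float
    n_used: int
    n_dropped: int          # rows removed for missing trait/covariates
    clamped: bool = False


@dataclass
class QstEstimate:
    trait: str
    qst: float
    c_over_h2: float


def _design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Return (X_reduced, X_full): covariate design without / with population
    dummies.  Sex is dummy-coded if non-numeric."""
    n = len(df)
    cols = [np.ones(n)]
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            for level in sorted(v.astype(str).unique())[1:]:
                cols.append((v.astype(str) == level).to_numpy(float))
        else:
            cols.append(v.to_numpy(float))
    x_red = np.column_stack(cols)
    pops = sorted(df["population"].astype(str).unique())
    pop_cols = [
        (df["population"].astype(str) == p).to_numpy(float) for p in pops[1:]
    ]
    x_full = np.column_stack([x_red] + pop_cols) if pop_cols else x_red
    return x_red, x_full


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank from least squares."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def variance_components(
    pheno: pd.DataFrame,
    trait: str,
    covariates=DEFAULT_COVARIATES,
) -> VarianceComponents:
    """Estimate MSB/MSW/n0 and the phenotypic variance components for a trait.

    ``pheno`` needs columns ``population``, the trait, and the covariates.
    Rows with a missing trait or covariate are dropped listwise (count
    reported on the result).  Requires >= 2 populations with >= 2 individuals
    each and positive residual degrees of freedom.
    """
    covariates = [c for c in covariates if c in pheno.columns]
    needed = ["population", trait, *covariates]
    df = pheno[needed].dropna()
    n_dropped = len(pheno) - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing %s/covariates", n_dropped, trait)

    counts = df.groupby("population").size()
    a = len(counts)
    if a < 2:
        raise ValueError("need at least two populations")
    if (counts < 2).any():
        raise ValueError(
            f"populations with <2 individuals: {list(counts[counts < 2].index)}"
        )

    y = df[trait].to_numpy(float)
    x_red, x_full = _design(df, covariates)
    rss_full, rank_full = _rss(y, x_full)
    rss_red, _ = _rss(y, x_red)

    n = len(df)
    df_pop = a - 1
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    msb = (rss_red - rss_full) / df_pop
    msw = rss_full / df_resid

    n_i = counts.to_numpy(float)
    n_tot = n_i.sum()
    n0 = (n_tot - (n_i**2).sum() / n_tot) / (a - 1)

    sigma2_pb = (msb - msw) / n0
    clamped = sigma2_pb < 0
    if clamped:
        logger.info("negative sigma2_pb (%.4g) clamped to 0 for %s", sigma2_pb, trait)
        sigma2_pb = 0.0

    from scipy import stats

    f_stat = msb / msw
    p_value = float(stats.f.sf(f_stat, df_pop, df_resid))

    return VarianceComponents(
        a=a,
        n_i=n_i,
        n0=float(n0),
        msb=float(msb),
        msw=float(msw),
        sigma2_pb=float(sigma2_pb),
        sigma2_pw=float(msw),
        f_stat=float(f_stat),
        p_value=p_value,
        n_used=n,
        n_dropped=n_dropped,
        clamped=bool(clamped),
    )


def variance_components_from_cells(
    cells: pd.DataFrame, trait: str | None = None
) -> VarianceComponents:
    """Sex-adjusted variance components from population-by-sex summaries.

    ``cells`` has one row per population x sex cell with columns
    ``population``, ``sex``, ``n``, ``mean``, ``sd`` (and optionally
    ``trait`` to select from a long table).  The additive model
    intercept + sex + population is fit by weighted least squares on the
    cell means; within-cell sums of squares (n-1)*sd^2 complete the exact
    individual-level ANOVA.  Age/BMI adjustment is impossible from
    summaries, so these components match the full covariate model only for
    traits with weak age/BMI dependence.
    """
    df = cells
    if trait is not None:
        df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"no cells for trait {trait!r}")
    pops = sorted(df["population"].astype(str).unique())
    a = len(pops)
    if a < 2:
        raise ValueError("need at least two populations")

    n = df["n"].to_numpy(float)
    mean = df["mean"].to_numpy(float)
    sd = df["sd"].to_numpy(float)
    sexes = sorted(df["sex"].astype(str).unique())

    def rss(with_pop: bool) -> float:
        cols = [np.ones(len(df))]
        cols += [(df["sex"].astype(str) == s).to_numpy(float)
                 for s in sexes[1:]]
        if with_pop:
            cols += [(df["population"].astype(str) == p).to_numpy(float)
                     for p in pops[1:]]
        x = np.column_stack(cols)
        w = np.sqrt(n)
        beta, _, _, _ = np.linalg.lstsq(x * w[:, None], mean * w, rcond=None)
        between = float(n @ (mean - x @ beta) ** 2)
        within = float(((n - 1) * sd**2).sum())
        return within + between

    rank_full = 1 + (len(sexes) - 1) + (a - 1)
    n_tot = n.sum()
    df_resid = n_tot - rank_full
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    msb = (rss(False) - rss(True)) / (a - 1)
    msw = rss(True) / df_resid

    n_i = df.groupby("population")["n"].sum().to_numpy(float)
    n0 = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (a - 1)
    sigma2_pb = (msb - msw) / n0
    clamped = sigma2_pb < 0
    sigma2_pb = max(sigma2_pb, 0.0)

    from scipy import stats

    return VarianceComponents(
        a=a, n_i=n_i, n0=float(n0), msb=float(msb), msw=float(msw),
        sigma2_pb=float(sigma2_pb), sigma2_pw=float(msw),
        f_stat=float(msb / msw),
        p_value=float(stats.f.sf(msb / msw, a - 1, df_resid)),
        n_used=int(n_tot), n_dropped=0, clamped=bool(clamped),
    )


def load_published_cells() -> pd.DataFrame:
    """The packaged population-by-sex cell summaries of the study cohort."""
    from importlib import resources

    with resources.files("qstfst.data").joinpath("cohort_cells.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def qst_value(
    vc: VarianceComponents, c_over_h2: float = 1.0, trait: str = ""
) -> QstEstimate:
    """Qst at a given c/h2 ratio from estimated phenotypic components."""
    if c_over_h2 <= 0:
        raise ValueError("c_over_h2 must be positive")
    return QstEstimate(
        trait=trait,
        qst=qst_from_components(vc.sigma2_pb, vc.sigma2_pw, c_over_h2),
        c_over_h2=float(c_over_h2),
    )


def qst_from_components(
    sigma2_pb: float | np.ndarray,
    sigma2_pw: float | np.ndarray,
    c_over_h2: float | np.ndarray = 1.0,
) -> float | np.ndarray:
    """Vectorized Qst(r) = r*s_pb / (r*s_pb + 2*s_pw); 0 where s_pb == 0."""
    num = c_over_h2 * sigma2_pb
    den = num + 2.0 * sigma2_pw
    out = np.divide(num, den, out=np.zeros_like(np.asarray(den, dtype=float)),
                    where=np.asarray(den) > 0)
    return float(out) if np.ndim(out) == 0 else out
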