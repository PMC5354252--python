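"""Stratified-bootstrap Qst-Fst comparison and c/h2 sensitivity analysis.

The test asks whether a trait is more differentiated across populations than
neutral genetic markers.  Pseudo-samples are drawn by resampling individuals
with replacement *within population-by-sex strata*, so every stratum keeps
its observed size; Qst is recomputed on each pseudo-sample with the same
covariate model.  Each pseudo-sample is paired with a draw from the realized
per-SNP theta distribution, and the empirical p-value is the proportion of
Qst - Fst differences below zero.

Because Qst(r) at any c/h2 ratio r is a deterministic function of the stored
per-draw variance components (Qst(r) = r*s_pb/(r*s_pb + 2*s_pw)), the
sensitivity curve over a grid of ratios reuses the same draws without
re-resampling.  The critical ratio is the smallest grid value where the
2.5% Qst quantile reaches the 97.5% Fst quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import FstDistribution
from .qst import DEFAULT_COVARIATES, _design, qst_from_components, variance_components

__all__ = [
    "QstDraws",
    "BootstrapResult",
    "SensitivityCurve",
    "bootstrap_qst",
    "qst_fst_test",
    "bonferroni_report",
    "sensitivity_curve",
    "DEFAULT_RATIO_GRID",
]

DEFAULT_N_BOOT = 10_000
DEFAULT_RATIO_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class QstDraws:
    """Per-pseudo-sample variance components for one trait.

    ``sigma2_pb`` is stored unclamped; Qst evaluation clamps at zero per
    draw so ratio rescaling stays consistent with the point estimator.
    """

    trait: str
    sigma2_pb: np.ndarray
    sigma2_pw: np.ndarray
    observed_qst: float
    observed_pb: float
    observed_pw: float
    n_boot: int
    seed: int

    def qst(self, c_over_h2: float = 1.0) -> np.ndarray:
        return qst_from_components(
            np.clip(self.sigma2_pb, 0.0, None), self.sigma2_pw, c_over_h2
        )


@dataclass
class BootstrapResult:
    trait: str
    qst_draws: np.ndarray
    fst_draws: np.ndarray
    observed_qst: float
    p_value: float          # 0.0 means "no draw below zero"; see p_label
    p_label: str
    n_boot: int
    seed: int

    @property
    def qst_minus_fst(self) -> np.ndarray:
        return self.qst_draws - self.fst_draws


@dataclass
class SensitivityCurve:
    trait: str
    ratios: np.ndarray
    qst_median: np.ndarray
    qst_lo: np.ndarray
    qst_hi: np.ndarray
    fst_median: float
    fst_lo: float
    fst_hi: float
    critical_ratio: float | None   # None when never reached within the grid
    critical_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c_over_h2": self.ratios,
                "qst_median": self.qst_median,
                "qst_lo": self.qst_lo,
                "qst_hi": self.qst_hi,
                "fst_median": self.fst_median,
                "fst_lo": self.fst_lo,
                "fst_hi": self.fst_hi,
            }
        )


def bootstrap_qst(
    pheno: pd.DataFrame,
    trait: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
    strata=("population", "sex"),
) -> QstDraws:
    """Stratified bootstrap of the Qst variance components.

    Individuals are resampled with replacement within each stratum (by
    default population x sex) so stratum sizes never change.  Components per
    draw come from the same fixed-effects model as the point estimate but
    through a fast two-regression path (full model vs. population dropped).
    """
    covariates = [c for c in covariates if c in pheno.columns]
    df = pheno[["population", trait, *covariates]].dropna().reset_index(drop=True)
    strata = [s for s in strata if s in df.columns]
    groups = df.groupby(strata, observed=True).indices
    empty = [k for k, v in groups.items() if len(v) == 0]
    if empty:
        raise ValueError(f"empty strata: {empty}")

    vc0 = variance_components(df, trait, covariates)
    observed = qst_from_components(vc0.sigma2_pb, vc0.sigma2_pw, 1.0)

    y = df[trait].to_numpy(float)
    x_red, x_full = _design(df, covariates)
    pops = df["population"].astype(str).to_numpy()
    counts = pd.Series(pops).value_counts()
    a = len(counts)
    n = len(df)
    n_i = counts.to_numpy(float)
    n0 = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (a - 1)
    df_pop = a - 1

    rng = np.random.default_rng(seed)
    stratum_idx = [np.asarray(v) for v in groups.values()]

    pb = np.empty(n_boot)
    pw = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rows[rng.integers(0, len(rows), len(rows))] for rows in stratum_idx]
        )
        yb = y[idx]
        xf = x_full[idx]
        xr = x_red[idx]
        bf, _, rank_f, _ = np.linalg.lstsq(xf, yb, rcond=None)
        rf = yb - xf @ bf
        br, _, _, _ = np.linalg.lstsq(xr, yb, rcond=None)
        rr = yb - xr @ br
        df_resid = n - rank_f
        msb = (rr @ rr - rf @ rf) / df_pop
        msw = (rf @ rf) / df_resid
        pb[b] = (msb - msw) / n0
        pw[b] = msw

    return QstDraws(
        trait=trait,
        sigma2_pb=pb,
        sigma2_pw=pw,
        observed_qst=observed,
        observed_pb=vc0.sigma2_pb,
        observed_pw=vc0.sigma2_pw,
        n_boot=n_boot,
        seed=seed,
    )


def draw_fst(
    fst_dist: FstDistribution,
    n_boot: int,
    rng: np.random.Generator,
    multilocus_resample: bool = False,
    block: int | None = None,
) -> np.ndarray:
    """Fst values paired with the Qst pseudo-samples.

    Default: one per-SNP theta drawn uniformly with replacement per
    pseudo-sample.  With ``multilocus_resample`` each draw is instead a
    ratio-of-sums theta over a resampled block of SNPs (size ``block``,
    default all SNPs) -- a smoother alternative reading of the procedure.
    """
    m = len(fst_dist.theta)
    if m == 0:
        raise ValueError("empty Fst distribution")
    if not multilocus_resample:
        return fst_dist.theta[rng.integers(0, m, n_boot)]
    k = block or m
    idx = rng.integers(0, m, (n_boot, k))
    return fst_dist.a[idx].sum(axis=1) / (
        fst_dist.a[idx] + fst_dist.bc[idx]
    ).sum(axis=1)


def qst_fst_test(
    qst_draws: QstDraws,
    fst_dist: FstDistribution,
    seed: int = 0,
    c_over_h2: float = 1.0,
    multilocus_resample: bool = False,
) -> BootstrapResult:
    """Pair Qst pseudo-samples with Fst draws; empirical p = P(Qst-Fst < 0)."""
    rng = np.random.default_rng(seed)
    n_boot = qst_draws.n_boot
    fst = draw_fst(fst_dist, n_boot, rng, multilocus_resample)
    qst = qst_draws.qst(c_over_h2)
    diff = qst - fst
    n_below = int((diff < 0).sum())
    p = n_below / n_boot
    label = f"<{1.0 / n_boot:g}" if n_below == 0 else f"{p:g}"
    return BootstrapResult(
        trait=qst_draws.trait,
        qst_draws=qst,
        fst_draws=fst,
        observed_qst=qst_draws.observed_qst,
        p_value=p,
        p_label=label,
        n_boot=n_boot,
        seed=seed,
    )


def bonferroni_report(
    p_values: dict[str, float], alpha: float = 0.05, n_tests: int = 7
) -> pd.DataFrame:
    """Flag traits with p strictly below alpha / n_tests."""
    thr = alpha / n_tests
    rows = []
    for trait, p in p_values.items():
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of range for {trait}: {p}")
        rows.append(
            {"trait": trait, "p_value": p, "threshold": thr,
             "accelerated_divergence": bool(p < thr)}
        )
    return pd.DataFrame(rows)


def sensitivity_curve(
    qst_draws: QstDraws,
    fst_draws: np.ndarray,
    grid: np.ndarray = DEFAULT_RATIO_GRID,
    ci: float = 0.95,
) -> SensitivityCurve:
    """Qst(r) quantile bands over a c/h2 grid and the critical ratio.

    The critical ratio is the smallest grid value at which the lower Qst
    bound meets the upper Fst bound; a trait whose lower bound never reaches
    it within the grid is flagged ">r_max".
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty ratio grid")
    if not (np.all(np.diff(grid) > 0) and grid[0] > 0):
        raise ValueError("grid must be increasing and positive")

    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    pb = np.clip(qst_draws.sigma2_pb, 0.0, None)
    pw = qst_draws.sigma2_pw
    qst_mat = qst_from_components(pb[None, :], pw[None, :], grid[:, None])

    q_med = np.median(qst_mat, axis=1)
    q_lo = np.quantile(qst_mat, lo_q, axis=1)
    q_hi = np.quantile(qst_mat, hi_q, axis=1)
    f_med = float(np.median(fst_draws))
    f_lo = float(np.quantile(fst_draws, lo_q))
    f_hi = float(np.quantile(fst_draws, hi_q))

    reached = np.nonzero(q_lo >= f_hi)[0]
    if reached.size:
        crit = float(grid[reached[0]])
        label = f"{crit:g}"
    else:
        crit = None
        label = f">{grid[-1]:g}"

    return SensitivityCurve(
        trait=qst_draws.trait,
        ratios=grid,
        qst_median=q_med,
        qst_lo=q_lo,
        qst_hi=q_hi,
        fst_median=f_med,
        fst_lo=f_lo,
        fst_hi=f_hi,
        critical_ratio=crit,
        critical_label=label,
    )


def critical_ratio_closed_form(
    sigma2_pb: float, sigma2_pw: float, fst: float
) -> float:
    """Noise-free critical ratio: solve r*s_pb/(r*s_pb + 2*s_pw) = fst.

    Used as an algebraic cross-check of the grid search when the component
    draws are degenerate (no sampling noise) and Fst is a point value.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0,1)")
    if sigma2_pb <= 0:
        raise ValueError("sigma2_pb must be positive")
    return 2.0 * sigma2_pw * fst / (sigma2_pb * (1.0 - fst))
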