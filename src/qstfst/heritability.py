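"""Kinship matrices and single-component REML heritability.

The genetic relationship matrix (GRM) between individuals i and j averages
(x_i - 2p)(x_j - 2p) / (2p(1-p)) over SNPs, with p the pooled sample allele
frequency -- the standard standardized-genotype construction, so the
diagonal averages ~1.  The same construction applied to local-ancestry
dosages in an admixed cohort yields an ancestry kinship matrix; the variance
a trait's REML fit attributes to it (h_y2) estimates the between-population
heritability c, because local ancestry carries only the between-population
part of the genetic variation.

REML fits y = Xb + g + e with g ~ N(0, K sg2), e ~ N(0, I se2).  After an
eigendecomposition K = U D U', the rotated model is diagonal and the REML
log-likelihood is a smooth one-dimensional function of h2 = sg2/(sg2+se2),
maximized by bounded Brent search; the total variance is profiled out.  The
standard error comes from the observed information (numerical second
derivative of the profile REML log-likelihood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .types import GenotypeMatrix, KinshipMatrix, LocalAncestryMatrix

logger = logging.getLogger(__name__)

__all__ = ["HeritabilityEstimate", "grm", "ancestry_grm", "top_pcs", "reml_h2"]

_H2_TOL = 1e-6


def _standardized_grm(dos: np.ndarray, skip_desc: str):
    """Shared GRM construction for genotype or ancestry dosages."""
    dos = np.asarray(dos, dtype=float)
    # mean-impute missing per SNP
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos = dos.copy()
        dos[nan_r, nan_c] = col_mean[nan_c]
    p = dos.mean(axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    # skip SNPs that are monomorphic in expectation (p in {0,1}) or carry no
    # sample variance at all (e.g. every individual dosage 1)
    keep = (var > 0) & (dos.std(axis=0) > 0)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipped %d %s SNPs", n_skipped, skip_desc)
    if not keep.any():
        raise ValueError(f"all SNPs {skip_desc}; cannot build kinship")
    z = (dos[:, keep] - 2.0 * p[keep]) / np.sqrt(var[keep])
    m = int(keep.sum())
    return (z @ z.T) / m, m


def grm(genos: GenotypeMatrix) -> KinshipMatrix:
    """Standardized genotype GRM; monomorphic SNPs skipped, missing dosages
    mean-imputed per SNP."""
    if genos.n_individuals < 2:
        raise ValueError("need at least two individuals")
    values, m = _standardized_grm(genos.dosages, "monomorphic")
    return KinshipMatrix(values, genos.individual_ids, source="genotype", n_markers=m)


def ancestry_grm(la: LocalAncestryMatrix) -> KinshipMatrix:
    """Local-ancestry kinship: same construction on ancestry dosages."""
    values, m = _standardized_grm(la.dosages, "zero-ancestry-variance")
    return KinshipMatrix(
        values, la.individual_ids, source="local-ancestry", n_markers=m
    )


def top_pcs(K: KinshipMatrix, k: int = 4) -> np.ndarray:
    """Leading k principal components of the kinship matrix.

    Columns are eigenvectors scaled by sqrt(eigenvalue), with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    n = len(K.individual_ids)
    if k >= n:
        raise ValueError("k must be < number of individuals")
    w, v = np.linalg.eigh(K.values)
    order = np.argsort(w)[::-1][:k]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    for j in range(k):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v * np.sqrt(w)


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    kind: str              # "h_g2" or "h_y2"
    n: int
    covariates: list
    boundary: bool = False


def _rotate(y, X, K_values):
    """Eigen-rotation shared by REML here and the ML fits in climate_assoc."""
    w, U = np.linalg.eigh(K_values)
    neg = w < 0
    if neg.any():
        if w.min() < -1e-6:
            logger.warning("kinship has negative eigenvalues (min %.3g); clipped",
                           w.min())
        w = np.clip(w, 0.0, None)
    return w, U.T @ y, U.T @ X


def _reml_neg_loglik(h2, w, yt, Xt):
    """Negative profile REML log-likelihood at heritability h2 (variance
    profiled out), up to an additive constant."""
    n, p = Xt.shape
    v = h2 * w + (1.0 - h2)          # eigenvalues of V / total variance
    if np.any(v <= 0):
        return np.inf
    vi = 1.0 / v
    xtvx = Xt.T @ (Xt * vi[:, None])
    try:
        beta = np.linalg.solve(xtvx, Xt.T @ (yt * vi))
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    rss = float(r @ (r * vi))
    if rss <= 0:
        return np.inf
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.sum(np.log(v))
        + logdet_xtvx
        + (n - p)
    )
    return -ll


def reml_h2(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix,
    kind: str = "h_g2",
    covariate_names: list | None = None,
) -> HeritabilityEstimate:
    """REML estimate of h2 = sg2/(sg2+se2) with fixed effects X.

    X must contain the intercept.  Returns the variance components on the
    phenotypic scale, the REML log-likelihood (up to a constant), and an SE
    from the observed information; estimates on the [0,1] boundary are
    flagged and their SE is computed from the one-sided curvature.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n or K.values.shape[0] != n:
        raise ValueError("y, X, K are not conformable")
    p = np.linalg.matrix_rank(X)
    if n <= p:
        raise ValueError("n must exceed rank(X)")

    w, yt, Xt = _rotate(y, X, K.values)

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, 1.0), args=(w, yt, Xt),
        method="bounded", options={"xatol": _H2_TOL},
    )
    h2 = float(res.x)
    nll = float(res.fun)
    if not np.isfinite(nll):
        raise ValueError("non-finite REML likelihood")
    # snap to boundary when the optimum sits against it
    for edge in (0.0, 1.0 - 1e-9):
        if abs(h2 - edge) < 5e-6 or _reml_neg_loglik(edge, w, yt, Xt) <= nll:
            if _reml_neg_loglik(edge, w, yt, Xt) <= nll:
                h2, nll = edge, float(_reml_neg_loglik(edge, w, yt, Xt))
    boundary = h2 < 1e-4 or h2 > 1 - 1e-4

    # total variance at the optimum, for reporting sg2/se2
    v = h2 * w + (1.0 - h2)
    vi = 1.0 / v
    xtvx = Xt.T @ (Xt * vi[:, None])
    beta = np.linalg.solve(xtvx, Xt.T @ (yt * vi))
    r = yt - Xt @ beta
    sigma_p2 = float(r @ (r * vi)) / (n - X.shape[1])

    # observed information from a central/one-sided second difference
    eps = 1e-4
    lo = min(max(h2 - eps, 0.0), 1.0 - 2 * eps)
    f0, f1, f2 = (
        _reml_neg_loglik(lo, w, yt, Xt),
        _reml_neg_loglik(lo + eps, w, yt, Xt),
        _reml_neg_loglik(lo + 2 * eps, w, yt, Xt),
    )
    info = (f0 - 2 * f1 + f2) / eps**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")

    return HeritabilityEstimate(
        h2=h2,
        se=se,
        sigma_g2=h2 * sigma_p2,
        sigma_e2=(1.0 - h2) * sigma_p2,
        loglik=-nll,
        kind=kind,
        n=n,
        covariates=covariate_names or [],
        boundary=boundary,
    )
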