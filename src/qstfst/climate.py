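"""Humidity derivation and kinship-corrected phenotype-climate association.

Climate exposure per individual is the long-term mean at the parents'
birthplaces (mean of the two parents where both are known).  Relative and
absolute humidity are derived from temperature and vapor pressure: the
Magnus form for saturation vapor pressure and the ideal-gas water-vapor
density for absolute humidity.

The association test fits y = Xb + eps with Var(eps) = sg2*K + se2*I,
where K is the genome-wide kinship matrix, X holds intercept, climate
variable, age and BMI (sex omitted when the cohort is single-sex).  The
variance ratio is estimated by maximum likelihood (not REML: ML likelihoods
are comparable across fixed-effect structures), the slope and its SE come
from generalized least squares at the ML ratio, and significance from the
likelihood-ratio test against the model with the climate column dropped,
referred to chi-square with 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .heritability import _rotate
from .types import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "saturation_vapor_pressure",
    "relative_humidity",
    "absolute_humidity",
    "ancestral_climate",
    "kinship_lmm_slope",
    "leave_one_population_out",
]


# ---------------------------------------------------------------- humidity

def saturation_vapor_pressure(t_celsius):
    """Magnus saturation vapor pressure (hPa) at temperature T (deg C)."""
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -243.04):
        raise ValueError("temperature at or below -243.04 C")
    out = 6.1094 * np.exp(17.625 * t / (t + 243.04))
    return float(out) if np.ndim(t_celsius) == 0 else out


def relative_humidity(e_hpa, t_celsius):
    """RH (%) = 100 * e / es(T), capped at 100 with a warning."""
    e = np.asarray(e_hpa, dtype=float)
    if np.any(e < 0):
        raise ValueError("vapor pressure must be non-negative")
    rh = 100.0 * e / saturation_vapor_pressure(t_celsius)
    if np.any(rh > 100.0):
        warnings.warn("relative humidity above 100% capped", stacklevel=2)
        rh = np.minimum(rh, 100.0)
    return float(rh) if np.ndim(e_hpa) == 0 else rh


def absolute_humidity(e_hpa, t_celsius):
    """Water-vapor density (g/m^3) = 216.7 * e[hPa] / T[K] (Rv = 461.5)."""
    e = np.asarray(e_hpa, dtype=float)
    t = np.asarray(t_celsius, dtype=float)
    if np.any(e < 0):
        raise ValueError("vapor pressure must be non-negative")
    ah = 216.7 * e / (t + 273.15)
    return float(ah) if np.ndim(e_hpa) == 0 else ah


CLIMATE_VARS = ["temperature", "vapor_pressure", "uvb",
                "relative_humidity", "absolute_humidity"]


def ancestral_climate(parent_climate: pd.DataFrame) -> pd.DataFrame:
    """Per-individual ancestral climate from parents' birthplace values.

    ``parent_climate`` has one row per parent: columns ``id`` plus any of
    the climate variables; NaN rows for a missing parent are ignored, so a
    single known parent passes through unchanged.  Derived humidity columns
    are added when temperature and vapor pressure are present.
    """
    if "id" not in parent_climate.columns:
        raise ValueError("parent climate table needs an 'id' column")
    value_cols = [c for c in parent_climate.columns if c != "id"]
    out = parent_climate.groupby("id", sort=False)[value_cols].mean().reset_index()
    if {"temperature", "vapor_pressure"} <= set(out.columns):
        out["relative_humidity"] = relative_humidity(
            out["vapor_pressure"].to_numpy(), out["temperature"].to_numpy()
        )
        out["absolute_humidity"] = absolute_humidity(
            out["vapor_pressure"].to_numpy(), out["temperature"].to_numpy()
        )
    return out


# ------------------------------------------------------------- mixed model

@dataclass
class AssociationResult:
    trait: str
    climate_var: str
    slope: float
    se: float
    t_stat: float
    lrt: float
    p_value: float
    n: int
    covariates: list
    h2_full: float


def _ml_neg_loglik(h2, w, yt, Xt):
    """Negative ML log-likelihood of the rotated LMM at variance ratio h2
    (total variance profiled out); exact up to the 2*pi constant."""
    n = len(yt)
    v = h2 * w + (1.0 - h2)
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
    return 0.5 * (n * np.log(rss / n) + np.sum(np.log(v)) + n)


def _ml_fit(y, X, K_values):
    """Maximize the ML likelihood over the variance ratio; return
    (loglik, h2, beta, cov_beta)."""
    w, yt, Xt = _rotate(y, X, K_values)
    res = optimize.minimize_scalar(
        _ml_neg_loglik, bounds=(0.0, 1.0 - 1e-9), args=(w, yt, Xt),
        method="bounded", options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    nll = float(res.fun)
    for edge in (0.0,):
        e_nll = _ml_neg_loglik(edge, w, yt, Xt)
        if e_nll <= nll:
            h2, nll = edge, float(e_nll)
    n = len(y)
    v = h2 * w + (1.0 - h2)
    vi = 1.0 / v
    xtvx = Xt.T @ (Xt * vi[:, None])
    beta = np.linalg.solve(xtvx, Xt.T @ (yt * vi))
    r = yt - Xt @ beta
    sigma2 = float(r @ (r * vi)) / n
    cov_beta = sigma2 * np.linalg.inv(xtvx)
    return -nll, h2, beta, cov_beta


def kinship_lmm_slope(
    y: np.ndarray,
    climate: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    K: KinshipMatrix,
    trait: str = "",
    climate_var: str = "",
    strict_gls: bool = False,
) -> AssociationResult:
    """Phenotype-climate slope under kinship-structured errors, with LRT.

    ``covariates`` (e.g. age, BMI) enter as fixed effects next to the
    intercept and the climate variable.  ``strict_gls`` drops the residual
    variance component and fits pure GLS with covariance proportional to K
    (the literal one-term error model; K is ridge-stabilized if singular).
    """
    y = np.asarray(y, dtype=float)
    climate = np.asarray(climate, dtype=float)
    n = len(y)
    if np.ptp(climate) == 0:
        raise ValueError("climate variable is constant")
    cov_names: list = []
    cols = [np.ones(n), climate]
    if covariates is not None:
        cov_arr = (
            covariates.to_numpy(float)
            if isinstance(covariates, pd.DataFrame)
            else np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        )
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
        cols.extend(cov_arr.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    X_red = np.delete(X, 1, axis=1)

    Kv = K.values
    if strict_gls:
        w = np.linalg.eigvalsh(Kv)
        if w.min() < 1e-10 * max(w.max(), 1.0):
            Kv = Kv + np.eye(n) * 1e-8 * max(w.max(), 1.0)
        ll_full, h2, beta, cov_beta = _gls_fixed(y, X, Kv)
        ll_red, _, _, _ = _gls_fixed(y, X_red, Kv)
    else:
        ll_full, h2, beta, cov_beta = _ml_fit(y, X, Kv)
        ll_red, _, _, _ = _ml_fit(y, X_red, Kv)

    slope = float(beta[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    p = float(stats.chi2.sf(lrt, df=1))
    return AssociationResult(
        trait=trait,
        climate_var=climate_var,
        slope=slope,
        se=se,
        t_stat=slope / se,
        lrt=lrt,
        p_value=p,
        n=n,
        covariates=cov_names,
        h2_full=h2,
    )


def _gls_fixed(y, X, Kv):
    """ML log-likelihood and GLS estimates with covariance fixed at K."""
    n = len(y)
    w, yt, Xt = _rotate(y, X, Kv)
    vi = 1.0 / w
    xtvx = Xt.T @ (Xt * vi[:, None])
    beta = np.linalg.solve(xtvx, Xt.T @ (yt * vi))
    r = yt - Xt @ beta
    sigma2 = float(r @ (r * vi)) / n
    ll = -0.5 * (n * np.log(sigma2) + np.sum(np.log(w)) + n)
    return ll, 1.0, beta, sigma2 * np.linalg.inv(xtvx)


def leave_one_population_out(
    y: np.ndarray,
    climate: np.ndarray,
    covariates: pd.DataFrame | None,
    K: KinshipMatrix,
    populations: np.ndarray,
    trait: str = "",
    climate_var: str = "",
) -> pd.DataFrame:
    """Refit the climate slope after dropping each population in turn.

    Returns one row per dropped population (plus a "none" row for the full
    data) with slope, SE, the 95% CI (slope +/- 1.96 SE) and whether the CI
    overlaps zero.
    """
    populations = np.asarray(populations)
    rows = []
    for drop in ["none", *sorted(pd.unique(populations).astype(str))]:
        keep = np.ones(len(y), bool) if drop == "none" else (
            populations.astype(str) != drop
        )
        if keep.sum() < 3:
            raise ValueError(f"dropping {drop} leaves <3 individuals")
        clim_k = climate[keep]
        if np.ptp(clim_k) == 0:
            raise ValueError(f"climate constant after dropping {drop}")
        cov_k = covariates.iloc[keep] if covariates is not None else None
        K_k = KinshipMatrix(
            K.values[np.ix_(keep, keep)],
            K.individual_ids[keep],
            source=K.source,
            n_markers=K.n_markers,
        )
        res = kinship_lmm_slope(
            y[keep], clim_k, cov_k, K_k, trait=trait, climate_var=climate_var
        )
        lo, hi = res.slope - 1.96 * res.se, res.slope + 1.96 * res.se
        rows.append(
            {
                "dropped": drop,
                "slope": res.slope,
                "se": res.se,
                "ci_lo": lo,
                "ci_hi": hi,
                "overlaps_zero": bool(lo <= 0.0 <= hi),
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
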