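"""Nose-shape traits from 3D landmarks and meshes, plus reliability stats.

Seven anthropometric landmarks define the linear traits: nasion (n),
pronasale (prn), subnasale (sn), left/right alar curvature (al_l, al_r) and
left/right alar base (ac_l, ac_r).  Five Euclidean distances (mm) are
derived from them -- nares width |al_l - al_r|, alar base width
|ac_l - ac_r|, nasal height |n - sn|, nasal ridge length |n - prn| and
nasal tip protrusion |sn - prn| -- and two areas (mm^2) from triangulated
mesh regions: external nose surface and mean nostril area.

Generalized Procrustes superimposition removes translation and rotation
only; scale is kept (a config flag exists) because the traits are absolute
millimetre measurements.  Bilateral asymmetry is removed by averaging each
configuration with its relabeled reflection.  Skin pigmentation is the
melanin index, 100*log10(1/reflectance at 650 nm).  Observer reliability is
the intraclass correlation from a two-way model with observer fixed and
subject random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARKS",
    "PAIRED_LANDMARKS",
    "DISTANCE_DEFS",
    "procrustes_align",
    "symmetrize",
    "landmark_distances",
    "region_area",
    "melanin_index",
    "inverse_melanin_index",
    "icc",
]

LANDMARKS = ("n", "prn", "sn", "al_l", "al_r", "ac_l", "ac_r")
PAIRED_LANDMARKS = {"al_l": "al_r", "al_r": "al_l", "ac_l": "ac_r", "ac_r": "ac_l"}
MIDLINE_LANDMARKS = ("n", "prn", "sn")

DISTANCE_DEFS = {
    "nares_width": ("al_l", "al_r"),
    "alar_base_width": ("ac_l", "ac_r"),
    "nasal_height": ("n", "sn"),
    "nasal_ridge_length": ("n", "prn"),
    "nasal_tip_protrusion": ("sn", "prn"),
}


# ----------------------------------------------------------- superimposition

def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix aligning centered config a onto centered config b."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0] * (a.shape[1] - 1) + [d])
    return u @ s @ vt


def procrustes_align(
    configs: np.ndarray,
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized Procrustes superimposition of homologous configurations.

    ``configs`` is (n_configs, n_points, 3).  Translation and rotation are
    removed by iterative alignment to the evolving consensus; with
    ``scale=True`` configurations are additionally scaled to unit centroid
    size.  Returns (aligned configs, consensus).  Convergence is declared
    when the consensus moves less than ``tol`` (RMS).
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("need >=2 configurations of shape (n_points, 3)")
    centered = configs - configs.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        raise ValueError("degenerate configuration: all landmarks coincident")
    if scale:
        centered = centered / sizes[:, None, None]

    aligned = centered.copy()
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _kabsch(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            break
    return aligned, consensus


def reflect(config: pd.DataFrame | np.ndarray, pairing=PAIRED_LANDMARKS):
    """Mirror a named-landmark frame: x -> -x, then swap left/right labels."""
    if isinstance(config, pd.DataFrame):
        out = config.copy()
        out["x"] = -out["x"]
        out.index = [pairing.get(lm, lm) for lm in out.index]
        return out.loc[config.index]
    raise TypeError("reflect expects a landmark DataFrame indexed by name")


def symmetrize(
    original: np.ndarray,
    reflected: np.ndarray,
    pairing: dict[int, int] | None = None,
) -> np.ndarray:
    """Average a configuration with its relabeled reflection.

    ``pairing`` maps point indices to their bilateral partners (an
    involution; unpaired midline points map to themselves).  ``reflected``
    must already carry the relabeling (partner rows swapped), as produced
    by :func:`reflect`; the output is then simply the pointwise mean, and is
    bilaterally symmetric up to numerical tolerance.
    """
    original = np.asarray(original, dtype=float)
    reflected = np.asarray(reflected, dtype=float)
    if original.shape != reflected.shape:
        raise ValueError("original and reflected shapes differ")
    if pairing is not None:
        for i, j in pairing.items():
            if pairing.get(j, j) != i:
                raise ValueError("pairing map is not an involution")
    return 0.5 * (original + reflected)


# ------------------------------------------------------------------ traits

def landmark_distances(lm: pd.DataFrame | dict) -> dict[str, float]:
    """The five linear nose-shape distances (mm) from named landmarks.

    ``lm`` maps landmark name -> (x, y, z) or is a DataFrame indexed by
    landmark name with columns x, y, z.
    """
    if isinstance(lm, pd.DataFrame):
        coords = {k: lm.loc[k, ["x", "y", "z"]].to_numpy(float) for k in lm.index}
    else:
        coords = {k: np.asarray(v, dtype=float) for k, v in lm.items()}
    missing = [k for k in LANDMARKS if k not in coords]
    if missing:
        raise ValueError(f"missing landmarks: {missing}")
    out = {}
    for name, (p, q) in DISTANCE_DEFS.items():
        out[name] = float(np.linalg.norm(coords[p] - coords[q]))
    return out


def region_area(
    vertices: np.ndarray, faces: np.ndarray, region: np.ndarray | None = None
) -> float:
    """Summed triangle area (mm^2) over a mesh region.

    ``region`` is a vertex-index mask/list; a triangle counts when all three
    of its vertices are in the region.  With ``region=None`` the whole mesh
    is used.  Triangle area is half the cross-product norm.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if faces.size == 0:
        raise ValueError("empty face list")
    if faces.max() >= len(vertices) or faces.min() < 0:
        raise ValueError("triangle index out of range")
    if region is not None:
        region = np.asarray(region)
        mask = np.zeros(len(vertices), bool)
        mask[region] = True
        faces = faces[mask[faces].all(axis=1)]
        if len(faces) == 0:
            raise ValueError("region contains no complete triangle")
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def melanin_index(reflectance) -> float | np.ndarray:
    """Melanin index = 100 * log10(1 / reflectance at 650 nm).

    Reflectance is a fraction in (0, 1]; percent-scale input (> 1) is
    detected, divided by 100 and warned about.  Per-individual values should
    be the mean over replicate readings (three per inner arm, both arms).
    """
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise ValueError("reflectance must be positive")
    if np.any(r > 1):
        if np.any(r > 100):
            raise ValueError("reflectance above 100%")
        warnings.warn("reflectance looks percent-scaled; dividing by 100",
                      stacklevel=2)
        r = r / 100.0
    out = 100.0 * np.log10(1.0 / r)
    return float(out) if np.ndim(reflectance) == 0 else out


def inverse_melanin_index(mi) -> float | np.ndarray:
    """1/MI, the more normally distributed transform used for testing."""
    mi = np.asarray(mi, dtype=float)
    if np.any(mi == 0):
        raise ValueError("melanin index of 0 has no inverse")
    out = 1.0 / mi
    return float(out) if np.ndim(out) == 0 else out


# ------------------------------------------------------------- reliability

@dataclass
class ICCResult:
    trait: str
    icc: float
    sigma2_subject: float
    sigma2_error: float
    observer_sd_quantiles: pd.DataFrame  # per-observer within-subject SD 2.5/97.5%


def icc(measurements: pd.DataFrame, value: str) -> ICCResult:
    """Intraclass correlation for a replicated trait measurement.

    ``measurements`` has columns ``subject``, ``observer``, ``replicate``
    and the value column.  Variance components come from the two-way
    crossed ANOVA with observer fixed and subject random:
    sigma2_subject = (MS_subject - MS_error) / k0 with k0 the effective
    replicates per subject, sigma2_error = MS_error, and
    ICC = sigma2_subject / (sigma2_subject + sigma2_error).  Also reports
    each observer's within-subject SD 2.5%/97.5% quantiles (intra-observer
    error).
    """
    df = measurements[["subject", "observer", "replicate", value]].dropna()
    subjects = df["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("ICC undefined for a single subject")

    y = df[value].to_numpy(float)
    n = len(df)
    grand = y.mean()

    # two-way ANOVA sums of squares (observer + subject, no interaction term:
    # interaction and residual pool into error, matching the fixed-observer
    # random-subject model)
    ss_total = ((y - grand) ** 2).sum()
    subj_means = df.groupby("subject")[value].transform("mean").to_numpy()
    obs_means = df.groupby("observer")[value].transform("mean").to_numpy()
    subj_counts = df.groupby("subject")[value].count()
    obs_counts = df.groupby("observer")[value].count()
    ss_subj = ((subj_means - grand) ** 2).sum()
    ss_obs = ((obs_means - grand) ** 2).sum()
    df_subj = len(subjects) - 1
    df_obs = df["observer"].nunique() - 1
    df_err = n - 1 - df_subj - df_obs
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom for ICC")
    ss_err = ss_total - ss_subj - ss_obs
    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err

    # effective replicates per subject (n0-style correction for imbalance)
    nc = subj_counts.to_numpy(float)
    k0 = (nc.sum() - (nc**2).sum() / nc.sum()) / df_subj

    s2_subj = max(0.0, (ms_subj - ms_err) / k0)
    s2_err = max(0.0, ms_err)
    denom = s2_subj + s2_err
    icc_val = 1.0 if denom == 0 or s2_err == 0 else s2_subj / denom

    sds = (
        df.groupby(["observer", "subject"])[value]
        .std(ddof=1)
        .reset_index()
        .rename(columns={value: "sd"})
        .dropna()
    )
    if len(sds):
        quant = (
            sds.groupby("observer")["sd"]
            .quantile([0.025, 0.975])
            .unstack()
            .rename(columns={0.025: "lower_2.5%", 0.975: "upper_97.5%"})
            .reset_index()
        )
    else:
        quant = pd.DataFrame(columns=["observer", "lower_2.5%", "upper_97.5%"])

    return ICCResult(
        trait=value,
        icc=float(icc_val),
        sigma2_subject=float(s2_subj),
        sigma2_error=float(s2_err),
        observer_sd_quantiles=quant,
    )


def replicate_mean_traits(landmark_table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual distances: mean within each observer's replicates,
    then mean across observers.

    ``landmark_table`` is long format: columns id, observer, replicate,
    landmark, x, y, z.  Individuals missing any of the seven landmarks in a
    replicate have that replicate excluded (logged via warning).
    """
    rows = []
    for (ind, obs, rep), grp in landmark_table.groupby(
        ["id", "observer", "replicate"]
    ):
        lm = grp.set_index("landmark")[["x", "y", "z"]]
        if not set(LANDMARKS) <= set(lm.index):
            warnings.warn(
                f"id={ind} observer={obs} replicate={rep}: incomplete landmarks,"
                " replicate excluded", stacklevel=2,
            )
            continue
        d = landmark_distances(lm)
        rows.append({"id": ind, "observer": obs, "replicate": rep, **d})
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise ValueError("no complete landmark replicates")
    per_obs = per_rep.groupby(["id", "observer"])[list(DISTANCE_DEFS)].mean()
    return per_obs.groupby("id").mean().reset_index()
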