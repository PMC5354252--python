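"""Readers and writers for the pipeline's tabular formats.

Genotypes come in as VCF (biallelic GT records, parsed with pysam) or as a
dosage TSV whose header row holds SNP ids, first column the individual id
and entries 0/1/2/NA, plus a two-column population map TSV.  Phenotype,
landmark, local-ancestry and climate tables are TSV with documented
mandatory columns.  JSON result files carry the seed and a config hash so
every artifact self-describes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, KinshipMatrix, LocalAncestryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_phenotypes",
    "read_landmarks",
    "read_climate",
    "read_mesh",
    "read_local_ancestry",
    "read_kinship",
    "write_kinship",
    "write_json_result",
]

PHENOTYPE_REQUIRED = ["id", "population"]
LANDMARK_REQUIRED = ["id", "observer", "replicate", "landmark", "x", "y", "z"]
CLIMATE_REQUIRED = ["id"]


def _require(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} missing columns: {missing}")


# ---------------------------------------------------------------- genotypes

def read_genotypes(
    path, fmt: str | None = None, population_map=None
) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or dosage TSV.

    ``fmt`` is inferred from the suffix when omitted.  ``population_map`` is
    a path to a two-column TSV (id, population) or a dict; individuals
    without a label get "unknown" for VCF input, while the TSV dialect may
    carry its own ``population`` column.
    """
    path = Path(path)
    fmt = fmt or ("vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf"
                  else "tsv")
    if fmt == "vcf":
        gm = _read_vcf(path)
    elif fmt == "tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {fmt}")

    if population_map is not None:
        if not isinstance(population_map, dict):
            pm = pd.read_csv(population_map, sep="\t")
            _require(pm, ["id", "population"], "population map", population_map)
            population_map = dict(zip(pm["id"].astype(str), pm["population"]))
        labels = np.array(
            [str(population_map.get(str(i), "unknown")) for i in
             gm.individual_ids]
        )
        n_unknown = int((labels == "unknown").sum())
        if n_unknown:
            logger.warning("%d individuals without a population label", n_unknown)
        gm = GenotypeMatrix(gm.dosages, gm.individual_ids, labels, gm.snp_ids)
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, snp_ids = [], []
    n_multiallelic = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multiallelic += 1
            continue
        dos = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                dos.append(np.nan)
            else:
                dos.append(float(sum(1 for a in gt if a != 0)))
        rows.append(dos)
        snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
    if n_multiallelic:
        logger.info("skipped %d multi-allelic records", n_multiallelic)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    dosages = np.array(rows, dtype=float).T
    return GenotypeMatrix(
        dosages,
        np.array(samples),
        np.array(["unknown"] * len(samples)),
        np.array(snp_ids),
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    pop = None
    if "population" in df.columns:
        pop = df["population"].astype(str).to_numpy()
        df = df.drop(columns=["population"])
    snp_cols = [c for c in df.columns if c != id_col]
    dosages = df[snp_cols].to_numpy(float)
    bad = dosages[~np.isnan(dosages)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        rows = np.unique(np.nonzero(~np.isnan(dosages)
                                    & ~np.isin(dosages, (0, 1, 2)))[0])[:5]
        raise ValueError(
            f"malformed dosages in {path} at data rows {list(rows + 2)}"
        )
    return GenotypeMatrix(
        dosages,
        df[id_col].astype(str).to_numpy(),
        pop if pop is not None else np.array(["unknown"] * len(df)),
        np.array(snp_cols),
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a biallelic VCF (GT field, placeholder alleles).

    Positions are 1-based consecutive on a single contig; dosage d becomes
    an unphased genotype with d ALT alleles, NaN becomes ./..  Population
    labels do not fit in VCF and travel separately (population map TSV).
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=%d>" % (gm.n_snps + 1))
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for s in gm.individual_ids:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, snp in enumerate(gm.snp_ids):
            rec = vcf.new_record(
                contig="1", start=j, stop=j + 1, alleles=("A", "G"),
                id=str(snp),
            )
            for i, s in enumerate(gm.individual_ids):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    d = int(d)
                    rec.samples[str(s)]["GT"] = (1 if d == 2 else 0,
                                                 1 if d >= 1 else 0)
            vcf.write(rec)


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    df.insert(0, "population", gm.populations)
    df.insert(0, "id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------------------- tables

def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: id, population, then sex/age/bmi and trait columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, PHENOTYPE_REQUIRED, "phenotype", path)
    df["id"] = df["id"].astype(str)
    return df


def read_landmarks(path) -> pd.DataFrame:
    """Landmark TSV (long): id, observer, replicate, landmark, x, y, z (mm)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, LANDMARK_REQUIRED, "landmark", path)
    df["id"] = df["id"].astype(str)
    return df


def read_climate(path) -> pd.DataFrame:
    """Climate TSV: id plus any of temperature (degC), vapor_pressure (hPa),
    uvb (J/m2), relative_humidity (%), absolute_humidity (g/m3)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, CLIMATE_REQUIRED, "climate", path)
    df["id"] = df["id"].astype(str)
    return df


def read_mesh(path, region_mask_path=None):
    """Load a triangulated mesh (PLY or OBJ) plus optional region masks.

    Vertex order is preserved (no merging/reprocessing) so the region-mask
    JSON -- ``{"region name": [0-based vertex indices], ...}`` -- stays
    valid.  Returns (vertices, faces, masks) with masks a dict of index
    arrays ({} when no mask file is given).
    """
    import trimesh

    mesh = trimesh.load(str(path), force="mesh", process=False)
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    masks: dict = {}
    if region_mask_path is not None:
        raw = json.loads(Path(region_mask_path).read_text())
        for name, idx in raw.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(vertices)):
                raise ValueError(
                    f"region '{name}' has vertex indices outside 0..{len(vertices) - 1}"
                )
            masks[name] = idx
    return vertices, faces, masks


def read_local_ancestry(path) -> LocalAncestryMatrix:
    """Local-ancestry dosage TSV: same dialect as the genotype TSV."""
    gm = _read_dosage_tsv(Path(path))
    return LocalAncestryMatrix(gm.dosages, gm.individual_ids, gm.snp_ids)


def join_on_id(left: pd.DataFrame, right: pd.DataFrame, what: str = "table"
               ) -> pd.DataFrame:
    """Inner-join two tables on id, warning about unmatched ids."""
    merged = left.merge(right, on="id", how="inner")
    lost = sorted(set(left["id"]) ^ set(right["id"]))
    if lost:
        logger.warning("%d ids unmatched joining %s: %s%s", len(lost), what,
                       lost[:5], "..." if len(lost) > 5 else "")
    return merged


# ------------------------------------------------------------------ kinship

def read_kinship(path, source: str = "genotype") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(float), df.index.astype(str).to_numpy(),
                         source=source)


def write_kinship(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.individual_ids,
                 columns=K.individual_ids).to_csv(path, sep="\t")


# -------------------------------------------------------------------- results

def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_json_result(payload: dict, path, seed: int | None = None,
                      config: dict | None = None) -> None:
    """Write a result JSON with seed and config hash attached."""
    meta = {"seed": seed}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    out = {**payload, "_meta": meta}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
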