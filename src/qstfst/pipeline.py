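"""Umbrella pipeline: chain the analysis stages from one config dict.

The config (usually parsed from YAML) selects stages and supplies paths or
simulation settings.  All randomness flows from the single ``seed``; every
artifact written carries the seed and a config hash, so a rerun with the
same config is byte-identical apart from filesystem timestamps.

Config keys (all optional unless a stage needs them):

    seed: int
    out_dir: str
    stages: [simulate, qst, fst, qstfst_test, sensitivity, heritability,
             climate_assoc]
    simulate: {SimConfig fields}
    pheno: path (used when 'simulate' is off)
    genotypes: path
    traits: [trait column names]
    n_boot: int (default 10000)
    ratio_grid_max: float (default 1.0)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence, fst as fst_mod, heritability, io, qst
from . import synthetic_data as sim

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(cfg: dict) -> dict:
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "qstfst_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get(
        "stages",
        ["simulate", "qst", "fst", "qstfst_test", "sensitivity"],
    )
    n_boot = int(cfg.get("n_boot", 10_000))

    genos = None
    if "simulate" in stages:
        sim_cfg = sim.SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
        genos = sim.simulate_genotypes(sim_cfg)
        pheno = sim.simulate_phenotype(genos, sim_cfg)
        io.write_genotypes_tsv(genos, out_dir / "genotypes.tsv")
        pheno.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
        io.write_json_result(pheno.attrs["truth"], out_dir / "truth.json",
                             seed=seed, config=cfg)
        traits = cfg.get("traits", ["trait"])
    else:
        pheno = io.read_phenotypes(cfg["pheno"])
        if "genotypes" in cfg:
            genos = io.read_genotypes(cfg["genotypes"],
                                      population_map=cfg.get("pop_map"))
        traits = cfg.get("traits") or [
            c for c in pheno.columns
            if c not in ("id", "population", "sex", "age", "bmi")
        ]

    summary: dict = {"seed": seed, "traits": {}}

    fst_dist = None
    if "fst" in stages:
        if genos is None:
            raise RuntimeError("stage 'fst' needs genotypes")
        try:
            fst_dist = fst_mod.wc_theta(genos)
        except ValueError as e:
            raise RuntimeError(f"stage 'fst' failed: {e}") from e
        fst_dist.to_frame().to_csv(out_dir / "theta.tsv", sep="\t",
                                   index=False)
        io.write_json_result(fst_dist.summary(), out_dir / "theta.json",
                             seed=seed, config=cfg)
        summary["theta_multilocus"] = fst_dist.theta_multilocus

    grid = np.round(
        np.arange(0.01, float(cfg.get("ratio_grid_max", 1.0)) + 1e-9, 0.01), 2
    )
    for t_i, trait in enumerate(traits):
        row: dict = {}
        try:
            if "qst" in stages:
                vc = qst.variance_components(pheno, trait)
                row["qst"] = qst.qst_value(vc, 1.0, trait=trait).qst
            if "qstfst_test" in stages or "sensitivity" in stages:
                if fst_dist is None:
                    raise RuntimeError("needs the 'fst' stage")
                draws = divergence.bootstrap_qst(
                    pheno, trait, n_boot=n_boot, seed=seed + 101 + t_i
                )
                if "qstfst_test" in stages:
                    res = divergence.qst_fst_test(
                        draws, fst_dist, seed=seed + 201 + t_i
                    )
                    row["p_value"] = res.p_value
                    row["p_label"] = res.p_label
                    fst_draws = res.fst_draws
                else:
                    rng = np.random.default_rng(seed + 201 + t_i)
                    fst_draws = divergence.draw_fst(fst_dist, n_boot, rng)
                if "sensitivity" in stages:
                    curve = divergence.sensitivity_curve(
                        draws, fst_draws, grid=grid
                    )
                    curve.to_frame().to_csv(
                        out_dir / f"sensitivity_{trait}.tsv", sep="\t",
                        index=False,
                    )
                    row["critical_c_over_h2"] = curve.critical_label
        except Exception as e:
            raise RuntimeError(f"stage failed for trait '{trait}': {e}") from e
        summary["traits"][trait] = row

    if "heritability" in stages:
        if genos is None:
            raise RuntimeError("stage 'heritability' needs genotypes")
        K = heritability.grm(genos)
        io.write_kinship(K, out_dir / "grm.tsv")
        for trait in traits:
            df = pheno.dropna(subset=[trait])
            Ksub = K.subset(df["id"].tolist())
            X = [np.ones(len(df))]
            for cov in ("sex", "age", "bmi"):
                if cov in df.columns:
                    v = df[cov]
                    X.append((v.astype(str) == "M").to_numpy(float)
                             if v.dtype == object else v.to_numpy(float))
            est = heritability.reml_h2(df[trait].to_numpy(float),
                                       np.column_stack(X), Ksub)
            summary["traits"].setdefault(trait, {})["h_g2"] = est.h2
            summary["traits"][trait]["h_g2_se"] = est.se

    table = pd.DataFrame(
        [{"trait": t, **row} for t, row in summary["traits"].items()]
    )
    table.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    io.write_json_result(summary, out_dir / "summary.json", seed=seed,
                         config=cfg)
    return summary
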