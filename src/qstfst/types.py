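"""Core in-memory containers shared across the pipeline.

These are thin, validated wrappers around numpy arrays and pandas frames:
a genotype dosage matrix with population labels, a local-ancestry dosage
matrix, and a kinship matrix.  Phenotype, climate and landmark tables are
plain ``pandas.DataFrame`` objects with documented schemas (see
:mod:`qstfst.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "LocalAncestryMatrix", "KinshipMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix (0/1/2, NaN = missing)."""

    dosages: np.ndarray
    individual_ids: np.ndarray
    populations: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        self.populations = np.asarray(self.populations)
        self.snp_ids = np.asarray(self.snp_ids)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length != number of rows")
        if len(self.populations) != n:
            raise ValueError("every individual needs a population label")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length != number of columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in {0,1,2} or be missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Pooled sample allele frequency per SNP, ignoring missing."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class LocalAncestryMatrix:
    """Copies (0/1/2) from one parental population at each SNP."""

    dosages: np.ndarray
    individual_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("ancestry dosages must lie in {0,1,2}")

    def global_ancestry(self) -> np.ndarray:
        """Per-individual mean ancestry fraction (row mean / 2)."""
        return np.nanmean(self.dosages, axis=1) / 2.0


@dataclass
class KinshipMatrix:
    """Square symmetric relatedness matrix over individuals.

    ``source`` records how it was built ("genotype" or "local-ancestry");
    ``n_markers`` the number of SNPs that contributed.
    """

    values: np.ndarray
    individual_ids: np.ndarray
    source: str = "genotype"
    n_markers: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square over the ids")
        if np.isnan(self.values).any():
            raise ValueError("kinship matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    def subset(self, ids) -> "KinshipMatrix":
        """Restrict to the given individual ids, preserving their order."""
        pos = {x: i for i, x in enumerate(self.individual_ids)}
        missing = [x for x in ids if x not in pos]
        if missing:
            raise KeyError(f"ids not in kinship matrix: {missing[:5]}")
        idx = np.array([pos[x] for x in ids])
        return KinshipMatrix(
            self.values[np.ix_(idx, idx)],
            np.asarray(ids),
            source=self.source,
            n_markers=self.n_markers,
        )
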