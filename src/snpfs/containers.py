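"""Shared in-memory containers and text I/O for genotype and cohort data.

The dosage matrix is the substrate of every modelling stage: one row per
sample, one column per biallelic SNP, entries in [0, 2] counting copies of
the minor allele (hard calls here; imputed fractional dosages are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)] + ["array"]
COHORT_COLUMNS = ["sample_id", "phenotype"] + COVARIATE_COLUMNS


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with identifiers.

    Invariants: dosages lie in [0, 2] with no missing values; the column
    count equals ``len(snp_ids)``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    _snp_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D matrix")
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if np.isnan(self.dosage).any():
            raise ValueError("dosage contains missing values")
        if self.dosage.min() < 0 or self.dosage.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def columns(self, snp_ids: list[str]) -> np.ndarray:
        """Dosage sub-matrix for the given SNPs, in the given order."""
        missing = [s for s in snp_ids if s not in self._snp_index]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
        idx = [self._snp_index[s] for s in snp_ids]
        return self.dosage[:, idx]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, list(snp_ids), self.columns(list(snp_ids)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=self.snp_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        sample_ids = df["sample_id"].astype(str).tolist()
        snp_ids = [c for c in df.columns if c != "sample_id"]
        return cls(sample_ids, snp_ids, df[snp_ids].to_numpy(dtype=float))


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table contract: binary phenotype, complete covariates."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    pheno = cohort["phenotype"]
    if not np.isin(pheno.unique(), [0, 1]).all():
        raise ValueError("phenotype must be binary 0/1")
    if cohort[COVARIATE_COLUMNS].isna().any().any():
        raise ValueError("covariate columns must be complete")
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))
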