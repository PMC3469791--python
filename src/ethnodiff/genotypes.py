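"""Dosage-coded genotype matrices and their on-disk TSV/VCF forms.

Genotypes are stored as allele-dosage codes 0/1/2 (copies of the coded
allele per SNP) with NaN marking missing calls. Rows are SNPs, columns are
samples, matching the tab-separated interchange format used throughout the
package: first column ``snp_id``, then one column per sample, entries
``0``/``1``/``2``/``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhenotypeTable"]


@dataclass
class GenotypeMatrix:
    """SNP-by-sample allele dosage matrix.

    dosages[i, j] counts copies of ``coded_alleles[i]`` carried by sample j
    at SNP i; NaN means no call.
    """

    snp_ids: list
    sample_ids: list
    dosages: np.ndarray
    coded_alleles: Optional[list] = None
    other_alleles: Optional[list] = None
    chrom: Optional[list] = None
    pos: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.sample_ids)} samples"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in genotype matrix")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[self.snp_index(snp_id)]

    def snp_call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def sample_call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def coded_allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the coded allele over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def genotype_counts(self, snp_id: str) -> tuple:
        """(n_zero, n_het, n_two) coded-allele-dosage counts at one SNP."""
        d = self.dosage_of(snp_id)
        d = d[~np.isnan(d)]
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            dosages=self.dosages[idx, :].copy(),
            coded_alleles=[self.coded_alleles[i] for i in idx] if self.coded_alleles else None,
            other_alleles=[self.other_alleles[i] for i in idx] if self.other_alleles else None,
            chrom=[self.chrom[i] for i in idx] if self.chrom else None,
            pos=self.pos[idx].copy() if self.pos is not None else None,
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            snp_ids=list(self.snp_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            coded_alleles=list(self.coded_alleles) if self.coded_alleles else None,
            other_alleles=list(self.other_alleles) if self.other_alleles else None,
            chrom=list(self.chrom) if self.chrom else None,
            pos=self.pos.copy() if self.pos is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.snp_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "snp_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="snp_id", na_values=["NA"])
        return cls(
            snp_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            dosages=df.to_numpy(dtype=float),
        )

    def write_vcf(self, path) -> None:
        """Minimal unphased GT-only VCF v4.2 export.

        Requires allele labels and coordinates; dosage counts copies of the
        ALT allele (coded allele written as ALT).
        """
        if self.coded_alleles is None or self.other_alleles is None:
            raise ValueError("allele labels required for VCF export")
        chrom = self.chrom if self.chrom is not None else ["1"] * self.n_snps
        pos = self.pos if self.pos is not None else np.arange(1, self.n_snps + 1)
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.sample_ids)
                + "\n"
            )
            for i, snp in enumerate(self.snp_ids):
                calls = [
                    gt_map.get(d, "./.") if not np.isnan(d) else "./."
                    for d in self.dosages[i]
                ]
                fh.write(
                    f"{chrom[i]}\t{int(pos[i])}\t{snp}\t{self.other_alleles[i]}\t"
                    f"{self.coded_alleles[i]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
                )


@dataclass
class PhenotypeTable:
    """Case-control status plus covariates, aligned to a sample list.

    ``status`` is 1 for cases, 0 for controls. ``covariates`` columns (e.g.
    principal components, study-site indicators) are real-valued and enter
    association models as-is.
    """

    sample_ids: list
    status: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    group: Optional[list] = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.sample_ids),):
            raise ValueError("status length does not match sample_ids")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be binary 0/1")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ValueError("covariate rows do not match sample_ids")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "status": self.status})
        if self.group is not None:
            df["group"] = self.group
        for col in self.covariates.columns:
            df[col] = np.asarray(self.covariates[col])
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        required = {"sample_id", "status"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype file must have columns {sorted(required)}")
        covar_cols = [c for c in df.columns if c not in ("sample_id", "status", "group")]
        return cls(
            sample_ids=list(df["sample_id"].astype(str)),
            status=df["status"].to_numpy(),
            covariates=df[covar_cols].astype(float) if covar_cols else pd.DataFrame(),
            group=list(df["group"].astype(str)) if "group" in df.columns else None,
        )

    def subset(self, indices: Sequence[int]) -> "PhenotypeTable":
        idx = list(indices)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            status=self.status[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates)
            else pd.DataFrame(),
            group=[self.group[i] for i in idx] if self.group is not None else None,
        )
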