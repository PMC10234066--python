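"""SNP panel metadata.

A panel lists the markers that enter the cumulative genetic score (CGS):
for each SNP the "first" (counted) allele, the other allele, and one GWAS
effect-size beta per phenotype.  Only the *sign* of each beta is consumed
by the score coding; the magnitudes are carried along as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: phenotype tags: RF = reading fluency (timed), CR = character recognition
PHENOTYPE_TAGS = ("RF", "CR")


@dataclass(frozen=True)
class Snp:
    snp_id: str
    first_allele: str
    other_allele: str
    beta_rf: float
    beta_cr: float
    maf: float

    def __post_init__(self) -> None:
        if self.first_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.first_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: first and other allele must differ")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must lie in (0, 0.5], got {self.maf}")

    def beta(self, phenotype_tag: str) -> float:
        if phenotype_tag == "RF":
            return self.beta_rf
        if phenotype_tag == "CR":
            return self.beta_cr
        raise ValueError(f"unknown phenotype tag {phenotype_tag!r}")


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of SNPs with unique identifiers."""

    snps: tuple[Snp, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("panel must contain at least one SNP")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids must be unique")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps])

    def get(self, snp_id: str) -> Snp:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def betas(self, phenotype_tag: str) -> np.ndarray:
        return np.array([s.beta(phenotype_tag) for s in self.snps])

    def subset(self, snp_ids: list[str]) -> "SnpPanel":
        keep = set(snp_ids)
        return SnpPanel(tuple(s for s in self.snps if s.snp_id in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "first_allele": [s.first_allele for s in self.snps],
                "other_allele": [s.other_allele for s in self.snps],
                "beta_rf": [s.beta_rf for s in self.snps],
                "beta_cr": [s.beta_cr for s in self.snps],
                "maf": [s.maf for s in self.snps],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpPanel":
        required = {"snp_id", "first_allele", "other_allele", "beta_rf", "beta_cr", "maf"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        snps = tuple(
            Snp(
                snp_id=str(r.snp_id),
                first_allele=str(r.first_allele),
                other_allele=str(r.other_allele),
                beta_rf=float(r.beta_rf),
                beta_cr=float(r.beta_cr),
                maf=float(r.maf),
            )
            for r in df.itertuples()
        )
        return cls(snps)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SnpPanel":
        return cls.from_frame(pd.read_csv(path))


# Default 13-marker panel.  Identifiers, allele pairs, MAFs and beta signs are
# synthetic but chosen to look like a small candidate-gene panel: MAFs spread
# over [0.05, 0.45] and beta signs mixed so both coding orientations are
# exercised.  Beta magnitudes are on the scale of single-SNP effects on a
# timed reading measure (seconds per allele).
_DEFAULT_ROWS = [
    # snp_id, first, other, beta_rf, beta_cr, maf
    ("snp01", "A", "G", 0.42, 0.21, 0.12),
    ("snp02", "C", "T", -0.31, 0.18, 0.31),
    ("snp03", "G", "A", 0.27, -0.25, 0.45),
    ("snp04", "T", "C", -0.55, -0.12, 0.22),
    ("snp05", "A", "C", 0.19, 0.30, 0.38),
    ("snp06", "G", "T", -0.44, 0.22, 0.08),
    ("snp07", "C", "G", 0.36, -0.17, 0.27),
    ("snp08", "T", "A", -0.23, -0.28, 0.41),
    ("snp09", "A", "T", 0.50, 0.15, 0.17),
    ("snp10", "G", "C", -0.38, 0.26, 0.34),
    ("snp11", "C", "A", 0.29, -0.20, 0.25),
    ("snp12", "T", "G", -0.47, 0.11, 0.44),
    ("snp13", "A", "G", 0.33, -0.24, 0.10),
]


def default_panel() -> SnpPanel:
    """The 13-SNP panel shipped with the package (synthetic metadata)."""
    return SnpPanel(tuple(Snp(*row) for row in _DEFAULT_ROWS))
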