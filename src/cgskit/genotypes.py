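"""Genotype matrix container and text-format I/O (VCF, PLINK .raw, CSV).

Codes count copies of the panel's *first* allele (0, 1 or 2); missing calls
are stored as NaN in a float matrix.  VCF genotypes count ALT copies, so the
reader reconciles orientation against the panel: if REF is the panel's first
allele the code is ``2 - alt_count``, if ALT is the first allele it is
``alt_count``; any other allele pair is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel


@dataclass
class GenotypeMatrix:
    """samples x SNPs matrix of first-allele copy counts with NaN missingness."""

    sample_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # float array, values in {0, 1, 2, nan}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"codes must be 0/1/2 or NaN; found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.sample_ids, columns=self.snp_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def sample_call_rate(self) -> pd.Series:
        ok = ~np.isnan(self.codes)
        return pd.Series(ok.mean(axis=1), index=self.sample_ids, name="call_rate")

    def snp_call_rate(self) -> pd.Series:
        ok = ~np.isnan(self.codes)
        return pd.Series(ok.mean(axis=0), index=self.snp_ids, name="call_rate")

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-first, het, hom-other) counts for SNP column ``j``."""
        col = self.codes[:, j]
        return (
            int(np.nansum(col == 2.0)),
            int(np.nansum(col == 1.0)),
            int(np.nansum(col == 0.0)),
        )

    def first_allele_freq(self) -> pd.Series:
        """Per-SNP frequency of the first allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.codes, axis=0) / 2.0
        return pd.Series(freq, index=self.snp_ids, name="first_allele_freq")

    def maf(self) -> pd.Series:
        f = self.first_allele_freq()
        return pd.Series(np.minimum(f, 1.0 - f), index=self.snp_ids, name="maf")

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeMatrix":
        df = self.to_frame()
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if snp_ids is not None:
            df = df[list(snp_ids)]
        return GenotypeMatrix.from_frame(df)


# ---------------------------------------------------------------------------
# writers

def write_csv(g: GenotypeMatrix, path: str | Path) -> None:
    g.to_frame().rename_axis("sample_id").to_csv(path)


def write_vcf(g: GenotypeMatrix, panel: SnpPanel, path: str | Path) -> None:
    """Minimal VCFv4.2: one record per SNP, GT field only.

    REF is the panel's first allele and ALT the other allele, so a code of 2
    (two first-allele copies) is written as 0/0.
    """
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=1>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids))
    gt_for_alt = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, snp_id in enumerate(g.snp_ids):
        snp = panel.get(snp_id)
        fields = ["1", str(1000 + j), snp_id, snp.first_allele, snp.other_allele, ".", "PASS", ".", "GT"]
        for i in range(g.n_samples):
            c = g.codes[i, j]
            fields.append("./." if np.isnan(c) else gt_for_alt[2 - int(c)])
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_plink_raw(g: GenotypeMatrix, panel: SnpPanel, path: str | Path) -> None:
    """PLINK ``--recode A`` style additive-dosage text table.

    The counted allele (header suffix) is the panel's first allele, so the
    dosage column equals the stored code directly; missing is NA.
    """
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    header += [f"{sid}_{panel.get(sid).first_allele}" for sid in g.snp_ids]
    rows = [" ".join(header)]
    for i, sid in enumerate(g.sample_ids):
        vals = ["NA" if np.isnan(c) else str(int(c)) for c in g.codes[i]]
        rows.append(" ".join([sid, sid, "0", "0", "0", "-9"] + vals))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# readers

def _read_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        vid = variant.ID
        snp = panel.get(vid)  # KeyError on unknown id
        ref, alt = variant.REF, variant.ALT[0] if variant.ALT else None
        if ref == snp.first_allele and alt == snp.other_allele:
            flip = True  # alt count -> 2 - count
        elif alt == snp.first_allele and ref == snp.other_allele:
            flip = False
        else:
            raise ValueError(f"{vid}: VCF alleles {ref}/{alt} do not match panel "
                             f"{snp.first_allele}/{snp.other_allele}")
        codes = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if any(a < 0 for a in alleles):
                continue
            alt_count = sum(1 for a in alleles if a > 0)
            codes[i] = 2 - alt_count if flip else alt_count
        snp_ids.append(vid)
        rows.append(codes)
    vcf.close()
    return GenotypeMatrix(sample_ids, snp_ids,
                          np.array(rows).T if rows else np.empty((len(sample_ids), 0)))


def _read_plink_raw(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    snp_cols = [c for c in df.columns if c not in meta]
    snp_ids, codes = [], []
    for col in snp_cols:
        sid, _, counted = col.rpartition("_")
        snp = panel.get(sid)
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if counted == snp.first_allele:
            pass
        elif counted == snp.other_allele:
            vals = 2.0 - vals
        else:
            raise ValueError(f"{sid}: counted allele {counted} not in panel")
        snp_ids.append(sid)
        codes.append(vals)
    return GenotypeMatrix(
        list(df["IID"].astype(str)), snp_ids,
        np.array(codes).T if codes else np.empty((len(df), 0)),
    )


def _read_csv(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    for sid in df.columns:
        panel.get(sid)  # raise on unknown SNP
    return GenotypeMatrix.from_frame(df)


def read_genotypes(path: str | Path, format: str, panel: SnpPanel) -> GenotypeMatrix:
    """Read a genotype matrix, reconciling allele orientation against the panel."""
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw, "csv": _read_csv}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path, panel)
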