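"""Genotype quality control: call rate, Hardy-Weinberg, MAF, relatedness.

Thresholds default to the conventional screening values for array data:
sample call rate > 0.90, SNP call rate > 0.95, HWE p >= 1e-5, MAF > 0.01,
PI_HAT <= 0.50.  Filters are applied in a fixed PLINK-like order (sample
call rate, SNP call rate, HWE, MAF, relatedness) and every removal is
logged with the metric value and the threshold it violated.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

#: fewer markers than this makes the method-of-moments PI_HAT unreliable
MIN_SNPS_FOR_RELATEDNESS = 50


@dataclass
class Removal:
    entity: str            # "sample" or "snp"
    identifier: str
    reason: str            # primary reason, exactly one per removal
    metric: float
    threshold: float


@dataclass
class QCReport:
    sample_call_rate: pd.Series = field(default_factory=pd.Series)
    snp_call_rate: pd.Series = field(default_factory=pd.Series)
    snp_maf: pd.Series = field(default_factory=pd.Series)
    hwe: pd.DataFrame = field(default_factory=pd.DataFrame)   # statistic, p per SNP
    pihat: pd.DataFrame = field(default_factory=pd.DataFrame)  # pairwise estimates
    removals: list[Removal] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def removed(self, entity: str) -> list[str]:
        return [r.identifier for r in self.removals if r.entity == entity]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "removals": [vars(r) for r in self.removals],
            "sample_call_rate": self.sample_call_rate.round(6).to_dict(),
            "snp_call_rate": self.snp_call_rate.round(6).to_dict(),
            "snp_maf": self.snp_maf.round(6).to_dict(),
            "hwe": self.hwe.round(10).to_dict(orient="index") if len(self.hwe) else {},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        rows = [vars(r) for r in self.removals]
        pd.DataFrame(rows, columns=["entity", "identifier", "reason", "metric", "threshold"]) \
            .to_csv(path, sep="\t", index=False)


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test on (hom-first, het, hom-other) counts.

    Expected counts come from the sample allele frequency.  A monomorphic
    SNP carries no information about HWE and returns (0.0, 1.0) by
    convention.
    """
    n_hom_first, n_het, n_hom_other = counts
    n = n_hom_first + n_het + n_hom_other
    if n <= 0:
        raise ValueError("total genotype count must be > 0")
    p = (2 * n_hom_first + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_hom_first, n_het, n_hom_other], dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return statistic, float(stats.chi2.sf(statistic, df=1))


def call_rate_filter(
    g: GenotypeMatrix,
    sample_min: float = 0.90,
    snp_min: float = 0.95,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Drop samples at or below sample_min, then SNPs at or below snp_min.

    SNP call rates are recomputed on the surviving samples, so a SNP whose
    missingness is concentrated in bad samples can be retained.
    """
    for t in (sample_min, snp_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("call-rate thresholds must lie in [0, 1]")
    report = report if report is not None else QCReport()
    scr = g.sample_call_rate()
    keep_samples = scr[scr > sample_min].index.tolist()
    for sid in scr.index[scr <= sample_min]:
        report.removals.append(Removal("sample", sid, "sample_call_rate", float(scr[sid]), sample_min))
    g = g.subset(sample_ids=keep_samples)
    ncr = g.snp_call_rate()
    keep_snps = ncr[ncr > snp_min].index.tolist()
    for sid in ncr.index[ncr <= snp_min]:
        report.removals.append(Removal("snp", sid, "snp_call_rate", float(ncr[sid]), snp_min))
    g = g.subset(snp_ids=keep_snps)
    if g.n_samples == 0 or g.n_snps == 0:
        warnings.warn("call_rate_filter removed everything", stacklevel=2)
    report.sample_call_rate = scr
    report.snp_call_rate = ncr
    return g


def hwe_filter(g: GenotypeMatrix, p_min: float = 1e-5,
               report: QCReport | None = None) -> GenotypeMatrix:
    """Drop SNPs whose HWE chi-square p-value falls below p_min."""
    report = report if report is not None else QCReport()
    rows = {}
    keep = []
    for j, sid in enumerate(g.snp_ids):
        statistic, p = hwe_test(g.genotype_counts(j))
        rows[sid] = {"statistic": statistic, "p_value": p}
        if p < p_min:
            report.removals.append(Removal("snp", sid, "hwe", p, p_min))
        else:
            keep.append(sid)
    report.hwe = pd.DataFrame.from_dict(rows, orient="index")
    return g.subset(snp_ids=keep)


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.01,
               report: QCReport | None = None) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency at or below min_maf."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    report = report if report is not None else QCReport()
    maf = g.maf()
    keep = maf[maf > min_maf].index.tolist()
    for sid in maf.index[maf <= min_maf]:
        report.removals.append(Removal("snp", sid, "maf", float(maf[sid]), min_maf))
    report.snp_maf = maf
    return g.subset(snp_ids=keep)


def estimate_pihat(g: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments pairwise relatedness from allele frequencies.

    For samples i, k the estimate is the allele-frequency-standardized
    genotype covariance averaged over markers,
    ``mean_m (x_im - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m))``,
    which is ~0 for unrelated pairs, ~0.5 for first-degree relatives and
    ~1 for duplicates — the same scale as PLINK's PI_HAT.  Markers missing
    in either sample, and monomorphic markers, are skipped pairwise.
    """
    p = g.first_allele_freq().to_numpy()
    poly = (p > 0) & (p < 1)
    x = g.codes[:, poly]
    p = p[poly]
    denom = 2 * p * (1 - p)
    centered = x - 2 * p[None, :]
    standardized = centered / np.sqrt(denom)[None, :]
    rows = []
    for i, k in itertools.combinations(range(g.n_samples), 2):
        both = ~np.isnan(standardized[i]) & ~np.isnan(standardized[k])
        if both.sum() == 0:
            est = np.nan
        else:
            est = float(np.mean(standardized[i, both] * standardized[k, both]))
        rows.append({"sample_1": g.sample_ids[i], "sample_2": g.sample_ids[k], "pi_hat": est})
    return pd.DataFrame(rows)


def relatedness_filter(
    g: GenotypeMatrix,
    pihat_max: float = 0.50,
    report: QCReport | None = None,
    min_snps: int = MIN_SNPS_FOR_RELATEDNESS,
) -> GenotypeMatrix:
    """Remove one member of each pair with PI_HAT above pihat_max.

    The member with the lower call rate is dropped (tie: the later sample
    id).  With fewer than ``min_snps`` markers the estimate is too noisy;
    a warning is issued and the filter is skipped.
    """
    if g.n_samples < 2:
        raise ValueError("relatedness filter needs at least 2 samples")
    report = report if report is not None else QCReport()
    if g.n_snps < min_snps:
        warnings.warn(
            f"only {g.n_snps} SNPs (< {min_snps}); PI_HAT unreliable, relatedness filter skipped",
            stacklevel=2,
        )
        return g
    pihat = estimate_pihat(g)
    report.pihat = pihat
    call = g.sample_call_rate()
    removed: set[str] = set()
    flagged = pihat[pihat["pi_hat"] > pihat_max].sort_values("pi_hat", ascending=False)
    for row in flagged.itertuples():
        a, b = row.sample_1, row.sample_2
        if a in removed or b in removed:
            continue
        if call[a] < call[b]:
            drop = a
        elif call[b] < call[a]:
            drop = b
        else:
            drop = max(a, b)  # tie -> later sample id
        removed.add(drop)
        report.removals.append(Removal("sample", drop, "relatedness", float(row.pi_hat), pihat_max))
    keep = [s for s in g.sample_ids if s not in removed]
    return g.subset(sample_ids=keep)


def run_qc(
    g: GenotypeMatrix,
    sample_call_min: float = 0.90,
    snp_call_min: float = 0.95,
    hwe_p_min: float = 1e-5,
    maf_min: float = 0.01,
    pihat_max: float = 0.50,
    relatedness_min_snps: int = MIN_SNPS_FOR_RELATEDNESS,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pipeline in fixed order; returns the surviving matrix + report."""
    report = QCReport(thresholds={
        "sample_call_min": sample_call_min,
        "snp_call_min": snp_call_min,
        "hwe_p_min": hwe_p_min,
        "maf_min": maf_min,
        "pihat_max": pihat_max,
    })
    g = call_rate_filter(g, sample_call_min, snp_call_min, report)
    g = hwe_filter(g, hwe_p_min, report)
    g = maf_filter(g, maf_min, report)
    if g.n_samples >= 2:
        g = relatedness_filter(g, pihat_max, report, min_snps=relatedness_min_snps)
    return g, report
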