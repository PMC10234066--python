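"""Cumulative genetic score (CGS) construction.

Each SNP contributes 0, 1 or 2 points counting *score-increasing* alleles:
when the SNP's phenotype beta is positive the first-allele copy count is
used directly, and when it is negative the coding is flipped (2 - count).
Only the sign of beta enters; the default score is the unweighted sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix
from .panel import SnpPanel

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("complete_case", "mean_dosage", "rescale")


def code_snp(first_allele_copies: int, beta: float) -> int:
    """Risk-allele count for one genotype call.

    beta > 0: code = copies of the first allele; beta < 0: code is flipped.
    A zero beta leaves the orientation undefined and is rejected.
    """
    if beta == 0:
        raise ValueError("beta = 0 gives no coding orientation")
    if first_allele_copies not in (0, 1, 2):
        raise ValueError(f"first_allele_copies must be 0/1/2, got {first_allele_copies}")
    return first_allele_copies if beta > 0 else 2 - first_allele_copies


@dataclass
class CgsVector:
    sample_ids: list[str]
    phenotype_tag: str
    score: np.ndarray
    n_used: np.ndarray  # non-missing SNPs per sample

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.score) == len(self.n_used)):
            raise ValueError("sample_ids, score and n_used must align")


def compute_cgs(
    g: GenotypeMatrix,
    panel: SnpPanel,
    phenotype_tag: str = "RF",
    missing_policy: str = "mean_dosage",
    weighted: bool = False,
) -> CgsVector:
    """Sum per-SNP risk-allele codes into one score per sample.

    missing_policy:
      * ``mean_dosage`` (default) — a missing call contributes the SNP's
        mean coded dosage across non-missing samples;
      * ``rescale`` — the observed sum is scaled by n_snps / n_used;
      * ``complete_case`` — samples with any missing call are dropped
        (logged).

    ``weighted=True`` multiplies each code by |beta| instead of 1; the
    unweighted sum is the default and the scale downstream stages assume.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    betas = panel.betas(phenotype_tag)
    if np.any(betas == 0):
        raise ValueError("panel contains beta = 0 for this phenotype; coding undefined")
    order = [g.snp_ids.index(s) for s in panel.snp_ids if s in g.snp_ids]
    used_betas = np.array([panel.betas(phenotype_tag)[i]
                           for i, s in enumerate(panel.snp_ids) if s in g.snp_ids])
    codes = g.codes[:, order]

    coded = np.where(used_betas[None, :] > 0, codes, 2.0 - codes)  # NaN propagates
    if weighted:
        coded = coded * np.abs(used_betas)[None, :]
    missing = np.isnan(coded)
    n_snps = coded.shape[1]
    n_used = (~missing).sum(axis=1)

    if missing_policy == "complete_case":
        keep = n_used == n_snps
        dropped = [sid for sid, k in zip(g.sample_ids, keep) if not k]
        if dropped:
            logger.info("compute_cgs: dropped %d samples with missing genotypes: %s",
                        len(dropped), dropped[:10])
        if not keep.any():
            raise ValueError("no complete cases for CGS under complete_case policy")
        score = np.nansum(coded[keep], axis=1)
        return CgsVector([s for s, k in zip(g.sample_ids, keep) if k],
                         phenotype_tag, score, n_used[keep])

    observed_sum = np.nansum(coded, axis=1)
    if missing_policy == "rescale":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(n_used > 0, observed_sum * n_snps / np.maximum(n_used, 1), np.nan)
        all_missing = n_used == 0
        if all_missing.any():
            logger.warning("compute_cgs: %d samples have no genotypes; score set to NaN",
                           int(all_missing.sum()))
    else:  # mean_dosage
        col_mean = np.nanmean(np.where(missing, np.nan, coded), axis=0)
        filled = np.where(missing, col_mean[None, :], coded)
        score = filled.sum(axis=1)
    return CgsVector(list(g.sample_ids), phenotype_tag, score, n_used)
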