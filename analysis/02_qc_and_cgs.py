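"""Genotype QC and cumulative-score construction.

Reads the simulated genotypes back from VCF, applies the standard QC
screen (sample call rate > 0.90, SNP call rate > 0.95, HWE p >= 1e-5,
MAF > 0.01, PI_HAT <= 0.50 — skipped with a warning at 13 markers), and
appends the two phenotype-specific cumulative scores to the cohort table.
"""

import warnings
from pathlib import Path

import pandas as pd

import cgskit as ck

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "qc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = ck.SnpPanel.from_csv(ROOT / "cohort" / "panel.csv")
    genotypes = ck.read_genotypes(ROOT / "cohort" / "genotypes.vcf", "vcf", panel)
    cohort = pd.read_csv(ROOT / "cohort" / "cohort.csv", index_col=0)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clean, report = ck.run_qc(genotypes)
    report.to_json(OUT / "qc_report.json")
    report.to_tsv(OUT / "qc_removals.tsv")
    print(f"QC: {genotypes.n_samples} -> {clean.n_samples} samples, "
          f"{genotypes.n_snps} -> {clean.n_snps} SNPs "
          f"({len(report.removals)} removals)")
    for w in caught:
        print(f"  note: {w.message}")

    survivors = panel.subset(clean.snp_ids)
    for tag in ("RF", "CR"):
        vec = ck.compute_cgs(clean, survivors, phenotype_tag=tag)
        cohort[f"cgs_{tag.lower()}"] = pd.Series(vec.score, index=vec.sample_ids)
        print(f"  {tag}-score: mean {vec.score.mean():.2f}, sd {vec.score.std():.2f}")
    cohort.to_csv(OUT / "cohort_with_scores.csv")
    print(f"wrote {OUT / 'cohort_with_scores.csv'}")


if __name__ == "__main__":
    main()
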