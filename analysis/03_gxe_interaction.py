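"""Correlations, interaction regressions and the per-SNP scan.

Fits the main-effects model and the model with the PE x CGS product term,
tests the R² increment, reports simple slopes of parental education at
low/high score levels, screens each SNP's interaction against the
Bonferroni threshold 0.05/13, and writes the FDR-adjusted correlation
matrix of score, environment, outcome and mediators.
"""

from pathlib import Path

import pandas as pd

import cgskit as ck

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "gxe"
MEDIATORS = ["ran_digit", "ran_dice", "ran_picture", "ran_color"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(ROOT / "qc" / "cohort_with_scores.csv", index_col=0)
    panel = ck.SnpPanel.from_csv(ROOT / "cohort" / "panel.csv")
    genotypes = ck.read_genotypes(ROOT / "cohort" / "genotypes.vcf", "vcf", panel)

    corr = ck.correlation_matrix(cohort[["cgs_rf", "pe", "reading_fluency", *MEDIATORS]])
    corr.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    print(f"correlations: {int(corr.p_adj.lt(0.05).sum())}/{len(corr)} "
          "FDR-significant at 0.05")

    y, pe, score = cohort.reading_fluency, cohort.pe, cohort.cgs_rf
    age, sex = cohort.age, cohort.sex
    m1 = ck.fit_gxe(y, pe, score, age, sex, include_interaction=False)
    m2 = ck.fit_gxe(y, pe, score, age, sex, include_interaction=True)
    f, dfs, p = ck.delta_r2_test(m1, m2)
    table = pd.concat([m1.summary_frame().add_suffix("_main"),
                       m2.summary_frame().add_suffix("_interaction")], axis=1)
    table.to_csv(OUT / "interaction_models.tsv", sep="\t")
    print(f"main effects: PE slope {m1.coef('pe'):.2f} (R² {m1.r_squared:.3f})")
    print(f"interaction:  b3 {m2.coef('pe_x_cgs'):.3f} "
          f"(p {m2.pvalue('pe_x_cgs'):.4f}, R² {m2.r_squared:.3f})")
    print(f"R² increment: F({dfs[0]},{dfs[1]}) = {f:.2f}, p = {p:.4f}")

    levels = {"low": float(score.mean() - score.std()),
              "high": float(score.mean() + score.std())}
    slopes = ck.simple_slopes(m2, levels)
    slopes.to_csv(OUT / "simple_slopes.tsv", sep="\t")
    lines = ck.gxe.slope_lines(m2, levels, pe_grid=pd.unique(pe.sort_values()),
                               age=float(age.mean()), sex=0.5)
    lines.to_csv(OUT / "slope_lines.csv", index=False)
    for label, row in slopes.iterrows():
        print(f"  simple slope ({label} score {row.level:.1f}): "
              f"{row.slope:.2f} s per PE level (p {row.p:.2g})")
    print("  (outcome is a time: a more negative slope means faster reading)")

    scan = ck.snp_scan(y, pe, genotypes.to_frame(), age, sex)
    scan.to_csv(OUT / "snp_scan.tsv", sep="\t", index=False)
    print(f"per-SNP scan: {int(scan.significant.sum())}/{len(scan)} interactions "
          f"pass Bonferroni threshold {scan.bonferroni_threshold.iloc[0]:.4f}")


if __name__ == "__main__":
    main()
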