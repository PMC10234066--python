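"""Main-effects and interaction regressions for the G×E stage.

The working model is ordinary least squares,

    Y = B0 + B1*PE + B2*CGS + B3*(PE*CGS) + B4*Age + B5*Sex + e,

fitted with and without the product term; nested models are compared by
the F test on the R² increment.  Supporting utilities: per-grade
Z-scoring, simple slopes at low/high score levels, a per-SNP interaction
scan with Bonferroni control, and a pairwise-complete Pearson correlation
matrix with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TERMS_FULL = ("const", "pe", "cgs", "pe_x_cgs", "age", "sex")


def zscore_by_grade(values: np.ndarray, grade: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0 / SD 1 within each grade group.

    NaNs are ignored in the group moments and propagate through.  A grade
    group with fewer than 2 non-missing values or zero variance is an
    error: a Z score is undefined there.
    """
    values = np.asarray(values, dtype=float)
    grade = np.asarray(grade)
    if values.shape != grade.shape:
        raise ValueError("values and grade must align")
    out = np.empty_like(values)
    for gr in np.unique(grade):
        mask = grade == gr
        v = values[mask]
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            raise ValueError(f"grade group {gr!r} has fewer than 2 observations")
        sd = np.nanstd(v, ddof=ddof)
        if sd == 0:
            raise ValueError(f"grade group {gr!r} has zero variance")
        out[mask] = (v - np.nanmean(v)) / sd
    return out


@dataclass
class GxEFit:
    """OLS coefficient set with inference for the interaction model."""

    terms: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n: int
    rss: float
    resid_var: float
    include_interaction: bool

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}, index=list(self.terms)
        )


def _design(pe, cgs, age, sex, include_interaction):
    cols = {"pe": pe, "cgs": cgs}
    if include_interaction:
        cols["pe_x_cgs"] = np.asarray(pe) * np.asarray(cgs)
    cols["age"] = age
    cols["sex"] = sex
    X = pd.DataFrame(cols)
    return sm.add_constant(X, prepend=True)


def fit_gxe(
    y: np.ndarray,
    pe: np.ndarray,
    cgs: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    include_interaction: bool = True,
) -> GxEFit:
    """Fit the main-effects (no product term) or interaction OLS model.

    Cases with any missing value are dropped listwise.  Rank deficiency
    (e.g. a constant score) raises with a diagnostic.
    """
    df = pd.DataFrame({"y": y, "pe": pe, "cgs": cgs, "age": age, "sex": sex}).dropna()
    k = 6 if include_interaction else 5
    if len(df) < k + 2:
        raise ValueError(f"need at least {k + 2} complete cases, have {len(df)}")
    X = _design(df["pe"], df["cgs"], df["age"], df["sex"], include_interaction)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            "check for constant or collinear predictors"
        )
    res = sm.OLS(df["y"].to_numpy(), X).fit()
    return GxEFit(
        terms=tuple(X.columns),
        params=res.params.to_numpy(),
        bse=res.bse.to_numpy(),
        pvalues=res.pvalues.to_numpy(),
        cov_params=res.cov_params().to_numpy(),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
        rss=float(res.ssr),
        resid_var=float(res.ssr / res.df_resid),
        include_interaction=include_interaction,
    )


def delta_r2_test(fit_reduced: GxEFit, fit_full: GxEFit) -> tuple[float, tuple[int, int], float]:
    """F test of the R² increment between nested OLS fits on the same cases.

    F = (dR²/dk) / ((1 - R²_full) / df_resid_full), df = (dk, df_resid_full).
    """
    if fit_reduced.n != fit_full.n:
        raise ValueError("fits must use identical cases (n differs)")
    if fit_reduced.terms == fit_full.terms:
        # degenerate comparison of a model with itself: no increment
        return 0.0, (0, fit_full.df_resid), 1.0
    dk = fit_full.df_model - fit_reduced.df_model
    if dk <= 0 or not set(fit_reduced.terms) < set(fit_full.terms):
        raise ValueError("fit_full must strictly nest fit_reduced")
    dr2 = fit_full.r_squared - fit_reduced.r_squared
    f = (dr2 / dk) / ((1.0 - fit_full.r_squared) / fit_full.df_resid)
    p = float(stats.f.sf(f, dk, fit_full.df_resid)) if f > 0 else 1.0
    return float(f), (dk, fit_full.df_resid), p


def simple_slopes(
    fit: GxEFit,
    gene_levels: dict[str, float],
) -> pd.DataFrame:
    """Slope of the environment at chosen score levels, with SE and p.

    slope(g) = B1 + B3*g;  Var = V11 + g² V33 + 2 g V13 from the
    coefficient covariance.  ``gene_levels`` maps labels (e.g. "low",
    "high") to score values, conventionally mean ∓ 1 SD.
    """
    if not fit.include_interaction:
        raise ValueError("simple slopes require the interaction fit")
    i1 = fit.terms.index("pe")
    i3 = fit.terms.index("pe_x_cgs")
    rows = {}
    for label, g in gene_levels.items():
        slope = fit.params[i1] + fit.params[i3] * g
        var = (
            fit.cov_params[i1, i1]
            + g * g * fit.cov_params[i3, i3]
            + 2 * g * fit.cov_params[i1, i3]
        )
        se = float(np.sqrt(var))
        t = slope / se
        rows[label] = {
            "level": g,
            "slope": float(slope),
            "se": se,
            "t": float(t),
            "p": float(2 * stats.t.sf(abs(t), fit.df_resid)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def slope_lines(fit: GxEFit, gene_levels: dict[str, float],
                pe_grid: np.ndarray, age: float, sex: float) -> pd.DataFrame:
    """Plot-ready predicted outcome lines over a PE grid per score level."""
    rows = []
    for label, g in gene_levels.items():
        for pe in pe_grid:
            pred = (
                fit.coef("const") + fit.coef("pe") * pe + fit.coef("cgs") * g
                + fit.coef("pe_x_cgs") * pe * g + fit.coef("age") * age + fit.coef("sex") * sex
            )
            rows.append({"group": label, "cgs": g, "pe": pe, "predicted": pred})
    return pd.DataFrame(rows)


def snp_scan(
    y: np.ndarray,
    pe: np.ndarray,
    genotypes: pd.DataFrame,
    age: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP interaction regressions with a Bonferroni threshold.

    Each SNP enters additively (0/1/2 first-allele copies); the product
    term's p-value is compared to alpha / m over the m testable SNPs.
    Monomorphic SNPs are skipped with a log entry.
    """
    if genotypes.shape[1] < 1:
        raise ValueError("need at least one SNP")
    rows = []
    for sid in genotypes.columns:
        geno = genotypes[sid].to_numpy(dtype=float)
        ok = ~np.isnan(geno)
        if np.nanstd(geno) == 0:
            logger.info("snp_scan: %s is monomorphic, skipped", sid)
            continue
        fit = fit_gxe(np.asarray(y)[ok], np.asarray(pe)[ok], geno[ok],
                      np.asarray(age)[ok], np.asarray(sex)[ok], include_interaction=True)
        rows.append({
            "snp_id": sid,
            "b_interaction": fit.coef("pe_x_cgs"),
            "se_interaction": fit.se("pe_x_cgs"),
            "p_interaction": fit.pvalue("pe_x_cgs"),
            "r_squared": fit.r_squared,
            "n": fit.n,
        })
    out = pd.DataFrame(rows)
    m = len(out)
    threshold = alpha / m if m else np.nan
    out["bonferroni_threshold"] = threshold
    out["significant"] = out["p_interaction"] < threshold
    return out


def correlation_matrix(variables: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with BH-adjusted p-values.

    Returns the long-format report (one row per unordered pair) with the
    raw and Benjamini-Hochberg adjusted p over the full reported set, and
    significance marks at 0.05 / 0.01 on the adjusted p.
    """
    cols = list(variables.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = variables[[a, b]].dropna()
            if len(pair) < min_pairs:
                raise ValueError(f"fewer than {min_pairs} complete pairs for ({a}, {b})")
            if pair[a].std() == 0 or pair[b].std() == 0:
                raise ValueError(f"constant variable in pair ({a}, {b})")
            r, p = stats.pearsonr(pair[a], pair[b])
            rows.append({"var_1": a, "var_2": b, "r": float(r), "p": float(p), "n": len(pair)})
    report = pd.DataFrame(rows)
    if len(report):
        _, adj, _, _ = multipletests(report["p"], method="fdr_bh")
        report["p_adj"] = adj
        report["mark"] = np.select(
            [report["p_adj"] < 0.01, report["p_adj"] < 0.05], ["**", "*"], default=""
        )
    return report


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha/m for an m-SNP interaction scan."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
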