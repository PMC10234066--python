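"""Parallel multiple-mediator path analysis with bootstrap inference.

The model is recursive: each mediator is regressed on the genetic score
plus covariates (a-paths), and the outcome on the score, all mediators and
covariates (b-paths and the direct effect c').  With free mediator
residual covariances the per-equation least-squares estimates are the ML
point estimates, so no general SEM engine is needed; full-covariance ML
enters only in the fit indices, where the model-implied covariance is
compared with the sample covariance.

Specific indirect effects are the products a_j * b_j, the total indirect
their sum, and significance comes from percentile bootstrap confidence
intervals over case resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta, se, residuals) for y on X (X includes the constant)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        xtx = X.T @ X
        cond = np.linalg.cond(xtx)
        raise ValueError(f"collinear predictors (rank {rank} < {X.shape[1]}, "
                         f"condition number {cond:.3g})")
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), resid


@dataclass
class MediationFit:
    mediator_names: tuple[str, ...]
    a: np.ndarray               # gene -> mediator, input scale
    a_se: np.ndarray
    b: np.ndarray               # mediator -> outcome
    b_se: np.ndarray
    c_prime: float              # direct gene -> outcome
    c_prime_se: float
    covariate_paths: dict       # age/sex coefficients in the outcome equation
    a_std: np.ndarray           # standardized (sd-ratio scaled) counterparts
    b_std: np.ndarray
    c_prime_std: float
    mediator_resid: np.ndarray = field(repr=False)   # n x k residual matrix
    outcome_resid: np.ndarray = field(repr=False)
    n: int = 0

    @property
    def specific_indirect(self) -> np.ndarray:
        return self.a * self.b

    @property
    def total_indirect(self) -> float:
        return float(self.specific_indirect.sum())

    @property
    def specific_indirect_std(self) -> np.ndarray:
        return self.a_std * self.b_std

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"path": f"gene -> {m} -> outcome", "a": self.a[j], "b": self.b[j],
             "indirect": self.a[j] * self.b[j],
             "indirect_std": self.a_std[j] * self.b_std[j]}
            for j, m in enumerate(self.mediator_names)
        ]
        rows.append({"path": "total indirect", "a": np.nan, "b": np.nan,
                     "indirect": self.total_indirect,
                     "indirect_std": float(self.specific_indirect_std.sum())})
        rows.append({"path": "direct (c')", "a": np.nan, "b": np.nan,
                     "indirect": self.c_prime, "indirect_std": self.c_prime_std})
        return pd.DataFrame(rows)


def _prepare(gene, mediators, outcome, age, sex, grade, standardize):
    from .gxe import zscore_by_grade

    med = pd.DataFrame(mediators).reset_index(drop=True)
    df = pd.concat(
        [pd.Series(np.asarray(gene, float), name="gene"), med,
         pd.Series(np.asarray(outcome, float), name="outcome"),
         pd.Series(np.asarray(age, float), name="age"),
         pd.Series(np.asarray(sex, float), name="sex")], axis=1)
    if grade is not None:
        df["grade"] = np.asarray(grade)
    df = df.dropna().reset_index(drop=True)
    if standardize == "by_grade":
        if grade is None:
            raise ValueError("per-grade standardization requires grade")
        for col in ["gene", "outcome", *med.columns]:
            df[col] = zscore_by_grade(df[col].to_numpy(), df["grade"].to_numpy())
    elif standardize == "overall":
        for col in ["gene", "outcome", *med.columns]:
            df[col] = (df[col] - df[col].mean()) / df[col].std(ddof=1)
    elif standardize != "none":
        raise ValueError("standardize must be 'none', 'overall' or 'by_grade'")
    return df, list(med.columns)


def fit_path_model(
    gene,
    mediators: pd.DataFrame,
    outcome,
    age,
    sex,
    grade=None,
    standardize: str = "none",
    omit_direct: bool = False,
) -> MediationFit:
    """Fit the parallel-mediation path model by per-equation least squares.

    ``standardize`` applies the study's per-grade Z-scoring ("by_grade"),
    a plain overall Z-scoring ("overall"), or leaves variables on their
    input scale ("none", default — path coefficients then multiply raw
    units).  ``mediators`` is a DataFrame with one column per mediator.
    A warning is logged when complete cases are fewer than five times the
    parameter count.
    """
    df, med_names = _prepare(gene, mediators, outcome, age, sex, grade, standardize)
    k = len(med_names)
    n = len(df)
    n_params = 3 * k + (k + 3) + k * (k + 1) // 2 + 7
    if n < 5 * n_params:
        logger.warning("fit_path_model: n=%d below 5x parameter count (%d)", n, 5 * n_params)

    ones = np.ones(n)
    Xa = np.column_stack([ones, df["gene"], df["age"], df["sex"]])
    a = np.empty(k)
    a_se = np.empty(k)
    m_resid = np.empty((n, k))
    for j, name in enumerate(med_names):
        beta, se, resid = _ols(Xa, df[name].to_numpy())
        a[j], a_se[j] = beta[1], se[1]
        m_resid[:, j] = resid

    med_block = df[med_names].to_numpy()
    if omit_direct:
        Xy = np.column_stack([ones, med_block, df["age"], df["sex"]])
        beta, se, y_resid = _ols(Xy, df["outcome"].to_numpy())
        c_prime, c_prime_se = 0.0, np.nan
        b, b_se = beta[1:1 + k], se[1:1 + k]
        cov_paths = {"age": float(beta[1 + k]), "sex": float(beta[2 + k])}
    else:
        Xy = np.column_stack([ones, df["gene"], med_block, df["age"], df["sex"]])
        beta, se, y_resid = _ols(Xy, df["outcome"].to_numpy())
        c_prime, c_prime_se = float(beta[1]), float(se[1])
        b, b_se = beta[2:2 + k], se[2:2 + k]
        cov_paths = {"age": float(beta[2 + k]), "sex": float(beta[3 + k])}

    sd_g = df["gene"].std(ddof=1)
    sd_m = df[med_names].std(ddof=1).to_numpy()
    sd_y = df["outcome"].std(ddof=1)
    return MediationFit(
        mediator_names=tuple(med_names),
        a=a, a_se=a_se, b=b, b_se=b_se,
        c_prime=c_prime, c_prime_se=c_prime_se,
        covariate_paths=cov_paths,
        a_std=a * sd_g / sd_m, b_std=b * sd_m / sd_y,
        c_prime_std=c_prime * sd_g / sd_y,
        mediator_resid=m_resid, outcome_resid=y_resid, n=n,
    )


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_indirect(
    gene,
    mediators: pd.DataFrame,
    outcome,
    age,
    sex,
    replicates: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    grade=None,
    standardize: str = "none",
    stratify_by_grade: bool = False,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for specific and total indirect effects.

    Whole cases (rows) are resampled with replacement; ``replicates``
    defaults to 5000 and an effect is called significant when its CI
    excludes zero.  Degenerate resamples (constant gene) are redrawn and
    counted in the log.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    point = fit_path_model(gene, mediators, outcome, age, sex,
                           grade=grade, standardize=standardize)
    df, med_names = _prepare(gene, mediators, outcome, age, sex, grade, "none")
    n = len(df)
    k = len(med_names)
    rng = np.random.default_rng(seed)
    gene_arr = df["gene"].to_numpy()
    grade_arr = df["grade"].to_numpy() if "grade" in df else None

    med_arr = df[med_names].to_numpy()
    y_arr = df["outcome"].to_numpy()
    age_arr = df["age"].to_numpy()
    sex_arr = df["sex"].to_numpy()
    fast = standardize == "none" and not stratify_by_grade
    draws = np.empty((replicates, k + 1))
    redraws = 0
    for r in range(replicates):
        while True:
            if stratify_by_grade and grade_arr is not None:
                idx = np.concatenate([
                    rng.choice(np.flatnonzero(grade_arr == gr),
                               size=(grade_arr == gr).sum(), replace=True)
                    for gr in np.unique(grade_arr)
                ])
            else:
                idx = rng.integers(0, n, size=n)
            if np.ptp(gene_arr[idx]) > 0:
                break
            redraws += 1
        if fast:
            # plain-numpy refit: same estimator as fit_path_model on the
            # input scale, without the container overhead
            ones = np.ones(n)
            Xa = np.column_stack([ones, gene_arr[idx], age_arr[idx], sex_arr[idx]])
            a_r = np.linalg.lstsq(Xa, med_arr[idx], rcond=None)[0][1]
            Xy = np.column_stack([ones, gene_arr[idx], med_arr[idx],
                                  age_arr[idx], sex_arr[idx]])
            b_r = np.linalg.lstsq(Xy, y_arr[idx], rcond=None)[0][2:2 + k]
            draws[r, :k] = a_r * b_r
            draws[r, k] = float(np.sum(a_r * b_r))
        else:
            sub = df.iloc[idx]
            fit = fit_path_model(
                sub["gene"], sub[med_names], sub["outcome"], sub["age"], sub["sex"],
                grade=sub["grade"] if grade_arr is not None else None,
                standardize=standardize,
            )
            draws[r, :k] = fit.specific_indirect
            draws[r, k] = fit.total_indirect
    if redraws:
        logger.info("bootstrap_indirect: redrew %d degenerate resamples", redraws)

    alpha = 1.0 - ci_level
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    estimates = np.append(point.specific_indirect, point.total_indirect)
    labels = [f"gene -> {m} -> outcome" for m in med_names] + ["total indirect"]
    out = pd.DataFrame({
        "effect": labels,
        "estimate": estimates,
        "boot_se": draws.std(axis=0, ddof=1),
        "ci_low": lo,
        "ci_high": hi,
    })
    out["significant"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    return out


# ---------------------------------------------------------------------------
# fit indices

@dataclass
class FitIndices:
    chi_square: float
    df: int
    chi_square_per_df: float
    cfi: float
    tli: float
    rmsea: float

    def passes_conventional_cutoffs(self) -> dict:
        """Conventional adequacy marks: CFI > 0.90, TLI > 0.90, chi2/df < 3."""
        return {
            "cfi_gt_0.90": self.cfi > 0.90,
            "tli_gt_0.90": self.tli > 0.90,
            "chi2_per_df_lt_3": self.chi_square_per_df < 3 if self.df > 0 else True,
        }


def _recursive_indices(
    df: pd.DataFrame,
    exog: list[str],
    endo_equations: dict[str, list[str]],
    free_resid_cov: list[str],
) -> FitIndices:
    """Fit indices for a recursive path model estimated per equation.

    ``endo_equations`` maps each endogenous variable to its regressors (a
    constant is always included); residual covariances are freed among the
    variables listed in ``free_resid_cov`` (a subset of the endogenous
    ones).  The implied covariance is (I - B)^-1 Psi (I - B)^-T with the
    exogenous block of Psi taken saturated from the sample.
    """
    endo = list(endo_equations)
    order = exog + endo
    p = len(order)
    n = len(df)
    S = df[order].cov(ddof=1).to_numpy()
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance is not positive definite")

    pos = {v: i for i, v in enumerate(order)}
    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    psi[:len(exog), :len(exog)] = S[:len(exog), :len(exog)]
    resids = {}
    ones = np.ones(n)
    n_free = len(exog) * (len(exog) + 1) // 2
    for var, regressors in endo_equations.items():
        X = np.column_stack([ones] + [df[r].to_numpy() for r in regressors])
        beta, _, resid = _ols(X, df[var].to_numpy())
        for coef, r in zip(beta[1:], regressors):
            B[pos[var], pos[r]] = coef
        resids[var] = resid
        n_free += len(regressors)
    # residual (co)variances
    for i, v in enumerate(endo):
        psi[pos[v], pos[v]] = np.var(resids[v], ddof=1)
        n_free += 1
    for i, v in enumerate(free_resid_cov):
        for w in free_resid_cov[i + 1:]:
            cov = float(np.cov(resids[v], resids[w], ddof=1)[0, 1])
            psi[pos[v], pos[w]] = psi[pos[w], pos[v]] = cov
            n_free += 1

    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv @ psi @ inv.T
    df_m = p * (p + 1) // 2 - n_free
    _, logdet_sigma = np.linalg.slogdet(sigma)
    f_ml = logdet_sigma - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    chi_m = max((n - 1) * f_ml, 0.0)

    if df_m <= 0:
        return FitIndices(0.0, 0, 0.0, 1.0, 1.0, 0.0)
    # independence baseline: free variances, zero covariances
    f_b = float(np.sum(np.log(np.diag(S)))) - logdet_s \
        + float(np.trace(S @ np.linalg.inv(np.diag(np.diag(S))))) - p
    chi_b = max((n - 1) * f_b, 0.0)
    df_b = p * (p + 1) // 2 - p
    cfi = 1.0 - max(chi_m - df_m, 0.0) / max(chi_b - df_b, chi_m - df_m, 1e-300)
    tli = ((chi_b / df_b) - (chi_m / df_m)) / max((chi_b / df_b) - 1.0, 1e-300)
    tli = min(max(tli, 0.0), 1.0)
    cfi = min(max(cfi, 0.0), 1.0)
    rmsea = float(np.sqrt(max(chi_m - df_m, 0.0) / (df_m * (n - 1))))
    return FitIndices(float(chi_m), int(df_m), float(chi_m / df_m), float(cfi), float(tli), rmsea)


def fit_indices(
    gene,
    mediators: pd.DataFrame,
    outcome,
    age,
    sex,
    grade=None,
    standardize: str = "none",
    omit_direct: bool = False,
) -> FitIndices:
    """ML-discrepancy fit indices for the parallel-mediation path model.

    chi^2 = (n-1) F_ML with F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p;
    the baseline model frees only the variances.  The full model (direct
    effect included, mediator residual covariances free) is just
    identified, so it reports the saturated-model convention chi^2 = 0,
    CFI = 1, RMSEA = 0; ``omit_direct=True`` drops the gene -> outcome
    path and yields one testable degree of freedom.
    """
    df, med_names = _prepare(gene, mediators, outcome, age, sex, grade, standardize)
    eqs = {m: ["gene", "age", "sex"] for m in med_names}
    y_regs = ([*med_names, "age", "sex"] if omit_direct
              else ["gene", *med_names, "age", "sex"])
    eqs["outcome"] = y_regs
    return _recursive_indices(df, ["gene", "age", "sex"], eqs, med_names)


# ---------------------------------------------------------------------------
# moderated mediation

def fit_moderated_mediation(
    gene,
    moderator,
    mediators: pd.DataFrame,
    outcome,
    age,
    sex,
    replicates: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame, FitIndices]:
    """First-stage moderated mediation: gene x moderator -> mediator -> outcome.

    Each mediator is regressed on gene, moderator, their product and the
    covariates; the index of moderated mediation for mediator j is the
    product of its interaction a-path with its b-path, with a percentile
    bootstrap CI.  Returns (path table, index table, fit indices); the
    indices treat the gene x moderator product as an exogenous variable of
    its own, so they are descriptive rather than strictly distributional.
    """
    med = pd.DataFrame(mediators).reset_index(drop=True)
    df = pd.concat(
        [pd.Series(np.asarray(gene, float), name="gene"),
         pd.Series(np.asarray(moderator, float), name="mod"), med,
         pd.Series(np.asarray(outcome, float), name="outcome"),
         pd.Series(np.asarray(age, float), name="age"),
         pd.Series(np.asarray(sex, float), name="sex")], axis=1).dropna()
    med_names = list(med.columns)
    k = len(med_names)

    def _indices(frame) -> tuple[np.ndarray, pd.DataFrame]:
        n = len(frame)
        ones = np.ones(n)
        inter = frame["gene"].to_numpy() * frame["mod"].to_numpy()
        Xa = np.column_stack([ones, frame["gene"], frame["mod"], inter,
                              frame["age"], frame["sex"]])
        a_int = np.empty(k)
        a_main = np.empty(k)
        for j, name in enumerate(med_names):
            beta, _, _ = _ols(Xa, frame[name].to_numpy())
            a_main[j], a_int[j] = beta[1], beta[3]
        Xy = np.column_stack([ones, frame["gene"], frame[med_names].to_numpy(),
                              frame["mod"], frame["age"], frame["sex"]])
        beta_y, _, _ = _ols(Xy, frame["outcome"].to_numpy())
        b = beta_y[2:2 + k]
        paths = pd.DataFrame({"mediator": med_names, "a_main": a_main,
                              "a_interaction": a_int, "b": b})
        return a_int * b, paths

    point, paths = _indices(df)
    rng = np.random.default_rng(seed)
    draws = np.empty((replicates, k))
    n = len(df)
    for r in range(replicates):
        idx = rng.integers(0, n, size=n)
        draws[r], _ = _indices(df.iloc[idx])
    alpha = 1.0 - ci_level
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    index = pd.DataFrame({
        "mediator": med_names,
        "index_of_moderated_mediation": point,
        "ci_low": lo,
        "ci_high": hi,
    })
    index["significant"] = (index["ci_low"] > 0) | (index["ci_high"] < 0)

    aug = df.copy()
    aug["gene_x_mod"] = aug["gene"] * aug["mod"]
    eqs = {m: ["gene", "mod", "gene_x_mod", "age", "sex"] for m in med_names}
    eqs["outcome"] = ["gene", *med_names, "mod", "age", "sex"]
    indices = _recursive_indices(aug, ["gene", "mod", "gene_x_mod", "age", "sex"],
                                 eqs, med_names)
    return paths, index, indices
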