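"""Reparameterized crossover models and regime competition.

The interaction OLS model can be rewritten exactly as

    Y = B0 + B1*(PE - C) + B2*((PE - C) * CGS) + B_age*Age + B_sex*Sex + e,

where C — the PE value at which the regression lines for different score
levels intersect — becomes an explicit parameter with a standard error.
A disordinal (crossover-inside-the-range) interaction supports the
differential-susceptibility reading; pinning C at the observed PE maximum
gives the nested diathesis-stress model, and the two are compared by an
R²-increment F test and by AIC/BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
import statsmodels.api as sm

from .gxe import GxEFit, fit_gxe

FREE_TERMS = ("B0", "B1", "B2", "C", "B_age", "B_sex")


@dataclass
class CrossoverFit:
    terms: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray            # SE of C is NaN when c_fixed
    c_fixed: bool
    c_ci: tuple[float, float] | None
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n: int
    rss: float
    loglik: float
    aic: float
    bic: float
    n_mean_params: int

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    @property
    def c(self) -> float:
        return self.coef("C")


@dataclass
class RegimeCall:
    regime: str
    env_range: tuple[float, float]
    rationale: str


def _gaussian_loglik(rss: float, n: int) -> float:
    """Log-likelihood at the residual-variance MLE (sigma^2 = RSS/n)."""
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _ics(rss: float, n: int, n_mean_params: int) -> tuple[float, float, float]:
    """(loglik, AIC, BIC); k counts mean parameters plus one for the variance."""
    ll = _gaussian_loglik(rss, n)
    k = n_mean_params + 1
    return ll, -2 * ll + 2 * k, -2 * ll + k * np.log(n)


def _complete(y, pe, cgs, age, sex):
    arrs = [np.asarray(a, dtype=float) for a in (y, pe, cgs, age, sex)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all inputs must have equal length")
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    return [a[ok] for a in arrs]


def fit_free_crossover(
    y, pe, cgs, age, sex,
    ci_level: float = 0.95,
    ci_method: str = "wald",
    b3_tol: float = 1e-10,
) -> CrossoverFit:
    """Nonlinear least squares over (B0, B1, B2, C, B_age, B_sex).

    The model is an exact reparameterization of the interaction OLS fit, so
    the optimizer is seeded at the closed-form map from that fit
    (C = -b2/b3, B0 = b0 + b1*C, B1 = b1, B2 = b3) and converges
    deterministically; a coarse grid multi-start over the observed PE range
    backs up near-degenerate starts.  SEs come from the NLS Jacobian;
    the CI for C is Wald by default or profile-likelihood on request.

    Raises if the interaction coefficient magnitude is below ``b3_tol``:
    C is then unidentifiable.
    """
    y, pe, cgs, age, sex = _complete(y, pe, cgs, age, sex)
    lin = fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
    b0, b1, b2, b3 = (lin.coef(t) for t in ("const", "pe", "cgs", "pe_x_cgs"))
    if abs(b3) <= b3_tol:
        raise ValueError(
            f"interaction coefficient {b3:.3g} is below tolerance {b3_tol:g}; "
            "the crossover point is unidentifiable"
        )
    c0 = -b2 / b3
    x0 = np.array([b0 + b1 * c0, b1, b3, c0, lin.coef("age"), lin.coef("sex")])

    def model(theta):
        B0, B1, B2, C, Ba, Bs = theta
        u = pe - C
        return B0 + B1 * u + B2 * u * cgs + Ba * age + Bs * sex

    def residuals(theta):
        return y - model(theta)

    def jac(theta):
        _, B1, B2, C, _, _ = theta
        u = pe - C
        cols = np.column_stack([
            np.ones_like(u), u, u * cgs, -(B1 + B2 * cgs), age, sex
        ])
        return -cols

    sol = optimize.least_squares(residuals, x0, jac=jac, method="lm",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    # multi-start fallback over the observed PE range if the seeded run
    # failed to reach the RSS the linear fit guarantees is attainable
    if not sol.success or np.sum(sol.fun**2) > lin.rss * (1 + 1e-8):
        best = sol
        for c_try in np.linspace(pe.min(), pe.max(), 11):
            x_try = x0.copy()
            x_try[3] = c_try
            cand = optimize.least_squares(residuals, x_try, jac=jac, method="lm",
                                          xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if np.sum(cand.fun**2) < np.sum(best.fun**2):
                best = cand
        sol = best

    theta = sol.x
    rss = float(np.sum(sol.fun**2))
    n = len(y)
    k = 6
    resid_var = rss / (n - k)
    J = jac(theta)
    cov = resid_var * np.linalg.inv(J.T @ J)
    bse = np.sqrt(np.diag(cov))

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    if ci_method == "wald":
        ci = (theta[3] - z * bse[3], theta[3] + z * bse[3])
    elif ci_method == "profile":
        ci = _profile_ci_c(y, pe, cgs, age, sex, rss, n, level=ci_level)
    else:
        raise ValueError("ci_method must be 'wald' or 'profile'")

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    df_model, df_resid = k - 1, n - k
    f = np.inf if r2 >= 1.0 else (r2 / df_model) / ((1 - r2) / df_resid)
    ll, aic, bic = _ics(rss, n, k)
    return CrossoverFit(
        terms=FREE_TERMS, params=theta, bse=bse, c_fixed=False,
        c_ci=(float(ci[0]), float(ci[1])), r_squared=r2, f_statistic=float(f),
        df_model=df_model, df_resid=df_resid, n=n, rss=rss,
        loglik=ll, aic=float(aic), bic=float(bic), n_mean_params=k,
    )


def _rss_at_c(y, pe, cgs, age, sex, c: float) -> float:
    u = pe - c
    X = sm.add_constant(np.column_stack([u, u * cgs, age, sex]), prepend=True)
    res = sm.OLS(y, X).fit()
    return float(res.ssr)


def _profile_ci_c(y, pe, cgs, age, sex, rss_min, n, level=0.95) -> tuple[float, float]:
    """Profile-likelihood CI: {C : n log(RSS(C)/RSS_min) <= chi2_1(level)}."""
    cut = stats.chi2.ppf(level, df=1)

    def excess(c):
        return n * np.log(_rss_at_c(y, pe, cgs, age, sex, c) / rss_min) - cut

    span = pe.max() - pe.min()
    lo_grid = np.linspace(pe.min() - 3 * span, pe.max() + 3 * span, 801)
    vals = np.array([excess(c) for c in lo_grid])
    inside = np.where(vals <= 0)[0]
    if len(inside) == 0:
        return (np.nan, np.nan)
    lo, hi = lo_grid[inside[0]], lo_grid[inside[-1]]
    if inside[0] > 0:
        lo = optimize.brentq(excess, lo_grid[inside[0] - 1], lo)
    if inside[-1] < len(lo_grid) - 1:
        hi = optimize.brentq(excess, hi, lo_grid[inside[-1] + 1])
    return float(lo), float(hi)


def fit_fixed_crossover(y, pe, cgs, age, sex, c_fixed: float | None = None) -> CrossoverFit:
    """Linear least squares with the crossover point held fixed.

    ``c_fixed`` defaults to the observed maximum of PE (crossover at the
    most favorable environment: the diathesis-stress competitor).  C has no
    SE or CI; one fewer free parameter than the free-crossover model.
    """
    y, pe, cgs, age, sex = _complete(y, pe, cgs, age, sex)
    c = float(pe.max()) if c_fixed is None else float(c_fixed)
    if not np.isfinite(c):
        raise ValueError("c_fixed must be finite")
    u = pe - c
    X = sm.add_constant(np.column_stack([u, u * cgs, age, sex]), prepend=True)
    res = sm.OLS(y, X).fit()
    n, k = len(y), 5
    params = np.array([res.params[0], res.params[1], res.params[2], c,
                       res.params[3], res.params[4]])
    bse = np.array([res.bse[0], res.bse[1], res.bse[2], np.nan, res.bse[3], res.bse[4]])
    ll, aic, bic = _ics(float(res.ssr), n, k)
    return CrossoverFit(
        terms=FREE_TERMS, params=params, bse=bse, c_fixed=True, c_ci=None,
        r_squared=float(res.rsquared), f_statistic=float(res.fvalue),
        df_model=int(res.df_model), df_resid=int(res.df_resid), n=n,
        rss=float(res.ssr), loglik=ll, aic=float(aic), bic=float(bic),
        n_mean_params=k,
    )


@dataclass
class ModelComparison:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    delta_aic: float   # fixed - free; positive favors the free model
    delta_bic: float
    selected: str      # "free", "fixed" or "ambiguous"


def compare_models(free: CrossoverFit, fixed: CrossoverFit) -> ModelComparison:
    """F test on the R² increment plus AIC/BIC comparison of the nested pair."""
    if free.n != fixed.n:
        raise ValueError("models must be fitted to the same cases")
    if free.c_fixed or not fixed.c_fixed:
        raise ValueError("expected (free-C, fixed-C) in that order")
    dk = free.n_mean_params - fixed.n_mean_params
    f = ((fixed.rss - free.rss) / dk) / (free.rss / (free.n - free.n_mean_params))
    f = max(f, 0.0)
    p = float(stats.f.sf(f, dk, free.n - free.n_mean_params))
    d_aic = fixed.aic - free.aic
    d_bic = fixed.bic - free.bic
    if d_aic > 0 and d_bic > 0:
        selected = "free"
    elif d_aic < 0 and d_bic < 0:
        selected = "fixed"
    else:
        selected = "ambiguous"
    return ModelComparison(float(f), (dk, free.n - free.n_mean_params), p,
                           float(d_aic), float(d_bic), selected)


def classify_regime(
    fit: CrossoverFit,
    env_min: float,
    env_max: float,
    vantage_fraction: float = 0.2,
) -> RegimeCall:
    """Call the G×E regime from the crossover point and its CI.

    Disordinal rule: C and its entire CI inside [env_min, env_max] gives
    differential susceptibility; otherwise the interaction is ordinal
    (diathesis-stress).  A crossover in the lowest ``vantage_fraction`` of
    the range is additionally flagged as a vantage-sensitivity candidate
    (genotypes differing mainly in benefit from enriched environments).
    """
    if fit.c_ci is None:
        raise ValueError("regime classification requires a free-C fit with a CI")
    lo, hi = fit.c_ci
    c = fit.c
    interior = env_min <= lo and hi <= env_max and env_min <= c <= env_max
    cutoff = env_min + vantage_fraction * (env_max - env_min)
    if c <= cutoff:
        return RegimeCall(
            "vantage_sensitivity_candidate", (env_min, env_max),
            f"C = {c:.3f} lies within the lowest {vantage_fraction:.0%} of the "
            f"environment range [{env_min}, {env_max}] (cutoff {cutoff:.3f})",
        )
    if interior:
        return RegimeCall(
            "differential_susceptibility", (env_min, env_max),
            f"C = {c:.3f} with CI [{lo:.3f}, {hi:.3f}] lies fully inside "
            f"[{env_min}, {env_max}]: disordinal interaction",
        )
    return RegimeCall(
        "diathesis_stress", (env_min, env_max),
        f"C = {c:.3f} with CI [{lo:.3f}, {hi:.3f}] is not fully inside "
        f"[{env_min}, {env_max}]: ordinal interaction",
    )
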