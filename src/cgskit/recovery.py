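"""Parameter-recovery simulations at the package-default effect sizes.

Repeatedly generates cohorts under the default crossover truth (or a
caller-supplied one), fits the interaction OLS model and the free- and
fixed-crossover models on each, and collects the per-replicate estimates.
This is the engine behind the recovery acceptance checks and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossover import compare_models, fit_fixed_crossover, fit_free_crossover
from .gxe import fit_gxe
from .simulate import GxETruth, default_gxe_truth, simulate_gxe_cohort


def run_recovery_simulation(
    n_cohorts: int = 200,
    n: int = 1589,
    seed: int = 1,
    truth: GxETruth | None = None,
    fit_fixed: bool = False,
) -> pd.DataFrame:
    """One row per simulated cohort with interaction and crossover estimates.

    Columns: linear-model slopes (``b1_lin``, ``b2_lin``, ``b3_lin``),
    free-crossover estimates (``b1_free``, ``b2_free``, ``c_hat`` with
    ``c_se`` and Wald CI bounds), a flag for whether the CI covers the
    generating crossover, and — when ``fit_fixed`` — the AIC/BIC
    differences against the crossover-at-PE-max competitor and which model
    they select.
    """
    truth = truth or default_gxe_truth()
    seeds = np.random.SeedSequence(seed).spawn(n_cohorts)
    rows = []
    for ss in seeds:
        cohort_seed = int(ss.generate_state(1)[0] % (2**31))
        _, t = simulate_gxe_cohort(n, seed=cohort_seed, truth=truth)
        y, pe, cgs = t["reading_fluency"], t["pe"], t["cgs"]
        age, sex = t["age"], t["sex"]
        lin = fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
        free = fit_free_crossover(y, pe, cgs, age, sex)
        row = {
            "seed": cohort_seed,
            "b1_lin": lin.coef("pe"),
            "b2_lin": lin.coef("cgs"),
            "b3_lin": lin.coef("pe_x_cgs"),
            "r2": lin.r_squared,
            "b1_free": free.coef("B1"),
            "b2_free": free.coef("B2"),
            "c_hat": free.c,
            "c_se": free.se("C"),
            "c_ci_low": free.c_ci[0],
            "c_ci_high": free.c_ci[1],
            "c_covered": free.c_ci[0] <= truth.c <= free.c_ci[1],
        }
        if fit_fixed:
            fixed = fit_fixed_crossover(y, pe, cgs, age, sex, c_fixed=float(pe.max()))
            comp = compare_models(free, fixed)
            row.update({
                "delta_aic": comp.delta_aic,
                "delta_bic": comp.delta_bic,
                "selected": comp.selected,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame, truth: GxETruth | None = None) -> dict:
    """Means, Monte-Carlo SEs and CI coverage for the key parameters."""
    truth = truth or default_gxe_truth()
    reps = len(results)

    def stat(col):
        m = float(results[col].mean())
        return m, float(results[col].std(ddof=1) / np.sqrt(reps))

    b3_mean, b3_mcse = stat("b3_lin")
    b1_mean, b1_mcse = stat("b1_free")
    c_mean, c_mcse = stat("c_hat")
    return {
        "n_cohorts": reps,
        "interaction_slope_mean": b3_mean,
        "interaction_slope_mc_se": b3_mcse,
        "environment_slope_mean": b1_mean,
        "environment_slope_mc_se": b1_mcse,
        "crossover_mean": c_mean,
        "crossover_mc_se": c_mcse,
        "crossover_ci_coverage": float(results["c_covered"].mean()),
        "truth": {"b1": truth.b1, "b2": truth.b2, "c": truth.c},
    }
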