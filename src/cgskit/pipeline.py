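"""End-to-end orchestration from a YAML config.

Stage order: load or simulate -> genotype QC -> CGS -> per-grade Z-scoring
and correlations -> interaction regressions -> crossover model competition
and regime call -> bootstrap mediation.  Every intermediate table is
persisted under the configured output directory and a machine-readable
``summary.json`` echoes each threshold and default in force, so no
behavior is silent.  Two runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cgs as cgs_mod
from . import crossover, gxe, mediation, qc, simulate
from .genotypes import read_genotypes, write_csv, write_plink_raw, write_vcf
from .panel import SnpPanel, default_panel

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    simulate_n: int | None = 1589          # None -> read real inputs
    genotypes_path: str | None = None
    genotypes_format: str = "csv"
    phenotypes_path: str | None = None
    panel_path: str | None = None
    sample_call_min: float = 0.90
    snp_call_min: float = 0.95
    hwe_p_min: float = 1e-5
    maf_min: float = 0.01
    pihat_max: float = 0.50
    phenotype_tag: str = "RF"
    missing_policy: str = "mean_dosage"
    include_interaction: bool = True
    env_range: str = "observed"            # or "theoretical" ([1, 8])
    ci_method: str = "wald"
    bootstrap_replicates: int = 5000
    mediation_enabled: bool = True
    mediator_columns: list[str] = field(default_factory=lambda: list(
        simulate.default_mediation_truth().mediator_names))

    def validate(self) -> list[str]:
        errors = []
        if not isinstance(self.seed, int):
            errors.append("seed: required integer (mandatory for any stochastic stage)")
        for name in ("sample_call_min", "snp_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}: must lie in [0, 1], got {v}")
        if not 0.0 <= self.maf_min <= 0.5:
            errors.append(f"maf_min: must lie in [0, 0.5], got {self.maf_min}")
        if not 0.0 < self.hwe_p_min < 1.0:
            errors.append(f"hwe_p_min: must lie in (0, 1), got {self.hwe_p_min}")
        if not 0.0 <= self.pihat_max <= 1.0:
            errors.append(f"pihat_max: must lie in [0, 1], got {self.pihat_max}")
        if self.phenotype_tag not in ("RF", "CR"):
            errors.append(f"phenotype_tag: must be RF or CR, got {self.phenotype_tag}")
        if self.missing_policy not in cgs_mod.MISSING_POLICIES:
            errors.append(f"missing_policy: must be one of {cgs_mod.MISSING_POLICIES}")
        if self.env_range not in ("observed", "theoretical"):
            errors.append("env_range: must be 'observed' or 'theoretical'")
        if self.ci_method not in ("wald", "profile"):
            errors.append("ci_method: must be 'wald' or 'profile'")
        if self.bootstrap_replicates < 100:
            errors.append("bootstrap_replicates: must be >= 100")
        if self.simulate_n is None and not (self.genotypes_path and self.phenotypes_path):
            errors.append("either simulate_n or genotypes_path + phenotypes_path is required")
        if not self.output_dir:
            errors.append("output_dir: required")
        return errors


_CONFIG_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_REQUIRED = ("seed", "output_dir")


def validate_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML config; every invalid field is listed."""
    raw = yaml.safe_load(Path(path).read_text())
    errors: list[str] = []
    if raw is None:
        raise ConfigError([f"{k}: required field missing" for k in _REQUIRED])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    unknown = set(raw) - _CONFIG_KEYS
    for k in sorted(unknown):
        errors.append(f"{k}: unknown field")
    for k in _REQUIRED:
        if k not in raw:
            errors.append(f"{k}: required field missing")
    if errors:
        raise ConfigError(errors)
    config = RunConfig(**{k: v for k, v in raw.items() if k in _CONFIG_KEYS})
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    return config


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and persists) the summary dict.

    A stage failure raises with the stage name after writing the partial
    summary collected so far.
    """
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "stages": {}}
    stage = "load"
    try:
        panel = (SnpPanel.from_csv(config.panel_path) if config.panel_path
                 else default_panel())
        if config.simulate_n is not None:
            g, table = simulate.simulate_study_cohort(
                config.simulate_n, seed=config.seed, panel=panel,
                phenotype_tag=config.phenotype_tag)
            write_vcf(g, panel, out / "genotypes.vcf")
            write_plink_raw(g, panel, out / "genotypes.raw")
            table.to_csv(out / "cohort.csv")
        else:
            g = read_genotypes(config.genotypes_path, config.genotypes_format, panel)
            table = pd.read_csv(config.phenotypes_path, index_col=0)
            table.index = table.index.astype(str)
        summary["stages"]["load"] = {
            "n_samples": g.n_samples, "n_snps": g.n_snps,
            "simulated": config.simulate_n is not None,
        }

        stage = "qc"
        g, report = qc.run_qc(
            g, config.sample_call_min, config.snp_call_min,
            config.hwe_p_min, config.maf_min, config.pihat_max)
        report.to_json(out / "qc_report.json")
        report.to_tsv(out / "qc_removals.tsv")
        table = table.loc[[s for s in g.sample_ids if s in table.index]]
        summary["stages"]["qc"] = {
            "n_samples_after": g.n_samples, "n_snps_after": g.n_snps,
            "removed_samples": report.removed("sample"),
            "removed_snps": report.removed("snp"),
            "thresholds": report.thresholds,
        }

        stage = "cgs"
        vec = cgs_mod.compute_cgs(g, panel.subset(g.snp_ids), config.phenotype_tag,
                                  config.missing_policy)
        score = pd.Series(vec.score, index=vec.sample_ids, name="cgs")
        table = table.loc[score.index]
        table["cgs"] = score
        table.to_csv(out / "cohort_with_cgs.csv")
        summary["stages"]["cgs"] = {
            "phenotype_tag": config.phenotype_tag,
            "missing_policy": config.missing_policy,
            "mean": float(score.mean()), "sd": float(score.std(ddof=1)),
            "min": float(score.min()), "max": float(score.max()),
        }

        stage = "correlations"
        med_cols = [c for c in config.mediator_columns if c in table.columns]
        corr_cols = ["cgs", "pe", "reading_fluency", *med_cols]
        corr = gxe.correlation_matrix(table[corr_cols])
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        summary["stages"]["correlations"] = {
            "variables": corr_cols, "fdr_family_size": len(corr),
            "n_fdr_significant": int(corr["p_adj"].lt(0.05).sum()),
        }

        stage = "gxe"
        y = table["reading_fluency"].to_numpy()
        pe = table["pe"].to_numpy()
        score_arr = table["cgs"].to_numpy()
        age = table["age"].to_numpy()
        sex = table["sex"].to_numpy()
        fit1 = gxe.fit_gxe(y, pe, score_arr, age, sex, include_interaction=False)
        gxe_summary = {"model_1": _fit_dict(fit1)}
        if config.include_interaction:
            fit2 = gxe.fit_gxe(y, pe, score_arr, age, sex, include_interaction=True)
            f, dfs, p = gxe.delta_r2_test(fit1, fit2)
            levels = {"low": float(score_arr.mean() - score_arr.std(ddof=1)),
                      "high": float(score_arr.mean() + score_arr.std(ddof=1))}
            slopes = gxe.simple_slopes(fit2, levels)
            slopes.to_csv(out / "simple_slopes.tsv", sep="\t")
            pd.concat([fit1.summary_frame().add_suffix("_m1"),
                       fit2.summary_frame().add_suffix("_m2")], axis=1) \
                .to_csv(out / "gxe_models.tsv", sep="\t")
            gxe_summary.update({
                "model_2": _fit_dict(fit2),
                "delta_r2_f": float(f), "delta_r2_df": list(dfs), "delta_r2_p": float(p),
                "simple_slopes": slopes.to_dict(orient="index"),
            })
        summary["stages"]["gxe"] = gxe_summary
        if not config.include_interaction:
            logger.info("interaction disabled: stopping after the main-effects model")
            return _finalize(summary, out)

        stage = "crossover"
        free = crossover.fit_free_crossover(y, pe, score_arr, age, sex,
                                            ci_method=config.ci_method)
        env_min, env_max = ((1.0, 8.0) if config.env_range == "theoretical"
                            else (float(pe.min()), float(pe.max())))
        fixed = crossover.fit_fixed_crossover(y, pe, score_arr, age, sex, c_fixed=env_max)
        comparison = crossover.compare_models(free, fixed)
        call = crossover.classify_regime(free, env_min, env_max)
        _crossover_table(free, fixed, comparison).to_csv(out / "crossover_models.tsv", sep="\t")
        summary["stages"]["crossover"] = {
            "free": _crossover_dict(free), "fixed": _crossover_dict(fixed),
            "comparison": asdict(comparison), "env_range": [env_min, env_max],
            "env_range_convention": config.env_range,
            "ci_method": config.ci_method,
            "regime": call.regime, "rationale": call.rationale,
        }

        if config.mediation_enabled and med_cols:
            stage = "mediation"
            y_z = gxe.zscore_by_grade(y, table["grade"].to_numpy())
            med_z = pd.DataFrame({
                c: gxe.zscore_by_grade(table[c].to_numpy(), table["grade"].to_numpy())
                for c in med_cols})
            gene_z = gxe.zscore_by_grade(score_arr, table["grade"].to_numpy())
            boot = mediation.bootstrap_indirect(
                gene_z, med_z, y_z, age, sex,
                replicates=config.bootstrap_replicates, seed=config.seed)
            boot.to_csv(out / "mediation_indirect.tsv", sep="\t", index=False)
            indices = mediation.fit_indices(gene_z, med_z, y_z, age, sex)
            summary["stages"]["mediation"] = {
                "mediators": med_cols,
                "bootstrap_replicates": config.bootstrap_replicates,
                "standardization": "per_grade_z",
                "indirect": boot.to_dict(orient="records"),
                "fit_indices": asdict(indices),
                "cutoffs": indices.passes_conventional_cutoffs(),
            }
    except Exception:
        summary["failed_stage"] = stage
        _finalize(summary, out, name="summary_partial.json")
        logger.exception("pipeline failed at stage %r", stage)
        raise
    return _finalize(summary, out)


def _fit_dict(fit: gxe.GxEFit) -> dict:
    return {
        "coefficients": dict(zip(fit.terms, fit.params)),
        "se": dict(zip(fit.terms, fit.bse)),
        "p": dict(zip(fit.terms, fit.pvalues)),
        "r_squared": fit.r_squared, "f": fit.f_statistic,
        "df": [fit.df_model, fit.df_resid], "n": fit.n,
    }


def _crossover_dict(fit: crossover.CrossoverFit) -> dict:
    return {
        "coefficients": dict(zip(fit.terms, fit.params)),
        "se": dict(zip(fit.terms, fit.bse)),
        "c_fixed": fit.c_fixed, "c_ci": fit.c_ci,
        "r_squared": fit.r_squared, "aic": fit.aic, "bic": fit.bic,
        "loglik": fit.loglik, "n": fit.n,
    }


def _crossover_table(free, fixed, comparison) -> pd.DataFrame:
    rows = {}
    for term in free.terms:
        rows[term] = {
            "free": f"{free.coef(term):.2f} ({free.se(term):.2f})",
            "fixed": (f"{fixed.coef(term):.2f} (-)" if term == "C"
                      else f"{fixed.coef(term):.2f} ({fixed.se(term):.2f})"),
        }
    rows["R2"] = {"free": f"{free.r_squared:.4f}", "fixed": f"{fixed.r_squared:.4f}"}
    rows["AIC"] = {"free": f"{free.aic:.2f}", "fixed": f"{fixed.aic:.2f}"}
    rows["BIC"] = {"free": f"{free.bic:.2f}", "fixed": f"{fixed.bic:.2f}"}
    rows["F_vs_free"] = {"free": "-",
                         "fixed": f"{comparison.f_statistic:.3f} (p={comparison.p_value:.4f})"}
    return pd.DataFrame.from_dict(rows, orient="index")


def _finalize(summary: dict, out: Path, name: str = "summary.json") -> dict:
    payload = _round_floats(summary)
    (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
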