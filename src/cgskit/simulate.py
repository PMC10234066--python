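"""Synthetic cohort generation.

Emulates the statistical structure the downstream analysis assumes: a small
biallelic SNP panel in Hardy-Weinberg equilibrium, a parent-averaged
education (PE) variable on a half-step ordinal lattice, school-grade /
age / sex covariates, a timed reading-fluency outcome generated under a
crossover gene-by-environment model, and a parallel-mediation structure
(genetic score -> correlated naming-speed mediators -> outcome).

Every generator takes an explicit integer seed and records it in the
returned object's provenance so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel, default_panel
from .genotypes import GenotypeMatrix

#: study-condition defaults: PE is the mean of two parents' 1-8 ordinal
#: levels, observed in the emulated cohort on the half-step lattice 1..6.
PE_MIN, PE_MAX, PE_STEP = 1.0, 6.0, 0.5
GRADES = (3, 4, 5, 6)

REGIMES = ("differential_susceptibility", "diathesis_stress", "vantage_sensitivity", "none")


@dataclass
class GxETruth:
    """True parameters of the crossover-form G×E generating model.

    The outcome is ``Y = b0 + b1*(PE - c) + b2*((PE - c) * CGS)
    + b_age*age + b_sex*sex + N(0, resid_sd)``: ``c`` is the PE value at
    which regression lines for different score levels intersect.
    """

    b0: float
    b1: float
    b2: float
    c: float
    b_age: float = 0.0
    b_sex: float = 0.0
    resid_sd: float = 1.0
    regime: str = "differential_susceptibility"

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.regime == "none" and self.b2 != 0.0:
            raise ValueError("regime 'none' requires b2 = 0")

    def validate_against_range(self, env_min: float, env_max: float) -> None:
        if self.regime == "diathesis_stress" and self.c != env_max:
            raise ValueError("diathesis_stress truth requires c at the environment maximum")
        if self.regime == "vantage_sensitivity" and self.c != env_min:
            raise ValueError("vantage_sensitivity truth requires c at the environment minimum")


@dataclass
class MediationTruth:
    """True parameters of the parallel-mediation generating model.

    Mediators are generated from the *standardized* genetic score x:
    ``M_j = a_j * x + e_j`` with ``e`` multivariate normal under
    ``mediator_resid_corr`` and per-mediator residual SDs (default
    ``sqrt(1 - a_j^2)`` so each mediator has unit variance);
    ``Y = c_prime * x + sum_j b_j * M_j + N(0, resid_sd_y)``.
    """

    mediator_names: tuple[str, ...]
    a_paths: tuple[float, ...]
    b_paths: tuple[float, ...]
    c_prime: float = 0.0
    mediator_resid_corr: np.ndarray | None = None
    mediator_resid_sd: tuple[float, ...] | None = None
    resid_sd_y: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.mediator_names)
        if k < 1:
            raise ValueError("need at least one mediator")
        if len(self.a_paths) != k or len(self.b_paths) != k:
            raise ValueError("a_paths/b_paths length must match mediator_names")
        if self.mediator_resid_corr is None:
            self.mediator_resid_corr = np.eye(k)
        self.mediator_resid_corr = np.asarray(self.mediator_resid_corr, dtype=float)
        R = self.mediator_resid_corr
        if R.shape != (k, k) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("mediator_resid_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ValueError("mediator_resid_corr must be positive definite")
        if self.mediator_resid_sd is None:
            self.mediator_resid_sd = tuple(
                float(np.sqrt(max(1.0 - a * a, 1e-12))) for a in self.a_paths
            )
        if self.resid_sd_y < 0:
            raise ValueError("resid_sd_y must be >= 0")

    @property
    def indirect_effects(self) -> np.ndarray:
        return np.array(self.a_paths) * np.array(self.b_paths)


# ---------------------------------------------------------------------------
# genotypes and environment

def simulate_genotypes(
    n: int,
    panel: SnpPanel,
    seed: int,
    first_allele_is_minor: bool = False,
) -> GenotypeMatrix:
    """Draw n samples of first-allele copy counts, each SNP independently in HWE.

    The first allele segregates at frequency ``1 - maf`` (or ``maf`` when
    ``first_allele_is_minor``), so copy counts are Binomial(2, freq) —
    exactly the p^2 / 2pq / q^2 Hardy-Weinberg proportions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = panel.mafs
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("all panel MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    freq = mafs if first_allele_is_minor else 1.0 - mafs
    codes = rng.binomial(2, freq, size=(n, len(panel))).astype(float)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, panel.snp_ids, codes)


def pe_lattice(min: float = PE_MIN, max: float = PE_MAX, grid_step: float = PE_STEP) -> np.ndarray:
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if min > max:
        raise ValueError("min must be <= max")
    n_pts = int(round((max - min) / grid_step)) + 1
    lattice = min + grid_step * np.arange(n_pts)
    if lattice.size == 0:
        raise ValueError("empty environment lattice")
    return lattice


def simulate_environment(
    n: int,
    grid_step: float = PE_STEP,
    min: float = PE_MIN,
    max: float = PE_MAX,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Draw parent-averaged education levels from the half-step lattice.

    Defaults to uniform weights over the lattice; pass ``weights`` to skew
    the distribution.
    """
    lattice = pe_lattice(min, max, grid_step)
    rng = np.random.default_rng(seed)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != lattice.shape:
            raise ValueError("weights must match the lattice length")
        weights = weights / weights.sum()
    return rng.choice(lattice, size=n, p=weights)


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Grade (uniform 3-6), age in years (grade entry age + uniform jitter), sex 0/1."""
    rng = np.random.default_rng(seed)
    grade = rng.integers(GRADES[0], GRADES[-1] + 1, size=n)
    age = grade + 6.5 + rng.uniform(-0.5, 0.5, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    return pd.DataFrame({"grade": grade, "age": age, "sex": sex})


# ---------------------------------------------------------------------------
# G×E outcome

def simulate_gxe_phenotype(
    cgs: np.ndarray,
    pe: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    truth: GxETruth,
    seed: int,
) -> np.ndarray:
    """Generate the outcome under the crossover-form model (see GxETruth)."""
    cgs, pe, age, sex = map(np.asarray, (cgs, pe, age, sex))
    if not (len(cgs) == len(pe) == len(age) == len(sex)):
        raise ValueError("cgs, pe, age, sex must have equal length")
    rng = np.random.default_rng(seed)
    u = pe - truth.c
    y = (
        truth.b0
        + truth.b1 * u
        + truth.b2 * u * cgs
        + truth.b_age * age
        + truth.b_sex * sex
    )
    if truth.resid_sd > 0:
        y = y + rng.normal(0.0, truth.resid_sd, size=len(y))
    return y


def risk_allele_freqs(panel: SnpPanel, phenotype_tag: str = "RF",
                      first_allele_is_minor: bool = False) -> np.ndarray:
    """Population frequency of the score-increasing allele per SNP."""
    p_first = panel.mafs if first_allele_is_minor else 1.0 - panel.mafs
    betas = panel.betas(phenotype_tag)
    return np.where(betas > 0, p_first, 1.0 - p_first)


def calibrate_resid_sd(
    truth: GxETruth,
    target_r2: float,
    panel: SnpPanel | None = None,
    phenotype_tag: str = "RF",
    pe_weights: np.ndarray | None = None,
    lattice: np.ndarray | None = None,
) -> float:
    """Residual SD giving the requested population R² under the generator.

    Uses closed-form moments of the independent PE lattice, binomial CGS,
    grade-derived age and Bernoulli sex:  with U = PE - c and G the score,
    Var(eta) = b1²VarU + b2²Var(UG) + 2 b1 b2 E[G]VarU + b_age²VarAge
    + b_sex²/4, and resid_sd = sqrt(Var(eta) (1-R²)/R²).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    panel = panel or default_panel()
    lattice = lattice if lattice is not None else pe_lattice()
    w = (np.full(lattice.shape, 1.0 / len(lattice)) if pe_weights is None
         else np.asarray(pe_weights, dtype=float) / np.sum(pe_weights))
    u = lattice - truth.c
    eu, eu2 = float(w @ u), float(w @ u**2)
    var_u = eu2 - eu**2
    r = risk_allele_freqs(panel, phenotype_tag)
    eg = float(np.sum(2 * r))
    var_g = float(np.sum(2 * r * (1 - r)))
    eg2 = var_g + eg**2
    var_ug = eu2 * eg2 - eu**2 * eg**2
    cov_u_ug = eg * var_u
    var_age = float(np.var(GRADES)) + 1.0 / 12.0
    var_eta = (
        truth.b1**2 * var_u
        + truth.b2**2 * var_ug
        + 2 * truth.b1 * truth.b2 * cov_u_ug
        + truth.b_age**2 * var_age
        + truth.b_sex**2 * 0.25
    )
    return float(np.sqrt(var_eta * (1.0 - target_r2) / target_r2))


def default_gxe_truth(regime: str = "differential_susceptibility") -> GxETruth:
    """Package-default generating parameters for the G×E stage.

    Effect sizes are representative of cumulative-score × parental-education
    moderation of a timed reading-fluency measure in a large primary-school
    cohort: intercept ≈ 247 s at the crossover, PE slope −10.4 s per level,
    interaction slope 0.52 s per (PE × score) unit, crossover at PE = 2.27,
    and residual SD calibrated so the full model explains R² ≈ 0.0875.
    For the diathesis-stress variant the crossover sits at the PE maximum.
    """
    c = PE_MAX if regime == "diathesis_stress" else 2.27
    truth = GxETruth(
        b0=246.63, b1=-10.40, b2=0.52, c=c,
        b_age=-0.83, b_sex=-2.13, resid_sd=1.0, regime=regime,
    )
    truth.resid_sd = calibrate_resid_sd(truth, target_r2=0.0875)
    return truth


def simulate_gxe_cohort(
    n: int,
    seed: int,
    panel: SnpPanel | None = None,
    truth: GxETruth | None = None,
    phenotype_tag: str = "RF",
    pe_weights: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Full G×E cohort: genotypes plus a phenotype/covariate table.

    Returns the genotype matrix and a table with columns
    ``pe, grade, age, sex, cgs, reading_fluency``; generation metadata
    (seed, truth parameters) is stored in ``table.attrs``.
    """
    from .cgs import compute_cgs  # local import to avoid a cycle at load time

    panel = panel or default_panel()
    truth = truth or default_gxe_truth()
    if truth.regime in ("diathesis_stress", "vantage_sensitivity"):
        truth.validate_against_range(PE_MIN, PE_MAX)
    seeds = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    g = simulate_genotypes(n, panel, seed=sub[0])
    pe = simulate_environment(n, seed=sub[1], weights=pe_weights)
    cov = simulate_covariates(n, seed=sub[2])
    cgs = compute_cgs(g, panel, phenotype_tag).score
    y = simulate_gxe_phenotype(cgs, pe, cov["age"].to_numpy(), cov["sex"].to_numpy(),
                               truth, seed=sub[3])
    table = pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "pe": pe,
            "grade": cov["grade"].to_numpy(),
            "age": cov["age"].to_numpy(),
            "sex": cov["sex"].to_numpy(),
            "cgs": cgs,
            "reading_fluency": y,
        }
    ).set_index("sample_id")
    table.attrs["seed"] = seed
    table.attrs["truth"] = asdict(truth)
    return g, table


# ---------------------------------------------------------------------------
# mediation cohort

def default_mediation_truth() -> MediationTruth:
    """Four naming-speed (RAN) mediators with exchangeable residual correlation 0.5.

    Path sizes mirror a weak gene -> endophenotype -> reading chain: small
    standardized a-paths (0.01-0.05), one dominant mediator-outcome b-path,
    and a near-zero direct effect.
    """
    k = 4
    corr = np.full((k, k), 0.5) + 0.5 * np.eye(k)
    return MediationTruth(
        mediator_names=("ran_digit", "ran_dice", "ran_picture", "ran_color"),
        a_paths=(0.05, 0.01, 0.03, 0.03),
        b_paths=(0.42, 0.05, 0.12, 0.10),
        c_prime=0.02,
        mediator_resid_corr=corr,
        resid_sd_y=0.85,
    )


def simulate_mediation_cohort(
    n: int,
    panel: SnpPanel | None = None,
    truth: MediationTruth | None = None,
    seed: int = 0,
    phenotype_tag: str = "RF",
    grade_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cohort with a genetic score, correlated mediators and an outcome.

    The score is computed from simulated HWE genotypes and standardized
    before entering the mediator and outcome equations, so the truth paths
    are on (approximately) standardized scales.  Grade is drawn from
    ``grade_weights`` (uniform by default) so per-grade standardization is
    exercised downstream.
    """
    from .cgs import compute_cgs

    panel = panel or default_panel()
    truth = truth or default_mediation_truth()
    seeds = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    rng = np.random.default_rng(sub[1])

    g = simulate_genotypes(n, panel, seed=sub[0])
    cgs = compute_cgs(g, panel, phenotype_tag).score
    x = (cgs - cgs.mean()) / cgs.std(ddof=0)

    k = len(truth.mediator_names)
    a = np.array(truth.a_paths)
    b = np.array(truth.b_paths)
    sds = np.array(truth.mediator_resid_sd)
    cov = truth.mediator_resid_corr * np.outer(sds, sds)
    resid = rng.multivariate_normal(np.zeros(k), cov, size=n)
    mediators = x[:, None] * a[None, :] + resid
    y = truth.c_prime * x + mediators @ b
    if truth.resid_sd_y > 0:
        y = y + rng.normal(0.0, truth.resid_sd_y, size=n)

    cov_rng = np.random.default_rng(sub[2])
    if grade_weights is None:
        grade = cov_rng.choice(GRADES, size=n)
    else:
        w = np.asarray(grade_weights, dtype=float)
        grade = cov_rng.choice(GRADES, size=n, p=w / w.sum())
    age = grade + 6.5 + cov_rng.uniform(-0.5, 0.5, size=n)
    sex = cov_rng.integers(0, 2, size=n).astype(float)
    pe = simulate_environment(n, seed=sub[3])

    table = pd.DataFrame({"cgs": cgs, "cgs_std": x}, index=g.sample_ids)
    for j, name in enumerate(truth.mediator_names):
        table[name] = mediators[:, j]
    table["reading_fluency"] = y
    table["grade"] = grade
    table["age"] = age
    table["sex"] = sex
    table["pe"] = pe
    table.index.name = "sample_id"
    table.attrs["seed"] = seed
    table.attrs["truth_indirect"] = truth.indirect_effects.tolist()
    return table


def simulate_study_cohort(
    n: int,
    seed: int,
    panel: SnpPanel | None = None,
    gxe_truth: GxETruth | None = None,
    mediation_truth: MediationTruth | None = None,
    phenotype_tag: str = "RF",
    pe_weights: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """One cohort carrying both the G×E and the mediation structure.

    The outcome keeps the crossover-model mean structure and total residual
    variance of ``gxe_truth``, but a share of that residual flows through
    the mediators: ``Y = mean_structure + resid_sd * (sum_j b_j e_j + e')``
    where ``e_j`` are the mediator residuals (unit-scale) and ``e'`` is
    shrunk so the total residual SD is unchanged.  Mediators are
    ``M_j = a_j * z(CGS) + e_j`` as in :func:`simulate_mediation_cohort`.
    Requires ``b' Cov(e) b < 1``.
    """
    from .cgs import compute_cgs

    panel = panel or default_panel()
    gxe_truth = gxe_truth or default_gxe_truth()
    med = mediation_truth or default_mediation_truth()
    seeds = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    g = simulate_genotypes(n, panel, seed=sub[0])
    pe = simulate_environment(n, seed=sub[1], weights=pe_weights)
    cov = simulate_covariates(n, seed=sub[2])
    cgs = compute_cgs(g, panel, phenotype_tag).score
    x = (cgs - cgs.mean()) / cgs.std(ddof=0)

    rng = np.random.default_rng(sub[3])
    k = len(med.mediator_names)
    a = np.array(med.a_paths)
    b = np.array(med.b_paths)
    sds = np.array(med.mediator_resid_sd)
    cov_e = med.mediator_resid_corr * np.outer(sds, sds)
    e = rng.multivariate_normal(np.zeros(k), cov_e, size=n)
    mediators = x[:, None] * a[None, :] + e

    through = float(b @ cov_e @ b)
    if through >= 1.0:
        raise ValueError("mediated residual share b' Cov(e) b must be < 1")
    u = pe - gxe_truth.c
    mean_part = (
        gxe_truth.b0 + gxe_truth.b1 * u + gxe_truth.b2 * u * cgs
        + gxe_truth.b_age * cov["age"].to_numpy() + gxe_truth.b_sex * cov["sex"].to_numpy()
    )
    eps = np.random.default_rng(sub[4]).normal(0.0, np.sqrt(1.0 - through), size=n)
    y = mean_part + gxe_truth.resid_sd * (e @ b + eps)

    table = pd.DataFrame(
        {"pe": pe, "grade": cov["grade"].to_numpy(), "age": cov["age"].to_numpy(),
         "sex": cov["sex"].to_numpy(), "cgs": cgs, "reading_fluency": y},
        index=g.sample_ids,
    )
    for j, name in enumerate(med.mediator_names):
        table[name] = mediators[:, j]
    table.index.name = "sample_id"
    table.attrs["seed"] = seed
    return g, table


def write_truth_sidecar(truth: GxETruth | MediationTruth, seed: int, path: str | Path) -> None:
    """Echo generating parameters and the seed to a JSON sidecar file."""
    payload = {"seed": seed, "truth": asdict(truth)}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
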