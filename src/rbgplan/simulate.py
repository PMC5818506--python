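"""Seeded Monte-Carlo engine: synthetic cohorts and empirical power.

Three jobs live here:

1. generate synthetic genotype/GRS/exposure/outcome/confounder cohorts under
   the same structural assumptions the analytic calculators make;
2. estimate empirical power of recall and random designs by replication, as
   the independent check on the analytic formulas;
3. contrast confounder balance between phenotype-extreme and genotype-extreme
   strata — the randomization property that motivates genotype-based recall:
   because genotypes are allocated at random at conception, strata cut on a
   GRS are balanced on confounders, while strata cut on the phenotype itself
   are not.

Replicate-level hypothesis tests mirror the analytic kernels — z statistics
against normal critical values, with the residual SD the structural model
fixes (unit phenotype noise; ``sqrt(1 - r2)`` outcome noise) treated as
known — so that any analytic-vs-empirical discrepancy isolates a formula
error rather than a small-sample test mismatch. The one place the variance
is genuinely unknown a priori, the within-tail outcome spread of a GRS-tail
arm, uses the pooled sample estimate, keeping the tail-variance propagation
formula under real test. Each replicate draws from its own stream seeded
from ``(master seed, replicate index)``; growing the replicate count
therefore never reshuffles earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import (
    Comparison,
    Method,
    MultiVariantDesign,
    PowerResult,
    SingleVariantDesign,
)
from .errors import InfeasibleDesignError, ParameterError
from .mv import grs_exposure_gradient  # noqa: F401  (re-exported convenience)

__all__ = [
    "CohortModel",
    "StrataBalanceReport",
    "simulate_sv_cohort",
    "simulate_grs_cohort",
    "empirical_power",
    "strata_balance_report",
]


@dataclass(frozen=True)
class CohortModel:
    """Generative specification for a synthetic GRS cohort.

    ``variants`` is a sequence of ``(maf, weight)`` pairs; the raw GRS is
    the weighted dosage sum, with population variance
    ``sum(2*maf*(1-maf)*weight^2)``, then standardized by its population
    moments. ``confounder_effects`` is a sequence of ``(on_exposure,
    on_outcome)`` standardized effect pairs for independent standard-normal
    confounders; independence from the GRS holds by construction.
    """

    n_individuals: int
    variants: Sequence[tuple[float, float]]
    r2_xg: float
    r2_yx: float
    confounder_effects: Sequence[tuple[float, float]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ParameterError("n_individuals", "must be at least 1")
        if len(self.variants) < 1:
            raise ParameterError("variants", "at least one variant is required")
        for maf, _w in self.variants:
            if not 0.0 < maf <= 0.5:
                raise ParameterError("variants", f"maf {maf} must be in (0, 0.5]")
        if not 0.0 <= self.r2_xg <= 1.0:
            raise ParameterError("r2_xg", "must be in [0, 1]")
        if not 0.0 <= self.r2_yx <= 1.0:
            raise ParameterError("r2_yx", "must be in [0, 1]")
        a = np.array([e[0] for e in self.confounder_effects], dtype=float)
        b = np.array([e[1] for e in self.confounder_effects], dtype=float)
        if self.r2_xg + float(a @ a) > 1.0:
            raise ParameterError(
                "confounder_effects", "exposure variance budget exceeds 1"
            )
        y_explained = (
            self.r2_yx + float(b @ b) + 2.0 * math.sqrt(self.r2_yx) * float(a @ b)
        )
        if y_explained > 1.0:
            raise ParameterError(
                "confounder_effects", "outcome variance budget exceeds 1"
            )


@dataclass(frozen=True)
class StrataBalanceReport:
    """Standardized mean differences between top and bottom strata.

    ``table`` has one row per variable (exposure, outcome, each confounder)
    and columns ``smd_exposure_strata``/``se_exposure_strata`` (strata cut
    on the exposure) and ``smd_grs_strata``/``se_grs_strata`` (strata cut
    on the GRS). Both stratifications use the same ``cut_fraction``.
    """

    table: pd.DataFrame
    cut_fraction: float


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def _two_sample_z(y1: np.ndarray, y0: np.ndarray, sd: float | None = None) -> float:
    """Two-sample z statistic; pooled-variance estimate when ``sd`` is unknown."""
    n1, n0 = y1.size, y0.size
    if sd is None:
        pooled = ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)) / (
            n1 + n0 - 2
        )
    else:
        pooled = sd * sd
    return float((y1.mean() - y0.mean()) / math.sqrt(pooled * (1.0 / n1 + 1.0 / n0)))


def _slope_z(x: np.ndarray, y: np.ndarray, resid_sd: float) -> float:
    """Simple-regression slope z with known residual SD; 0 for a constant regressor."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return 0.0
    b = float(xc @ y) / sxx
    return b * math.sqrt(sxx) / resid_sd


def simulate_sv_cohort(n: int, maf: float, beta: float, seed: int = 0) -> pd.DataFrame:
    """Synthetic single-variant cohort: HWE dosages and a linear phenotype.

    Dosages are Binomial(2, maf) counts of the minor allele (the HWE
    trinomial); phenotype is ``beta*dosage`` plus standard-normal noise.
    """
    if n < 1:
        raise ParameterError("n", "must be at least 1")
    if not 0.0 < maf <= 0.5:
        raise ParameterError("maf", "must be in (0, 0.5]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    dosage = rng.binomial(2, maf, size=n)
    phenotype = beta * dosage + rng.standard_normal(n)
    return pd.DataFrame(
        {"id": np.arange(n), "dosage": dosage, "phenotype": phenotype}
    )


def simulate_grs_cohort(model: CohortModel) -> pd.DataFrame:
    """Synthetic multi-variant cohort with GRS, exposure, outcome, confounders.

    The raw GRS is the weighted dosage sum over ``model.variants``, then
    standardized by its population mean and SD. Exposure and outcome follow
    the standardized structural chain ``X = sqrt(r2_xg)*G + sum(a_j*C_j) +
    e_x`` and ``Y = sqrt(r2_yx)*X + sum(b_j*C_j) + e_y`` with residual
    variances chosen so X and Y have unit variance. Confounders are
    independent standard normals, independent of the GRS by construction.

    Columns, in fixed order: ``id``, ``dosage_1..k``, ``grs``, ``exposure``,
    ``outcome``, ``conf_1..m``.
    """
    n = model.n_individuals
    rng = np.random.default_rng(np.random.SeedSequence([int(model.seed)]))
    mafs = np.array([v[0] for v in model.variants], dtype=float)
    weights = np.array([v[1] for v in model.variants], dtype=float)
    dosages = rng.binomial(2, mafs, size=(n, mafs.size))
    raw = dosages @ weights
    mean = float(2.0 * mafs @ weights)
    var = float((2.0 * mafs * (1.0 - mafs)) @ (weights**2))
    grs = (raw - mean) / math.sqrt(var)

    a = np.array([e[0] for e in model.confounder_effects], dtype=float)
    b = np.array([e[1] for e in model.confounder_effects], dtype=float)
    conf = rng.standard_normal((n, a.size)) if a.size else np.empty((n, 0))

    var_ex = 1.0 - model.r2_xg - float(a @ a)
    exposure = (
        math.sqrt(model.r2_xg) * grs
        + (conf @ a if a.size else 0.0)
        + math.sqrt(var_ex) * rng.standard_normal(n)
    )
    y_explained = (
        model.r2_yx + float(b @ b) + 2.0 * math.sqrt(model.r2_yx) * float(a @ b)
    )
    var_ey = 1.0 - y_explained
    outcome = (
        math.sqrt(model.r2_yx) * exposure
        + (conf @ b if b.size else 0.0)
        + math.sqrt(var_ey) * rng.standard_normal(n)
    )

    out = {"id": np.arange(n)}
    for j in range(mafs.size):
        out[f"dosage_{j + 1}"] = dosages[:, j]
    out["grs"] = grs
    out["exposure"] = exposure
    out["outcome"] = outcome
    for j in range(a.size):
        out[f"conf_{j + 1}"] = conf[:, j]
    return pd.DataFrame(out)


def _sv_replicate(
    design: SingleVariantDesign, n_random: int, rng: np.random.Generator, zcrit: float
) -> tuple[bool, bool]:
    dosage_minor = 2 if design.comparison is Comparison.HOM_VS_HOM else 1
    n1 = round(design.allocation * design.n_total)
    n2 = design.n_total - n1
    # recall arms: selection is on genotype, so the arms can be simulated
    # directly from the conditional phenotype model
    y_minor = design.beta * dosage_minor + rng.standard_normal(n1)
    y_major = rng.standard_normal(n2)
    reject_recall = abs(_two_sample_z(y_minor, y_major, sd=1.0)) > zcrit

    dosage = rng.binomial(2, design.maf, size=n_random)
    pheno = design.beta * dosage + rng.standard_normal(n_random)
    reject_random = abs(_slope_z(dosage.astype(float), pheno, resid_sd=1.0)) > zcrit
    return reject_recall, reject_random


def _mv_replicate(
    design: MultiVariantDesign,
    n_random: int,
    bioresource: int,
    rng: np.random.Generator,
    zcrit: float,
) -> tuple[bool, bool]:
    half = design.n_total // 2
    g = rng.standard_normal(bioresource)
    x = math.sqrt(design.r2_xg) * g + math.sqrt(1.0 - design.r2_xg) * rng.standard_normal(
        bioresource
    )
    y = math.sqrt(design.r2_yx) * x + math.sqrt(1.0 - design.r2_yx) * rng.standard_normal(
        bioresource
    )
    order = np.argsort(g)
    # within-tail outcome variance is what the analytic formula predicts,
    # so estimate it from the arms rather than assuming it
    reject_recall = abs(_two_sample_z(y[order[-half:]], y[order[:half]])) > zcrit

    g_r = rng.standard_normal(n_random)
    x_r = math.sqrt(design.r2_xg) * g_r + math.sqrt(
        1.0 - design.r2_xg
    ) * rng.standard_normal(n_random)
    y_r = math.sqrt(design.r2_yx) * x_r + math.sqrt(
        1.0 - design.r2_yx
    ) * rng.standard_normal(n_random)
    resid_sd = math.sqrt(1.0 - design.r2_xg * design.r2_yx)
    reject_random = abs(_slope_z(g_r, y_r, resid_sd)) > zcrit
    return reject_recall, reject_random


def empirical_power(
    design: SingleVariantDesign | MultiVariantDesign,
    n_reps: int = 10_000,
    seed: int = 0,
    n_random: int | None = None,
    cohort_size: int | None = None,
) -> PowerResult:
    """Empirical power of the recall and matched random designs.

    Runs ``n_reps`` independent replicates; within each, the recall design
    is simulated and tested (genotype arms for single-variant designs; a
    genotyped bioresource with GRS-tail selection for multi-variant
    designs), and a fresh random sample of ``n_random`` (default
    ``n_total``) is tested with the slope kernel. Returns the rejection
    fractions with ``mc_se`` the larger of the two binomial standard errors.

    For multi-variant designs ``cohort_size`` sets the simulated
    bioresource per replicate; the default is the smallest bioresource
    whose tails can fill both arms. A bioresource whose tail holds fewer
    people than an arm needs raises :class:`InfeasibleDesignError`.
    """
    if n_reps < 100:
        raise ParameterError("n_reps", "must be at least 100")
    if n_random is None:
        n_random = design.n_total
    zcrit = float(norm.ppf(1.0 - design.alpha / 2.0))

    if isinstance(design, MultiVariantDesign):
        half = design.n_total // 2
        if design.n_total % 2:
            raise ParameterError("n_total", "must be even for tail recall")
        if cohort_size is None:
            cohort_size = math.ceil(half / design.percentile)
        if design.percentile * cohort_size < half:
            raise InfeasibleDesignError(
                f"tail holds {design.percentile * cohort_size:.1f} people "
                f"but each arm needs {half}"
            )

    rej_recall = 0
    rej_random = 0
    for rep in range(n_reps):
        rng = _rep_rng(seed, rep)
        if isinstance(design, SingleVariantDesign):
            rec, ran = _sv_replicate(design, n_random, rng, zcrit)
        else:
            rec, ran = _mv_replicate(design, n_random, cohort_size, rng, zcrit)
        rej_recall += rec
        rej_random += ran

    p_rec = rej_recall / n_reps
    p_ran = rej_random / n_reps
    mc_se = max(
        math.sqrt(p_rec * (1.0 - p_rec) / n_reps),
        math.sqrt(p_ran * (1.0 - p_ran) / n_reps),
    )
    return PowerResult.from_powers(p_rec, p_ran, method=Method.SIMULATION, mc_se=mc_se)


def _smd(top: np.ndarray, bottom: np.ndarray) -> tuple[float, float]:
    """Standardized mean difference (top - bottom) and its standard error."""
    n1, n2 = top.size, bottom.size
    pooled = ((n1 - 1) * top.var(ddof=1) + (n2 - 1) * bottom.var(ddof=1)) / (
        n1 + n2 - 2
    )
    d = float((top.mean() - bottom.mean()) / math.sqrt(pooled))
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    return d, se


def strata_balance_report(
    model: CohortModel, cut_fraction: float = 0.30
) -> StrataBalanceReport:
    """Confounder balance in phenotype-extreme versus genotype-extreme strata.

    Simulates one cohort from ``model`` and, for each of exposure, outcome
    and every confounder, reports the standardized mean difference between
    the top and bottom ``cut_fraction`` strata — once cutting on the
    exposure and once on the GRS. GRS strata stay balanced on confounders
    for any confounding strength (genotypes are randomly allocated);
    exposure strata do not.
    """
    if not 0.0 < cut_fraction <= 0.5:
        raise ParameterError("cut_fraction", "must be in (0, 0.5]")
    cohort = simulate_grs_cohort(model)
    k = int(cut_fraction * model.n_individuals)
    if k < 100:
        raise ParameterError(
            "cut_fraction", f"each stratum needs at least 100 members, got {k}"
        )
    variables = ["exposure", "outcome"] + [
        c for c in cohort.columns if c.startswith("conf_")
    ]
    rows = {}
    for cut_var, label in (("exposure", "exposure_strata"), ("grs", "grs_strata")):
        order = np.argsort(cohort[cut_var].to_numpy())
        bottom_idx, top_idx = order[:k], order[-k:]
        for var in variables:
            vals = cohort[var].to_numpy()
            d, se = _smd(vals[top_idx], vals[bottom_idx])
            rows.setdefault(var, {})[f"smd_{label}"] = d
            rows.setdefault(var, {})[f"se_{label}"] = se
    table = pd.DataFrame.from_dict(rows, orient="index").loc[variables]
    table.index.name = "variable"
    return StrataBalanceReport(table=table, cut_fraction=cut_fraction)
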