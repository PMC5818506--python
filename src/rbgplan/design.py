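"""Shared design types, Hardy–Weinberg algebra, and power kernels.

Two recall-by-genotype (RbG) designs are planned with this package:

* ``RbG^sv`` — recall arms are genotype groups at a single variant
  (:class:`SingleVariantDesign`);
* ``RbG^mv`` — recall arms are the upper and lower tails of a genetic risk
  score (:class:`MultiVariantDesign`).

Both calculators reduce to one of two statistical kernels defined here: a
two-sided two-group mean comparison (:func:`two_group_power`) for the recall
arms, and a two-sided slope test in simple linear regression
(:func:`regression_power`) for the matched random-sample comparator. Both
kernels use the large-sample normal approximation; exact small-sample t/F
power is deliberately out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import ParameterError

__all__ = [
    "Comparison",
    "Method",
    "SingleVariantDesign",
    "MultiVariantDesign",
    "PowerResult",
    "genotype_frequencies",
    "two_group_power",
    "regression_power",
]


def _require(cond: bool, param: str, message: str) -> None:
    if not cond:
        raise ParameterError(param, message)


class Comparison(enum.Enum):
    """Which genotype groups form the two recall arms of an RbG^sv study."""

    HOM_VS_HOM = "hom-vs-hom"
    HOM_VS_HET = "hom-vs-het"

    @classmethod
    def parse(cls, value: "Comparison | str") -> "Comparison":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("_", "-")
        aliases = {
            "hom-vs-hom": cls.HOM_VS_HOM,
            "hom-hom": cls.HOM_VS_HOM,
            "hom-vs-het": cls.HOM_VS_HET,
            "hom-het": cls.HOM_VS_HET,
        }
        if key not in aliases:
            raise ParameterError(
                "comparison", f"unknown comparison {value!r}; use hom-hom or hom-het"
            )
        return aliases[key]


class Method(enum.Enum):
    ANALYTIC = "analytic"
    SIMULATION = "simulation"


@dataclass(frozen=True)
class SingleVariantDesign:
    """Parameters of a single-variant recall (RbG^sv) experiment.

    Parameters
    ----------
    maf
        Minor allele frequency, in (0, 0.5]. Alleles with frequency above
        0.5 must be recoded to the minor allele by the caller.
    beta
        Standardized per-allele effect: mean phenotype shift per minor
        allele, in within-genotype (residual) SD units. This
        standardization is what makes recall power exactly MAF-free.
    n_total
        Total recall sample size across both arms.
    comparison
        Which genotype groups are recalled (minor vs major homozygotes, or
        heterozygotes vs major homozygotes).
    allocation
        Fraction of ``n_total`` recruited into the minor-genotype arm.
    alpha
        Two-sided type-I error rate.
    """

    maf: float
    beta: float
    n_total: int
    comparison: Comparison = Comparison.HOM_VS_HOM
    allocation: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        _require(0.0 < self.maf <= 0.5, "maf", "must be in (0, 0.5]")
        _require(self.n_total >= 4, "n_total", "must be at least 4")
        _require(0.0 < self.allocation < 1.0, "allocation", "must be in (0, 1)")
        _require(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        object.__setattr__(self, "comparison", Comparison.parse(self.comparison))


@dataclass(frozen=True)
class MultiVariantDesign:
    """Parameters of a GRS-tail recall (RbG^mv) experiment.

    ``r2_xg`` is the fraction of exposure variance explained by the genetic
    risk score (instrument strength), ``r2_yx`` the fraction of outcome
    variance explained by the exposure. ``percentile`` is the tail
    recruitment threshold as a fraction per tail: 0.05 means recruitment
    from the top and bottom 5% of the GRS distribution.
    """

    r2_xg: float
    r2_yx: float
    percentile: float
    n_total: int
    alpha: float = 0.05

    def __post_init__(self):
        _require(0.0 <= self.r2_xg <= 1.0, "r2_xg", "must be in [0, 1]")
        _require(0.0 <= self.r2_yx <= 1.0, "r2_yx", "must be in [0, 1]")
        _require(self.r2_xg * self.r2_yx < 1.0, "r2_xg", "r2_xg*r2_yx must be < 1")
        _require(0.0 < self.percentile <= 0.5, "percentile", "must be in (0, 0.5]")
        _require(self.n_total >= 4, "n_total", "must be at least 4")
        _require(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Power of a recall design next to its matched random-sample design.

    ``gain`` is ``power_recall - power_random``; ``mc_se`` is the
    Monte-Carlo standard error of the estimated powers (the larger of the
    two arms' binomial SEs), zero for analytic results.
    """

    power_recall: float
    power_random: float
    gain: float
    method: Method = Method.ANALYTIC
    mc_se: float = 0.0

    @classmethod
    def from_powers(
        cls,
        power_recall: float,
        power_random: float,
        method: Method = Method.ANALYTIC,
        mc_se: float = 0.0,
    ) -> "PowerResult":
        return cls(power_recall, power_random, power_recall - power_random, method, mc_se)


def genotype_frequencies(maf: float) -> tuple[float, float, float]:
    """Hardy–Weinberg genotype frequencies ``(major hom, het, minor hom)``.

    For minor allele frequency ``q`` returns ``((1-q)^2, 2q(1-q), q^2)``.
    """
    _require(0.0 < maf <= 0.5, "maf", "must be in (0, 0.5]")
    q = maf
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def two_group_power(
    delta: float, sd_within: float, n1: float, n2: float, alpha: float = 0.05
) -> float:
    """Power of a two-sided two-group comparison of means.

    Normal approximation: with noncentrality
    ``|delta| / (sd_within * sqrt(1/n1 + 1/n2))`` the power is
    ``Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2})``. At
    ``delta = 0`` this equals ``alpha`` exactly, and the result is symmetric
    in the sign of ``delta``.
    """
    _require(sd_within > 0.0, "sd_within", "must be positive")
    _require(n1 >= 2 and n2 >= 2, "n1/n2", "each group needs at least 2 members")
    _require(0.0 < alpha < 1.0, "alpha", "must be in (0, 1)")
    se = sd_within * math.sqrt(1.0 / n1 + 1.0 / n2)
    ncp = abs(delta) / se
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(ncp - zcrit) + norm.cdf(-ncp - zcrit))


def regression_power(r2: float, n: float, alpha: float = 0.05) -> float:
    """Power of a two-sided test of zero slope in simple linear regression.

    For population variance explained ``r2`` at sample size ``n`` the
    noncentrality is ``sqrt(n * r2 / (1 - r2))``; power then follows the
    same normal form as :func:`two_group_power`.
    """
    _require(0.0 <= r2 < 1.0, "r2", "must be in [0, 1)")
    _require(n >= 3, "n", "must be at least 3")
    _require(0.0 < alpha < 1.0, "alpha", "must be in (0, 1)")
    ncp = math.sqrt(n * r2 / (1.0 - r2))
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(ncp - zcrit) + norm.cdf(-ncp - zcrit))
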