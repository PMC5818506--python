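"""Power and bioresource sizing for single-variant recall (RbG^sv) designs.

The recall design recruits two genotype arms (minor vs major homozygotes, or
heterozygotes vs major homozygotes) and compares phenotype means; its power
does not depend on the minor allele frequency, only on the per-allele effect
and the arm sizes. The matched random design genotypes a random sample of
the same size and regresses phenotype on allele dosage; its power collapses
as MAF falls, which is where recall designs gain the most.

The cost of the recall design is the size of the genotyped bioresource
needed to find the rare-genotype arm: under Hardy–Weinberg equilibrium the
expected number of minor homozygotes in a bioresource of size N is N*q^2,
so recruiting ``n`` of them needs roughly ``n / q^2`` genotyped people.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import (
    Comparison,
    Method,
    PowerResult,
    SingleVariantDesign,
    genotype_frequencies,
    regression_power,
    two_group_power,
)
from .errors import ParameterError

__all__ = [
    "BioresourceRequirement",
    "sv_recall_power",
    "sv_random_power",
    "sv_power_gain",
    "required_bioresource_size",
]


@dataclass(frozen=True)
class BioresourceRequirement:
    """Expected bioresource size needed to fill the rare-genotype arm."""

    n_minor_group: int
    required_bioresource: int
    participation_rate: float = 1.0


def sv_recall_power(design: SingleVariantDesign) -> float:
    """Analytic power of the recall design.

    The group mean difference is ``2*beta`` for homozygote-vs-homozygote
    recall (two allele copies apart) and ``beta`` for heterozygote recall,
    with unit within-group SD since ``beta`` is standardized in residual-SD
    units. The result is identical for every MAF.
    """
    delta = design.beta * (2.0 if design.comparison is Comparison.HOM_VS_HOM else 1.0)
    n1 = design.allocation * design.n_total
    n2 = (1.0 - design.allocation) * design.n_total
    return two_group_power(delta, 1.0, n1, n2, design.alpha)


def sv_random_power(design: SingleVariantDesign, n_random: int | None = None) -> float:
    """Analytic power of the matched random-sample design.

    A random sample of ``n_random`` (default: the recall budget
    ``n_total``) is regressed phenotype-on-dosage. Under additive coding
    the dosage variance is ``2q(1-q)`` so the variance explained is
    ``2q(1-q)*beta^2 / (1 + 2q(1-q)*beta^2)`` — the denominator is the
    total phenotypic variance (genetic plus unit residual).
    """
    if n_random is None:
        n_random = design.n_total
    q = design.maf
    het_var = 2.0 * q * (1.0 - q)
    genetic_var = het_var * design.beta**2
    r2 = genetic_var / (1.0 + genetic_var)
    return regression_power(r2, n_random, design.alpha)


def sv_power_gain(design: SingleVariantDesign, n_random: int | None = None) -> PowerResult:
    """Recall power, matched random power and their difference."""
    return PowerResult.from_powers(
        sv_recall_power(design),
        sv_random_power(design, n_random),
        method=Method.ANALYTIC,
    )


def required_bioresource_size(
    n_minor_group: int,
    maf: float,
    comparison: Comparison | str = Comparison.HOM_VS_HOM,
    participation_rate: float = 1.0,
) -> BioresourceRequirement:
    """Expected genotyped-bioresource size to recruit the rare-genotype arm.

    Uses the Hardy–Weinberg expectation: the target genotype occurs at
    frequency ``q^2`` (minor homozygotes) or ``2q(1-q)`` (heterozygotes),
    and only ``participation_rate`` of eligible carriers enrol, so

        required = ceil(n_minor_group / (freq * participation_rate)).

    Sampling variability in genotype counts is not modelled; the planning
    question is about expected resource size.
    """
    if n_minor_group < 1:
        raise ParameterError("n_minor_group", "must be at least 1")
    if not 0.0 < participation_rate <= 1.0:
        raise ParameterError("participation_rate", "must be in (0, 1]")
    comparison = Comparison.parse(comparison)
    _, f_het, f_minor_hom = genotype_frequencies(maf)
    freq = f_minor_hom if comparison is Comparison.HOM_VS_HOM else f_het
    raw = n_minor_group / (freq * participation_rate)
    # guard against binary-float crumbs pushing an exact ratio past the ceiling
    required = math.ceil(raw - 1e-9)
    return BioresourceRequirement(n_minor_group, required, participation_rate)
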