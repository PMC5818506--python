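# Methods

## Statistical model

### Power kernels

Both design calculators reduce to two-sided tests at level α under the
large-sample normal approximation.

**Two-group comparison.** For group mean difference δ, common within-group
SD σ and arm sizes n₁, n₂, the noncentrality is
ν = |δ| / (σ·√(1/n₁ + 1/n₂)) and

    power = Φ(ν − z_{1−α/2}) + Φ(−ν − z_{1−α/2}).

**Regression slope test.** For population variance explained R² at sample
size n, ν = √(n·R²/(1−R²)) with the same normal form.

At δ = 0 (or R² = 0) both reduce exactly to α; both are symmetric in the
sign of the effect and monotone in effect magnitude and sample size. Exact
small-sample t/F power is deliberately not implemented: at the sample
sizes recall studies are planned for (tens per arm and up), the normal and
t answers differ by well under a percentage point, which is far below the
uncertainty in the effect-size inputs themselves. The Monte-Carlo engine
(below) quantifies the residual approximation error.

### Single-variant recall (RbG^sv)

The per-allele effect β is standardized in **within-genotype (residual) SD
units**. Under additivity the recall arms sit 2β apart (homozygote vs
homozygote) or β apart (heterozygote vs homozygote) with unit within-group
SD, so recall power is exactly free of the minor allele frequency q — the
property that makes genotype-based recall attractive at rare variants.
This standardization choice is the only one under which that independence
is exact; its consequence is that the random design's variance explained
carries the genetic variance in its denominator:

    R² = 2q(1−q)β² / (1 + 2q(1−q)β²),

the total phenotypic variance being genetic (2q(1−q)β²) plus unit
residual. The random comparator is the standard additive-dosage regression
(the usual GWAS test); comparing genotype groups *within* a random sample
would be strictly worse and is not modelled. Dominance deviations are not
modelled; if the genetic model is known, the contrast should be adjusted
accordingly before using the calculator.

**Bioresource sizing** uses the Hardy–Weinberg expectation: the target
genotype occurs at frequency q² (minor homozygotes) or 2q(1−q)
(heterozygotes), thinned by the participation rate, with ceiling rounding.
Sampling variability of genotype counts is ignored — the planning question
is about expected resource size, and at the bioresource scales involved
(10⁴–10⁶) the relative fluctuation is negligible. A small (10⁻⁹) slack is
applied before the ceiling so exact ratios are not pushed up a unit by
binary-float representation.

### GRS-tail recall (RbG^mv)

The standardized GRS is treated as standard normal — justified by the CLT
for scores summing tens of weighted dosages, and checked empirically in
the simulator (Kolmogorov–Smirnov distance < 0.01 at 50 variants). For a
tail fraction c per side, with z_c = Φ⁻¹(1−c):

    λ(c) = φ(z_c)/c              (tail mean, inverse Mills ratio)
    v(c) = 1 + z_c·λ − λ²        (within-tail variance, < 1)

Under the standardized linear chain X = √R²_XG·G + e_x,
Y = √R²_YX·X + e_y, the conditional outcome mean given the GRS is
√(R²_XG·R²_YX)·G, so symmetric tail arms are separated by
Δ_Y = 2λ(c)·√(R²_XG·R²_YX) and the within-arm outcome SD is
√(R²·v(c) + (1−R²)) with R² = R²_XG·R²_YX. The variance-reduction term is
below 1% of the SD at realistic instrument strengths (R² ≤ 0.05) but is
kept because it is free and exact under the model. Power is the two-group
kernel at arms of n/2.

The random comparator tests the GRS–outcome slope (variance explained
R²_XG·R²_YX), not the exposure–outcome association: the random design
measures the same randomly allocated instrument, preserving the
causal-inference framing in which the GRS is the exposure proxy.

**Recruitment rate**: each tail of a genotyped cohort of size N holds c·N
people, so filling arms of n/2 needs a rate of (n/2)/(c·N); above 1 the
plan is flagged infeasible. Odd n is rejected rather than silently
rounded, because "half of n per tail" would otherwise be ambiguous.

## Monte-Carlo engine

`empirical_power` replays the full design n_reps times: single-variant
replicates simulate the two genotype arms directly (selection is on
genotype and the phenotype model is conditional on genotype, so this is
distribution-identical to selecting from a simulated bioresource, at a
fraction of the cost); multi-variant replicates simulate a genotyped
bioresource — by default the smallest whose tails can fill both arms —
rank on the GRS, and recruit the extremes. Each replicate also draws a
fresh random sample for the comparator design.

Replicate-level tests mirror the analytic kernels: z statistics against
normal critical values, with residual SDs the structural model fixes (unit
phenotype noise; √(1−R²) outcome noise) treated as known. The one variance
the model does *not* hand the test — the within-tail outcome spread of a
GRS-tail arm, which is exactly what the v(c) propagation predicts — is
pooled-estimated from the arms, keeping that formula under genuine test
(at ~150 per arm the estimation df effect is negligible). This mirroring
means analytic-vs-empirical discrepancies isolate formula errors rather
than small-sample test mismatches; the kernels' own adequacy is separately
checked in the test suite against fully independent vectorized simulations.

Each replicate draws from a dedicated stream seeded from (master seed,
replicate index) via numpy's `SeedSequence`, so results are bit-reproducible
and growing the replicate count never reshuffles earlier replicates.
Stochastic agreement between analytic and empirical power is asserted at
3 Monte-Carlo SEs on the 10⁴-replicate scale (≈ ±1.5 points near 50%
power), with the empirical side measured at 4×10⁴ replicates so a correct
formula is not failed on an unlucky draw.

## Synthetic cohorts

`simulate_grs_cohort` draws independent HWE dosages for each (maf, weight)
variant, standardizes the weighted sum by its population moments
(mean Σ2·maf·w, variance Σ2·maf(1−maf)·w²), and generates exposure and
outcome from the structural chain plus confounders. Confounders are
independent standard normals acting linearly on exposure (a_j) and outcome
(b_j); residual variances are solved so exposure and outcome have unit
variance, and models whose variance budget exceeds 1 are rejected. The
default demonstration model uses 50 variants (MAFs 0.1–0.5, weights
0.5–1.5 — only the variant count materially matters for score normality)
and three confounders with (a, b) = (0.2, 0.1), standing in for lifestyle
and socioeconomic confounders of, say, an adiposity exposure and a
blood-pressure outcome.

What the generator does **not** emulate: linkage disequilibrium between
variants, dosage-imputation uncertainty, non-linear or interacting
effects, non-normal confounder marginals, binary or survival outcomes, and
genotype-dependent participation. Passing tests therefore demonstrate
correctness *under the stated structural model*, not robustness to these
real-data features.

`strata_balance_report` cuts one simulated cohort at the top and bottom
30% (configurable) of the exposure and, separately, of the GRS, and
reports standardized mean differences with Hedges-type standard errors.
GRS strata stay balanced on confounders at any confounding strength (the
randomization property genotype recall inherits); exposure strata show the
confounding directly. Only this qualitative contrast is asserted — the
real-cohort magnitudes it emulates are not tabulated anywhere to compare
against.

## Numerical and interface choices

- Problem sizes: agreement grids run 4×10⁴ replicates per cell; balance
  demonstrations use cohorts of 10⁵; the KS normality check uses 50
  variants at n = 10⁵. These sizes put Monte-Carlo noise well below every
  asserted tolerance.
- MAF is restricted to (0, 0.5]; alleles above 0.5 must be recoded by the
  caller ("minor allele" semantics). Percentiles and rates are fractions
  everywhere (0.05 = 5%) to avoid percent-vs-fraction ambiguity.
- `solve_sample_size` searches even totals only (equal arms by default)
  with exponential bracketing plus bisection, returning the smallest n with
  power(n) ≥ target > power(n−2).
- CSV/JSON output is written at full shortest-round-trip precision
  (`repr`); reload CSVs with `pandas.read_csv(..., float_precision=
  "round_trip")` for exact round-trips. Powers are not pre-rounded:
  machine-readability and lossless reload take precedence over display.
- Degenerate inputs fail fast with the offending parameter named
  (`ParameterError`); infeasible recruitment is a distinct error carrying
  the computed rate; a constant regressor in a replicate counts as a
  non-rejection.
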