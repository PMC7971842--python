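# Methods

## Model

The sampling unit is a case family ascertained on an affected, genotyped
child. At one biallelic SNP, write (m, f, c) for mother/father/child
minor-allele dosages. Enumerating each parent's transmitted allele gives
15 Mendelian-consistent trio categories; tracking which parent supplied a
heterozygous child's minor allele splits the (1,1,1) category in two, for
16 cells in total. Each cell's expected count under the log-linear model
is

    mu_j · t · R_c · S_m · W^[paternal origin]

with t the Mendelian transmission factor (the factors sum to 1 over
child outcomes within every ordered parental pair), mu_j one of six
mating-type strata, R and S child- and maternal-genotype relative risks
(R_0 = S_0 = 1), and W the imprinting relative risk. Modelling counts
as Poisson and conditioning on the total is equivalent, for the
structural parameters, to a multinomial over the 16 cells; we implement
the multinomial directly (single implementation, documented equivalence).

Assumptions worth making explicit:

* **Parental mating symmetry.** The two orders of a heterogeneous
  parental pair share one stratum weight. Without this, parental
  asymmetry is confounded with W; it is the standard assumption of the
  log-linear trio framework, and the simulator (random mating) satisfies
  it by construction.
* **W applies to heterozygous children only.** A homozygous child
  received one minor allele from each parent; any such effect is
  absorbed by R_2. The reported relative risk is Ŵ itself.
* **Missing parents are marginalized, not imputed.** A family with an
  ungenotyped parent contributes the sum of cell probabilities
  compatible with its observed members, under the same mu parameters —
  no external allele-frequency or HWE assumption enters the likelihood.
  Because the observed patterns of a given missingness type partition
  the cell space, these pattern probabilities are a proper multinomial;
  validity requires missingness unrelated to genotype (the usual
  missing-at-random condition for this design).
* **One case child per family**; sibships, X-linkage and penetrance
  scale are out of scope (a case-only family design identifies relative
  risks only).

W is informed only by the six origin-unambiguous heterozygous-child
categories and the (1,1,1) category (whose observable probability
contains the factor (1 + W)/stuff through its latent split). A dataset
with no such families leaves W unidentified; the fit flags this
(`n_informative = 0`) and reports RR = NaN with p = 1 rather than a
spurious estimate.

## Fitting

All parameters are optimized on the log scale (unconstrained), by
L-BFGS-B with an analytic gradient, one zero start plus three jittered
restarts from a fixed stream; the best optimum is kept and convergence
flags are propagated. Log-parameters are boxed at ±30: a parameter whose
maximum-likelihood value is on the zero boundary (e.g. a mating stratum
with no compatible families in sparse data) settles at exp(−30) ≈ 1e−13
instead of overflowing, which is the boundary MLE to numerical accuracy.
Parameters appearing in **no** cell compatible with any observed family
are removed from the support entirely (their cells are deleted — the
exact zero-boundary limit) before either model is fitted, so full and
null models share one reduced support and the LRT remains nested.

The null model fixes W = 1 with identical settings. The test statistic
is 2(ℓ_full − ℓ_null), referred to χ²(1); tiny negative values (< 1e−8,
optimizer noise) are clipped to zero. Standard errors come from the
observed information, obtained by central finite differences of the
analytic gradient at the optimum; the 95% CI is exp(log Ŵ ± 1.96·se).
P-values are LRT-based while CIs are Wald — the two can disagree near
strong effects, which is visible in published tables of this design and
is expected behaviour, not an inconsistency.

Degenerate inputs: zero counts in informative categories need no
continuity correction (the multinomial handles structural zeros);
complete trios in Mendelian-impossible categories raise, since QC should
have removed them.

## Quality control

Four per-SNP filters, mirroring standard family-panel practice — a SNP
passes only if all hold:

| filter | statistic | default threshold |
|---|---|---|
| no-call | missing genotype slots / slots of pedigree-present individuals | ≤ 0.10 |
| Mendelian error | inconsistent trios (+ impossible duos) / informative families | ≤ 0.05 |
| MAF | folded founder minor-allele frequency, pooled | ≥ 0.05 |
| HWE | exact test (probability ordering) on founders, per stratum | min p ≥ 1e−4 |

Choices where practice varies: the error rate restricts to informative
comparisons (complete trios, plus parent-child duos which can only
reveal opposite-homozygote impossibilities); MAF uses founders only,
because case children are ascertainment-biased; the HWE test is the
exact conditional test rather than χ², and the significance level —
which published reports often leave as just "significant" — defaults to
1e−4, a common panel-QC choice that avoids over-pruning at
hundreds-of-SNPs scale. All four thresholds are configurable.

## Synthetic data

The generator emulates the structure of a candidate-gene case-family
study: 569 families, 38.7% full trios (the rest missing one parent, 90%
of the time the father), biallelic SNPs with MAF drawn from [0.05, 0.5],
and optional per-genotype no-calls. Parents are drawn under HWE random
mating; each transmits a fair allele with tracked origin; the family is
accepted into the case sample with probability proportional to
R_c · S_m · W^[paternal het] by rejection sampling against the maximum
multiplier (exact ascertainment, cheap at desk scale). The origin tag is
then discarded — it is unobservable. With all effects at 1 every family
is accepted, so the null reduces to unconditional sampling. Family
completeness is assigned once per family, making missingness consistent
across SNPs. An optional second stratum is generated out of HWE through
an inbreeding coefficient, to exercise the stratified HWE filter.

What it does **not** emulate: linkage disequilibrium between SNPs,
genotyping-error confusion beyond no-calls, population admixture, or
informative missingness. SNPs are also simulated independently, so a
multi-SNP panel is a collection of marginal draws rather than one cohort
genotyped at many linked markers. Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness
to LD, stratification or differential missingness in real data.

Default effect magnitudes for planted signals (W = 0.11, 0.30, 0.34)
mirror the relative risks reported by the motivating study, so that
power at study scale is realistic rather than flattering.

## Scan

The Bonferroni denominator is the number of SNPs actually tested
(post-QC) — for a 877-SNP panel at α = 0.05 that is 5.70×10⁻⁵ — with
exact division internally and rounding only for display. Ties in p are
ordered by (chromosome, position). Outputs are plot-ready tables
(ranked results, Manhattan coordinates, per-pathway relative risks); no
figure rendering in core.

## Problem sizes and numerics

The test suite's simulation studies use 2,000 null replicates of 500
families for LRT calibration and 200 replicates of 569 families for
W-recovery and CI coverage — sizes at which the binomial bands quoted in
the tests are meaningful while a full run stays in the low minutes on
one CPU. The acceptance script uses 400 null replicates and 100 recovery
replicates for the same summaries. Optimizer tolerances: `ftol` 1e−13,
projected-gradient 1e−8; stationary-point recovery on exact expected
counts is accurate to ~1e−5 relative, an order below the 1e−4 the tests
assert. The cell-probability normalization is exact to 1e−12.
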