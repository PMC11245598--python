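# Methods

## De novo identification

A record is a per-(family, site, alt-allele) observation with per-member
depth (DP), alternate depth (AD), and mapping quality. The filters, in
fixed order (each call retains the full trace):

1. evaluable evidence on every required member;
2. mapping quality ≥ 30 (site-level MQ is used when per-sample MQ is not
   in the call set);
3. total depth ≥ 20 in all required members;
4. child alternate depth ≥ 5 (applied to the child only — parents are
   required *absent*, so a parental alternate-depth floor would be
   meaningless);
5. child alternate allele fraction in [0.3, 0.7], both endpoints
   inclusive;
6. each parent's alternate allele fraction strictly below 0.05 ("absent in
   both parents" is read as *each* parent individually below the cutoff: a
   variant present in either parent is inherited).

X chromosome, male child: hemizygous calls present near-homozygous, so the
child window becomes [0.3, 1.0] (the upper bound is configurable; the
convention is stated here because trio callers differ) and only the mother
is a required member — the father does not transmit an X to a son, so his
genotype neither rejects nor is his depth required. Female children follow
the autosomal rules.

Boundary semantics throughout: window endpoints inclusive, "<" thresholds
strict. Rarity tiers (gnomAD non-neuro AF): ultra-rare < 5·10⁻⁵ ⊂ rare
< 10⁻³, both strict. Damage classes partition calls: PTV (stop-gain,
frameshift insertion/deletion, canonical splice), MisD (missense with
MPC > 2, strict — a missense record with no MPC score cannot reach MisD),
missense-other, synonymous, other. Collapse to one call per (family, gene)
keeps the most severe class, ties broken by lower position then
lexicographic alt allele. Families whose child carries strictly more than
20 calls are excluded as outliers. Multi-allelic sites are decomposed into
one record per alt allele before filtering.

## Burden statistics

Callable bp per family counts loci at depth ≥ 20, base quality ≥ 20, and
mapping quality ≥ 30 inside the capture-platform intersection (standard
0-based half-open BED semantics; 1-based positions are converted
explicitly). The haploid rate is x/(2T); the factor 2 (two haplotypes per
trio) cancels in the rate ratio but is kept in reported rates. Per-group
CIs are exact Garwood intervals via the chi-square representation of
Poisson tails. The case/control comparison is the exact conditional test
(no mid-p correction, matching the exact convention of the standard
rate-ratio implementations): conditional on the total, the case count is
binomial with success probability proportional to case exposure; the
alternative defaults to "case rate greater", the direction the burden
hypothesis specifies, and is configurable. The rate-ratio CI inverts the
Clopper–Pearson interval for the conditional proportion; it is reported
separately from the per-group Poisson CIs, which answer a different
question.

## Gene-level Bayesian association

Mixture model: a gene is a risk gene with probability π. Per evidence
category the relative risk γ of a risk gene has a Gamma prior
parameterized by mean γ̄ and dispersion β (shape γ̄β, rate β) — stated
explicitly because the (γ̄, β) convention leaves the density implicit.

De novo categories: H₀ count ~ Poisson(2Nμ); under H₁ the Gamma prior
integrates analytically to a negative binomial with shape γ̄β and success
probability β/(β + 2Nμ), so the Bayes factor is closed-form (computed in
log space). μ = 0 with a nonzero count falls back to a configurable rate
floor (default 10⁻⁹ per haploid gene-equivalent).

Case–control categories: the per-gene baseline rate is a nuisance
parameter. Conditioning on n = x_ca + x_co removes it exactly under
Poisson sampling: H₀ gives x_ca ~ Binomial(n, N_ca/(N_ca+N_co)); relative
risk γ tilts the success probability to N_ca·γ/(N_ca·γ + N_co). The Bayes
factor integrates the Gamma prior by adaptive quadrature over the prior's
quantile range (truncation at the 10⁻¹⁴ quantiles; the integrand is
bounded by the prior density, so this is safe even for near-degenerate
priors), split at the prior mode. Results are cached by count/parameter
tuple, which makes genome-scale runs cheap because distinct small-count
pairs are few. This conditional-likelihood formulation avoids inventing
the unreported baseline-rate hyperprior of the full hierarchical model;
for Poisson counts the two are equivalent.

Combination: category BFs multiply (missing categories contribute 1),
PP = πB/(πB + 1 − π), and the Bayesian FDR at rank k of the list sorted by
decreasing PP is the running mean of (1 − PP); tied PPs share the q of the
last tied rank. Tiers: q < 0.1 high-confidence, q < 0.3 potential. The
hyperparameter defaults are fixed point estimates from the ADHD analysis
(π = 0.055; γ̄ = 21.35/20.34 de novo PTV/MisD, 1.78/1.61 case–control;
β = 0.82/0.83/3.98/6.17); re-estimating them by MCMC is out of scope. The
risk-gene extrapolation is round(π·n_genes); with the rounded π = 5.50%
and 19,560 genes this gives 1076, whereas an unrounded mixture proportion
near 5.40% yields a count near 1057 — the extrapolation is only as precise
as the proportion supplied. The gene universe excludes the packaged list
of 58 medically-actionable (secondary-findings) genes, case-normalized.

## Enrichment

One-tailed hypergeometric over-representation (P(K ≥ k)); sets below the
minimum overlap (default 2) are dropped before counting tests; q = p·N/r
exactly as stated, with no monotonicity post-processing (the capped-at-1
value is reported alongside the raw one). Reference sets come from
user-supplied GMT snapshots rather than live database queries, for
reproducibility and offline operation; released database q-values are
therefore not expected to reproduce exactly.

## Synthetic cohorts

What is emulated: per-trio de novo counts Poisson with mean 2·Σμ (events
placed proportionally to per-gene rates; risk genes multiplied by a
relative risk in case trios only); inherited variants in exactly one
parent, transmitted with probability 1/2; Gamma-Poisson read depth
(mean 55, shape 8); heterozygous alt fractions Beta(20, 20) around 0.5 so
the 0.3–0.7 gate removes a realistic minority of true events; hemizygous
male-X fractions Beta(30, 1.5) near 1; parental contamination alt reads at
mean fraction 0.005 exercising the < 0.05 gate; mapping quality ~N(59, 2)
with a 2% low-MQ tail; true de novo gnomAD AFs mostly 0 with a 10% spike
in [10⁻⁵, 5·10⁻⁵] straddling the ultra-rare boundary; callable bp
~N(32 Mb, 2 Mb) per trio. Cohort sizes default to the study conditions
(147 case / 780 control trios; 83% / 45% male children). Per-gene rates
are drawn log-uniform over two decades and scaled to haploid class totals
(PTV 0.04, MisD 0.035, other missense 0.34, synonymous 0.125) matching
~1.1 coding de novo events per child; absolute per-gene calibration to a
published mutation-rate table is deliberately left configurable.

Not emulated: linkage disequilibrium, haplotype phasing, sequence-context
mutation models, CNVs, batch/platform effects, relatedness errors. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to artifacts absent from it.

Case–control counts: control count Poisson(N_co·q_g) with baseline
q_g = scale·μ_g (default scale 0.2, giving realistic sub-unit mean counts
at N ≈ 5000); case count Poisson(N_ca·q_g·γ) with γ ~ Gamma prior in risk
genes. This is exactly the model the conditional-binomial Bayes factor
assumes, which is what makes the FDR-calibration check a genuine
consistency test.

Determinism: a single `numpy` Generator seeded from the config drives
everything; identical configs give identical cohorts. Cohorts are written
as one VCF per family (plus PED, coverage TSV, truth TSV): a single joint
VCF would force genotype columns for every family at every other family's
sites, and the reader contractually emits one record per (family, site,
alt). The VCF emitter is a small text writer whose output is always read
back through cyvcf2 in the round-trip tests.

## Verification sizes and numerical choices

Oracles are independent of the code paths they check: Poisson CIs against
root-finding inversion of Poisson tails; rate-ratio p-values against
exhaustive binomial tail sums for all totals ≤ 50; the de novo Bayes
factor against adaptive quadrature with the H₀ likelihood factored into
the integrand (so nothing underflows at μ = 10⁻⁷), agreeing to better than
10⁻⁸ relative over counts ≤ 10 and μ ∈ [10⁻⁷, 10⁻⁴]; the case–control
Bayes factor against fine-grid Riemann integration; hypergeometric
p-values against combinatorial enumeration for universes ≤ 25.

Monte-Carlo checks use: 5000 Poisson draws at an expected count of 300 for
CI coverage (at small expected counts the exact interval's analytic
coverage exceeds 96% by construction; 300 places it near 95.0%, computed
by enumeration at design time); 500 null cohorts of 60 + 60 trios for
p-value uniformity (Kolmogorov–Smirnov at α = 0.001 — the p-value is
discrete, so cohort sizes are chosen to give ≈ 150 support points); 20
replicates of 5000 genes, 3000 trios, and the 3206/5002 case–control split
for FDR calibration (3000 trios rather than 147 so that the q < 0.1 set is
non-trivially populated; calibration is a model-consistency property and
holds at any N). These sizes keep the default test run under a minute of
statistical computation while leaving each check's expected margin several
standard errors wide.

## Known limitations

- Hyperparameters are consumed as fixed point estimates; no uncertainty
  propagation from their credible intervals.
- The conditional-binomial case–control likelihood matches the Poisson
  sampling model; under strong deviations (e.g. overdispersed counts) it
  inherits the usual fragility of exact conditional methods.
- The published cohort-level burden numbers (rate ratios 1.93/1.67/1.94)
  require the per-family supplementary coverage and variant tables as
  inputs; the repository carries only the fully printed 24-variant call
  table, so the burden recompute runs only when those tables are supplied
  locally.
- Capture-interval BED generation, read-level confirmation, relatedness
  QC, and annotation are upstream of this package and consumed as inputs.
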