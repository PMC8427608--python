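# Methods

## Scope and data model

The package analyses one biallelic indel locus at a time. Its reference
locus is the 104-bp insertion/deletion in the chicken *ADPRHL1* 5'UTR
(1-based inclusive span 138,752,529–138,752,632 on chromosome 1, so the
span length equals the indel length; diagnostic amplicons 218/114 bp, whose
difference must equal the indel length — both identities are enforced as
constructor invariants). Genotypes enter as calls (II, ID, DD or missing);
no read-level genotyping is attempted. Tables travel as UTF-8 delimited
text with header rows; the VCF exporter writes a single anchored record
(VCF 4.2) with an explicit flag for whether the reference carries the
insertion, since the variant can be described equivalently as an insertion
or a deletion. The indel segment's sequence is written as `N` bases: allele
identity at this locus is carried by length, which is what the gel assay
measures.

## Locus diversity statistics

Allele frequencies are obtained by gene counting. With p the deletion-allele
frequency and q = 1 − p:

- Ho = n_ID / n, He = 2pq, Ne = 1/(p² + q²),
- PIC = 1 − (p² + q²) − 2p²q² (the biallelic reduction of Botstein's
  measure; maximum 0.375 at p = 0.5),
- polymorphism classes: low (PIC < 0.25), moderate (0.25 ≤ PIC < 0.5),
  high (≥ 0.5, unreachable for two alleles).

Hardy–Weinberg equilibrium is tested two ways. The headline value is the
exact conditional test: given the observed allele counts, all heterozygote
counts of matching parity are enumerated, their conditional probabilities
computed in log space (log-gamma), and the p-value is the sum of
probabilities ≤ the observed configuration's (plain exact tail — no mid-p —
which is what GENEPOP-style software computes for two alleles, where the
Markov-chain approximation collapses to complete enumeration). A tie
tolerance of one part in 10¹² guards against floating-point noise, and the
sum is clamped at 1. A 1-df chi-square goodness-of-fit test is provided as a
cross-check. Fixed-locus conventions: He = PIC = 0, Ne = 1, both HWE
p-values 1.

All statistics are carried at full precision; publication-style rounding
(half-up: genotype frequencies/Ho/He to 2 decimals, allele
frequencies/Ne/PIC/HWE to 3) is applied only by the report renderer.

## Association models

Each trait is fitted by ordinary least squares under one of two fixed-effect
models: Model I (genotype + sex + hatch + family) for body weights, carcass,
meat-quality and serum traits; Model II (Model I + centered slaughter-weight
covariate) for linear body-size traits, where overall size should be
adjusted out. The model policy is keyed by trait category in the trait
registry; unknown codes fall back to Model I.

Numerical choices:

- Factors are coded sum-to-zero, so the intercept is the equal-weight grand
  mean and the LS mean of genotype g is the contrast μ + G_g with all other
  factors balanced and the covariate at its (analyzed-subset) mean. Its SEM
  is the square root of the contrast's sampling variance from the
  coefficient covariance.
- Rows missing the trait (or the covariate under Model II) are dropped
  listwise per trait. Factors reduced to a single level are dropped with a
  warning; a single genotype class is an error; rank deficiency raises,
  naming the factor(s) whose columns lie in the span of the rest.
- Genotype significance is a partial (Type-III style) model-comparison
  F-test — full fit versus the fit without the genotype columns on the same
  rows — chosen because the genotype classes of an intercross are heavily
  unbalanced, where sequential sums of squares would depend on term order.
- Pairwise genotype contrasts are t-tests at the Bonferroni-adjusted level
  α/3 (α = 0.05 default, per trait; no correction across traits). Letters
  are assigned by insert-and-absorb, with "a" anchored to the largest LS
  mean; "ab" marks a class distinguishable from neither neighbour.
- Additive and dominance effects are reported on the genotypic-value scale:
  a = (mean_II − mean_DD)/2, d = mean_ID − (mean_II + mean_DD)/2, with
  standard errors from the corresponding coefficient contrasts. The ±1/0/∓1
  regression codings estimate the same quantities up to scale (the ±1
  dominance contrast's coefficient equals d/2); the genotypic-value scale is
  used because it is what "additive/dominance effect" means in the
  quantitative-genetics tables this mirrors. When a homozygote class is
  absent, a and d are undefined and flagged rather than extrapolated.
- Perfectly fitted responses (zero residual variance) degenerate gracefully:
  F and t statistics become infinite with p = 0 where the effect is nonzero,
  p = 1 where it is exactly zero.

Family is a fixed effect with 7 levels, exactly as the model equation
specifies — not a random effect — so no shrinkage or REML machinery is
involved; this also means between-family genetic structure is absorbed, not
modelled.

## Expression analysis

The Livak formulation: ΔCT = CT_target − CT_reference per sample,
ΔΔCT = ΔCT − mean(ΔCT of the calibrator group) with the arithmetic mean,
fold change 2^−ΔΔCT. By construction the calibrator's geometric-mean fold
change is exactly 1 (its arithmetic mean is 1 only in the noise-free case).
Group comparison is a two-sided Welch t-test on the fold-change scale —
matching how such results are plotted (means ± SEM of fold change) — with a
log2-scale option off by default, and stars at 0.05/0.01. No
amplification-efficiency correction is applied.

## Synthetic F2 cross generator

The generator emulates the resource-population design the association stage
assumes: two founder lines — a local slow-growing breed and a commercial
broiler line — produce F1 hybrids; 7 F1 sires are each mated to up to 9 F1
dams; 783 F2 offspring are split near-equally across the 7 sire families,
with sex and hatch assigned 50/50 at random (the real design's sex ratio
and hatch sizes are unreported, so symmetric defaults are used). Each F1
carries one allele drawn from each line's insertion frequency; each F2
receives one uniformly chosen allele from its sire and one from a randomly
assigned dam of its family. Founder insertion frequencies default to
(0.68, 0.85): the first is the local breed's published frequency; the
broiler line's own frequency is unpublished, so a mid-range commercial
broiler value from the same survey is used. All randomness flows from one
integer seed; identical configurations reproduce byte-identical tables.

Phenotypes are generated from the analysis model itself, with Falconer
genotypic values (+a, d, −a on the II/ID/DD means):

    y = μ + a·x_a + d·x_dID + sex + hatch + family + [b·(W − W̄)] + e

where x_a = +1/0/−1 and x_dID is the heterozygote indicator. Family effects
are drawn N(0, family_sd) once per family per trait; residuals are iid
normal. Slaughter weight W is always generated, itself carrying a genotype
effect, so the Model II covariate is realistically collinear with genotype —
the reason the two models are distinguished; its term enters only traits
whose policy is Model II. Defaults are scaled to an 84-day weight-type trait:
μ = 1200 g, a = 15 g, d = −5 g, residual sd = 170 g (back-computed from a
published SEM of ≈8.3 g at n = 423), sex effect 120 g, hatch effect 20 g,
family sd 30 g, b = 0.35.

What the generator does *not* emulate: polygenic background and kinship
beyond the 7-family fixed structure, genotype-by-environment interaction,
non-normal or heteroscedastic residuals, selection, linkage to other loci,
and trait-trait correlations (each trait draws independent noise). Passing
tests therefore demonstrate the correctness and calibration of the
estimation machinery under the stated model, not robustness to those
real-data features.

## Calibration experiments (test suite)

- The exact HWE test is checked for literal equality against an independent
  integer-arithmetic enumeration (exact binomials + rationals) over random
  and exhaustive panels up to n = 50, and for conservativeness (rejection
  rate ≤ 0.07 at α = 0.05 over 1000 Hardy–Weinberg panels of n = 200 at
  p_I = 0.7).
- Least-squares fits are checked coefficient-wise against a pseudo-inverse
  normal-equations solve (1e-8 relative).
- Additive/dominance recovery is measured over 200 seeded crosses at the
  full design size (n = 783, 7 families). This calibration uses a
  high-signal configuration (a = 60 g, d = −20 g, residual sd = 60 g) chosen
  by power analysis so that the Monte-Carlo error of the 200-replicate mean
  (≈0.4 g) sits well inside the 5% bias band being verified; at the
  realistic default signal-to-noise the bias band would be narrower than the
  Monte-Carlo noise and the check would be uninformative. Replicates lacking
  a homozygote class (the deletion allele can be absent from all 7 sires)
  are excluded, as the effects are undefined there. Coverage of ±2·se is
  assessed per parameter against a [90%, 99%] band.
- The genotype F-test's type-I error is measured over 1000 null phenotype
  replicates on a fixed cross and required to lie in [0.03, 0.07] at
  α = 0.05.

Problem sizes (200 recovery replicates, 1000 null replicates, 1000 HWE
panels) are the package's standing calibration design; the full suite runs
in well under a minute of compute for the unit tests plus ~15 s for the
calibration experiments.

## Known limitations

- Single biallelic locus only: no multi-allelic statistics, no linkage
  disequilibrium, no multi-locus scans.
- Fixed-effect families mean no variance-component estimation; with many
  families the approach would lose efficiency relative to a mixed model.
- The expression module implements the 2^−ΔΔCT arithmetic and group tests
  only; published fold-change magnitudes cannot be reproduced without the
  underlying CT values, which are not public.
- Association results on real data from the original study are likewise not
  reproducible here because the raw phenotypes are not deposited; the
  pipeline's correctness is established on synthetic crosses instead.
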