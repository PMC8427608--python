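# indelpop

Population-genetic characterisation and genotype–trait association analysis
for a biallelic structural variant: a 104-bp insertion/deletion (indel) in
the 5'UTR of the chicken *ADPRHL1* gene (chromosome 1, positions
138,752,529–138,752,632; PCR products 218 bp for the insertion allele I and
114 bp for the deletion allele D). The package is aimed at animal-genetics
researchers running candidate-marker studies in resource populations: it
covers the locus-diversity statistics reported in breed surveys, the
fixed-effect least-squares association models used for F2 intercross data,
and the Livak 2^−ΔΔCT relative-expression arithmetic — plus a seeded
synthetic F2-cross generator so the whole pipeline can be validated without
access to the original animals.

## The statistics

**Locus diversity.** For genotype counts (n_DD, n_ID, n_II) with allele
frequency p = p_D = (2·n_DD + n_ID)/2n and q = 1 − p:

- observed heterozygosity Ho = n_ID / n
- expected heterozygosity He = 2pq
- effective allele number Ne = 1 / (p² + q²)
- polymorphism information content PIC = 1 − (p² + q²) − 2p²q²
  (low polymorphism if PIC < 0.25, moderate if 0.25 ≤ PIC < 0.5)
- Hardy–Weinberg equilibrium: the exact conditional test (complete
  enumeration of heterozygote counts given the allele counts, summing the
  probabilities of configurations no more probable than observed), plus a
  1-df chi-square cross-check.

**Association.** Per trait, a fixed-effect least-squares model

    Model I :  Y = μ + G_i + S_j + H_k + f_l + e
    Model II:  Y = μ + G_i + S_j + H_k + f_l + b·(W − W̄) + e

with genotype G (3 levels), sex S, hatch H, family f (7 levels), and — for
body-size traits — individual slaughter weight W centered at the analyzed
subset's mean. Factors enter under sum-to-zero constraints, so genotype
least-squares means are μ + G_g balanced over the other factors. Genotype
significance is a partial (Type-III) F-test; pairwise genotype contrasts are
Bonferroni-tested at α/3 and summarised as compact letters (a, b, ab);
additive and dominance effects follow Falconer: a = (mean_II − mean_DD)/2,
d = mean_ID − (mean_II + mean_DD)/2.

**Expression.** Per sample ΔCT = CT_target − CT_reference, ΔΔCT referenced
to a calibrator group's mean ΔCT, fold change 2^−ΔΔCT, Welch t-tests between
groups.

## Worked example

The published F2 resource population (n = 783) has genotype counts
DD = 23, ID = 423, II = 337:

```python
>>> import indelpop as ip
>>> print(ip.render_locus_summary_table([ip.summarize(ip.F2_PANEL)]))
population  n    freq_DD  freq_ID  freq_II  p_D    p_I    Ho    He    Ne     PIC    P_HWE
F2          783  0.03     0.54     0.43     0.299  0.701  0.54  0.42  1.723  0.332  0.000
```

Reading the row: the deletion allele segregates at 29.9%; more than half the
birds are heterozygous (Ho = 0.54), well above the Hardy–Weinberg
expectation He = 0.42 — the exact test rejects equilibrium (P < 0.001), as
expected in an intercross, whose heterozygosity is inflated by design.
Ne = 1.723 effective alleles and PIC = 0.332 classify the marker as
moderately informative in this population.

Association on a simulated cross (the generator reproduces the 7-family,
two-hatch, both-sexes design):

```python
>>> cfg = ip.SimConfig(seed=7)
>>> cross = ip.simulate_cross(cfg)
>>> phenos = ip.simulate_phenos(cross, cfg, ["BW2"])
>>> res = ip.GenotypeTraitModel.from_tables(phenos, cross.genotypes, "BW2", model="I").fit()
>>> print(res.summary())
Trait BW2 — Model I, n = 783, residual df = 772
Genotype F = 0.472, P = 0.6242
genotype     n      LS mean        SEM  letters
      DD    14    1282.8637    46.3824        a
      ID   329    1259.3388     9.7013        a
      II   440    1270.9354     8.3373        a
additive a = -5.9642 ± 23.7140, dominance d = -17.5607 ± 25.1162
```

Here the 2-week body weight was generated with a small additive effect
(a = 15 g) against a 170 g residual — at that signal-to-noise a single
replicate is, correctly, not significant (P = 0.62); all three genotypes
share letter "a". The estimates bracket the truth within their standard
errors.

The same steps are available from the shell:

```bash
indelpop simulate --seed 7 --out-dir data/
indelpop popgen --panels panels.tsv --out summary.tsv
indelpop assoc --phenotypes data/phenotypes.tsv --genotypes data/genotypes.tsv \
               --traits BW2,CW_carcass,BSL4 --out assoc.tsv
indelpop expr --ct ct.tsv --calibrator ID --out expr.tsv
```

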