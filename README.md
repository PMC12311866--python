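# hlaprofile

Population-level HLA–disease association profiles for immunogenetic
epidemiology.

## The problem

HLA genes are the most polymorphic in the human genome, and allele carriage
strongly shapes individual risk for autoimmune diseases such as type 1
diabetes (T1D). Cohort studies of individual carriage need prohibitively
large samples to cover hundreds of alleles. An alternative is ecological:
across a set of countries, correlate the *population frequency* of each
allele with the *population prevalence* of the disease. Alleles whose
frequency rises where the disease is rarer are presumed protective; alleles
whose frequency rises with prevalence are presumed susceptibility alleles.

`hlaprofile` implements this pipeline for the six classical loci (class I:
A, B, C; class II: DPB1, DQB1, DRB1):

1. read sparse allele × country frequency tables and per-country case
   counts/populations;
2. keep alleles reported in at least `min_countries` countries (default 9);
3. for each allele, compute the Pearson correlation *r* between allele
   frequency and ln(percent prevalence) over the countries reporting it
   (so the per-allele sample size *N* varies), under the empirical
   log-linear model ln *p* = α + β·*f*;
4. Fisher z-transform, *r′* = atanh(*r*) — the signed profile statistic;
5. run the profile-level battery: negative/positive sign splits with
   one-sample proportion z-tests, a one-way ANOVA of *r′* by *N* (sample-size
   bias check) with pairwise group-mean comparisons, a nested class/gene
   ANOVA, and pooled-variance t-tests comparing |*r′*| between the
   protective and susceptibility groups.

A seed-stable synthetic-data generator (Dirichlet frequency compositions
per locus and country, log-linear prevalence, record-level missingness)
makes every stage testable end to end, and the package ships a 127-allele
T1D reference profile over 14 Continental Western European countries as a
text fixture.

## Worked example

```bash
python analysis/01_reference_profile_stats.py
```

prints

```
profile: 127 alleles (57 protective / 70 susceptibility)
  sign split vs 50%: z = 1.154, p = 0.249  -> no significant excess of either sign
  class I vs II membership: z = 0.976, p = 0.329
  r' by sample size N: F(5,121) = 1.184, p = 0.32 -> no bias from varying country coverage
  strength |r'| negative vs positive: min p = 0.077 over 8 class/gene comparisons (all > 0.05)
  top-5 susceptibility: A*02:05, DRB1*12:01, A*36:01, A*33:01, DQB1*03:02
  top-5 protective: A*01:01, C*07:04, C*06:02, DPB1*13:01, A*26:01
```

Reading: of the 127 alleles, 70 correlate positively with T1D prevalence
and 57 negatively — a split consistent with a 50/50 null (z = 1.154,
p = 0.249), so neither direction dominates the profile as a whole. The
varying per-allele country coverage (N = 9–14) does not bias *r′*
(F(5,121) = 1.184). The extremes of the profile are the interesting part:
DQB1\*03:02 (a well-established T1D risk allele) ranks among the strongest
susceptibility signals, and A\*01:01 is the strongest protective one.

The same pipeline runs on your own data from the shell:

```bash
hlaprofile profile --freq freq.csv --prev prev.csv --min-countries 9 --out profile.tsv
hlaprofile stats --profile profile.tsv --report report.json
hlaprofile simulate --config cfg.yaml --reps 100 --out-dir sim/
```

`analysis/02_synthetic_recovery.py` and `analysis/03_null_calibration.py`
validate the method on synthetic data: with noiseless prevalence and an
isolated effect allele the sign of *r′* recovers the generating slope's
sign in every repetition, recovery degrades monotonically as prevalence
noise grows, and under an all-null generator the sign-split test rejects
at close to its nominal 5% level.

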