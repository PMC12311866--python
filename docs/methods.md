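# Methods

## The profile statistic

For allele *a*, let *f₍a,c₎* be its population frequency in country *c* and
*p₍c₎* the country's disease prevalence expressed as a percentage
(100 × cases / population). Over the countries where both quantities are
known, the package computes the Pearson correlation

r₍a₎ = corr( f₍a,·₎ , ln p₍·₎ )

and the Fisher z-transform r′₍a₎ = atanh(r₍a₎). The log transform of
prevalence reflects the empirical pattern that prevalence varies
exponentially with allele frequency, so its logarithm is linear in
frequency; the correlation itself is invariant to the ×100 percent scaling,
which affects reporting only. atanh is variance-stabilizing and
approximately normalizes the distribution of correlations, which is what
licenses the downstream ANOVAs and t-tests on r′. The sign of r′ encodes
direction (negative = protective, positive = susceptibility); |r′| encodes
strength.

### Intersection rule and coverage filter

Allele-frequency reporting is sparse: each allele appears in only a subset
of countries. Each correlation therefore uses exactly the countries that
report that allele *and* have a prevalence value, so the per-allele sample
size N varies across the profile (9–14 in the reference profile, against
14 available prevalences). Alleles with fewer than `min_countries`
(default 9) usable countries are removed before correlation; the default
is deliberately conservative — correlations from fewer countries are
estimable but volatile. The one-way ANOVA of r′ by N, with pairwise
group-mean comparisons, is the built-in check that this varying N does not
bias the profile.

### Degenerate inputs

Correlations need ≥ 3 pairs and non-constant coordinates; |r| = 1 (which
happens on noiseless synthetic data) makes r′ infinite. These cases raise
a typed error rather than emitting ±inf, because a single infinite r′
would poison every downstream mean, ANOVA and t-test. Callers that expect
perfect correlations (the simulation harness) pass `clamp=True`, which
clips |r| at 1 − 1e−12 before transforming. `build_profile` never drops an
allele silently: un-analyzable alleles are listed with reasons in the
profile metadata.

## The inference battery

* **Sign splits.** Counts of negative/positive r′ (exact zeros tracked
  separately) are tested against a 50% null with the normal-approximation
  one-sample proportion test, z = (k − n/2)/√(n/4), *without* continuity
  correction, two-sided. This specific form is used because it is the z
  statistic that mainstream statistics packages print alongside a
  "binomial test" of a proportion; an exact two-sided binomial p
  (minimum-likelihood method) is provided as a labelled alternative and
  cross-checked against full enumeration in the tests.
* **Wald two-proportion test.** Implemented in the standard unpooled form
  for comparing independent proportions. Note that the negative/positive
  shares of one profile are complementary, not independent; for that
  question the one-sample test above is the reproduction path, and the
  caveat is documented on the function.
* **Nested class/gene ANOVA.** Gene (6 levels) is nested in class (2
  levels), so the sums of squares partition sequentially: SS(class) from
  the class-only fit, SS(gene within class) as the increment explained by
  the gene fit, residual from the gene fit — df 1, 4, n − 6. The error
  term for the class effect is genuinely ambiguous in a mixed reading
  (fixed class, random gene): the default tests class over the residual
  mean square, and `class_error_term="gene"` switches to the
  gene-within-class mean square.
* **Strength t-tests.** Within each class and each gene, |r′| of the
  protective group is compared with the susceptibility group by a
  pooled-variance two-sided t-test (the classic "independent samples
  t-test"); an unequal-variance option is not the default because the
  pooled form is the one conventionally reported. Cells with fewer than
  two alleles of either sign are skipped with a warning.
* **Multiplicity.** Pairwise group-mean comparisons after the sample-size
  ANOVA are Bonferroni-adjusted by default (conservative; configurable to
  `none`). No multiple-testing correction is applied across the per-allele
  correlations themselves — the profile is an estimation object, not a
  set of per-allele hypothesis tests.

## The synthetic-data generator

`SyntheticConfig` defaults encode the study conditions: 14 countries, 127
alleles over the six loci (A 20, B 36, C 13, DPB1 15, DQB1 14, DRB1 29),
missingness 0.2 (mean coverage 14 × 0.8 = 11.2 countries, spanning the
observed 9–14 range once binomial spread is added), baseline prevalence
0.3% (α = ln 0.3), prevalence noise σ = 0.15 on the ln scale (≈ ±15%
country-to-country prevalence variation, a realistic registry-level
spread), and Dirichlet concentration 50 (allele-frequency compositions
similar across countries but visibly heterogeneous, as real European HLA
data are).

Frequencies: per locus, a mean composition is drawn once from a flat
Dirichlet, rescaled to leave a `hidden_mass` (default 0.15) share for a
never-reported rare tail; each country then draws its composition from
Dirichlet(concentration × mean). The hidden tail matters: if the observed
alleles of a locus summed exactly to one in every country, their sample
covariances with any prevalence vector would sum to exactly zero, making
correlation signs within a locus deterministically anticorrelated — an
artifact real data (where reported alleles are a subset of all alleles) do
not show. As concentration → ∞ the between-country variance vanishes,
which the tests exploit as a law-of-large-numbers check.

Prevalence: ln p₍c₎ = α + Σₐ βₐ f₍a,c₎ + ε₍c₎ with ε ~ N(0, σ²), additive
on the log scale with no interactions. Percent prevalence is converted to
an integer case count against a nominal population of 10⁷ (rounding
perturbs ln p by < 10⁻⁵; a floor of one case keeps log prevalence finite
in deep noise tails). Prevalence is generated from the *complete*
frequency table before missingness, since a country's disease burden does
not depend on which alleles happen to be reported there. Effect-map names
must exist in the generated table; unknown names raise instead of silently
contributing nothing. All stages draw from named substreams of a single
integer seed.

### What the generator does and does not emulate

It reproduces the data's statistical skeleton: compositional per-locus
frequencies, between-country heterogeneity, record-level missingness, and
log-linear prevalence. It does not model linkage disequilibrium or
haplotype structure between loci, geographic autocorrelation between
neighbouring countries, reporting biases of frequency databases
(sample-size-weighted national aggregation), or demographic differences
among the actual countries. Passing recovery tests therefore show the
*pipeline* is correct and calibrated under its own assumptions — not that
real-world profiles are unconfounded; ecological correlations never
establish individual-level risk by themselves.

## Validation results computed by the test suite

* Noiseless limit: with σ = 0, no missingness and one isolated nonzero
  slope, the estimated correlation is exactly ±1 and the sign-recovery
  rate is 1.0 in every repetition. With several simultaneous effect
  alleles this exactness is lost (each allele's correlation picks up the
  other effects), which is why the recovery experiments use isolated
  effects.
* Null calibration: under an all-null generator, r′ across alleles is
  centered at zero and the sign-split test rejects at ≈ 3–5% over 500
  repetitions — near nominal, slightly conservative because compositional
  frequencies make signs within a locus negatively dependent while the
  test assumes independence.
* The packaged reference profile reproduces its published battery: sign
  splits 57/70 (z = 1.154, p = 0.249), class splits 31/38 and 26/32,
  class membership z = 0.976, ANOVA F(5,121) = 1.185 within the 3-decimal
  rounding of the stored r′ values, all strength t-tests p > 0.05, and
  the published top-5 rankings in both directions.

## Numerical and design choices

* The reference profile stores r′ exactly as printed (3 decimals); r is
  recovered as tanh(r′). Statistics over the fixture are therefore
  compared at tolerances matching that precision (e.g. ±0.01 on the
  ANOVA F).
* Profile TSV uses UTF-8, tab separation, `.` decimals and `repr`-exact
  floats; reading uses round-trip float parsing, so write→read is
  bit-exact.
* Ranking ties break by canonical allele order (locus A, B, C, DPB1,
  DQB1, DRB1, then numeric fields).
* Only the six classical loci are accepted; other loci raise a parse
  error rather than being silently classed. Higher-resolution allele
  names truncate to two fields with a warning. Country keys are
  case-insensitive with a small alias map for common abbreviations.
* Problem sizes in the default test run and the reproduction script —
  500 null repetitions, 10–30 repetitions for recovery curves — were
  chosen so Monte-Carlo error is well inside the asserted bands.

## Known limitations

* The country-level inputs behind the reference profile (per-country
  allele frequencies and prevalence values) are not distributed with the
  package, so per-allele correlations of that profile cannot be
  recomputed from raw data here; the profile itself is the fixture.
* The coverage threshold (≥ 9 countries) is a judgment call inherited
  from the study design; the filter exposes it as a parameter.
* The Wald two-proportion function reports the test exactly as named even
  where its independence assumption is questionable (complementary
  splits); it logs the caveat rather than second-guessing the caller.
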