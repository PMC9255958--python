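# Methods

## The problem and the model

A postzygotic mutation restricted to a man's germline ("gonadal
mosaicism") is carried by a fraction *f* of his sperm. Since sperm are
haploid, deep sequencing of bulk sperm DNA measures *f* directly as
the allelic fraction (AF) at the site, and *f* is also the probability
that any single fertilisation transmits the mutation. Given a set of
mosaic variants with sperm AFs `p_1 … p_k` genotyped across `n`
blastocysts, the total number of transmission events under the
assumption that variants transmit independently is a Poisson-binomial
random variable with

```
E[T]   = Σ_i n_i p_i          Var[T] = Σ_i n_i p_i (1 − p_i)
```

where `n_i` is the number of blastocysts with genotyping data for
variant *i* (cells without data are excluded from both the observed
total and the expectation, so numerator and denominator always match).
The package estimates this distribution by Monte Carlo (default
10,000 draws; each draw is a sum of `Binomial(n_i, p_i)` variables)
and summarises it the way the field reports it: a Gaussian
`A·exp(−(x−μ)²/2σ²)` is least-squares fitted to the unit-bin histogram
of draw totals (`scipy.optimize.curve_fit`), and the 95% CI is
`μ ± 1.96 σ`. The exact Poisson-binomial mean and SD are always
computed alongside as an analytic cross-check; tests require the
fitted mean to sit within 0.5 of the exact mean whenever the exact
mean is ≥ 2 (the fit degrades for very small means, where the
histogram is dominated by a spike at zero).

Independence is knowingly a simplification: mutations that arise in
the same spermatogonial lineage co-transmit, which inflates the
variance of `T` without changing its mean and concentrates events in
few blastocysts. The package does not correct the expectation for
this; instead it (a) exposes the evenness permutation test that
detects the signature, and (b) lets the synthetic generator produce
both regimes so the consequence of the violation can be measured.

For trio offspring the machinery is identical with children as units;
families are pooled by concatenating the per-family `(p_i, n_i)`
pairs, so the pooled exact mean is the sum of per-family means.

Sex-chromosome variants would need `p = 2·AF` (only half of sperm
carry a given sex chromosome); the convention is implemented with a
warning but is not exercised by the generator, which draws autosomal
sites only.

## Genotyping rules

All intervals are exact Clopper–Pearson binomial CIs, computed from
beta quantiles: `lower = B(α/2; k, n−k+1)`, `upper = B(1−α/2; k+1,
n−k)`, with the endpoints pinned to 0 (k = 0) and 1 (k = n).

* **Population threshold.** The noise ceiling is the empirical 95th
  percentile of AFs observed at reference-homozygous control-SNP
  sites, pooled across the cohort's non-blastocyst samples (donor
  tissues where the donor is WGS ref-hom, and unrelated controls).
  The 'higher' quantile method is used so the statistic is an actually
  observed AF and is exactly invariant under duplication of the input
  set. A pooled (rather than per-donor) threshold reflects that noise
  is a property of the assay, not the donor.
* **Tissue mosaic call** (three criteria, all required): depth ≥ 100×;
  variant CI lower bound strictly above `max(threshold, max control CI
  upper bound)`; and at least one control's CI lower bound at or below
  the threshold. Ties reject — "does not overlap" is implemented
  strictly, which is the conservative direction for mosaic calling.
  Sites with no control coverage are reported as uncallable, a state
  distinct from negative, and are excluded from denominators.
* **Classification.** Sperm and somatic (blood/saliva) flags combine
  to sperm_only / shared / soma_only / rejected; the gonadal
  (transmissible) set is sperm_only ∪ shared. soma_only variants
  (e.g. clonal hematopoiesis) never enter the transmission matrix.
* **SNP genotypes** in tissues: AF < 0.2 ref-hom, [0.2, 0.8) het,
  ≥ 0.8 alt-hom, requiring depth ≥ 100×; both boundaries closed on
  the left.
* **Blastocyst calls**: depth < 20× is no-data. For mosaic variants a
  blastocyst is positive only when the CI lower bound exceeds 0.05 AF;
  for SNPs the point AF > 0.05 suffices (het and hom not
  distinguished). The stricter mosaic rule is what the false-positive
  calibration measures.
* **Blastocyst QC**: a blastocyst with < 10% of panel positions at
  ≥ 20× is dropped from every downstream stage; exactly 10% passes.

## Calibration

The false-negative rate is the fraction of (parental alt-hom SNP,
blastocyst) pairs with data called negative — those SNPs must be
present in every blastocyst, so every negative is an error (dominated
by WGA allelic dropout). Parental genotypes come from the package's
own tissue SNP genotyper (somatic sample preferred, sperm as
fallback), keeping the calibration self-contained; WGS annotations in
the panel serve as a cross-check. Heterozygous parental SNPs provide
a Mendelian control (transmission ≈ 0.5 × (1 − FN)). The
false-positive rate is the fraction of cross-donor (gonadal variant of
donor X, QC-passing blastocyst of donor Y ≠ X) pairs with data called
positive. The denominators count pairs, the natural unit of "of those
analyzed"; no-data pairs are excluded from both sides. Rates are
reported, never used to adjust transmission counts.

## Evenness permutation test

The T observed transmission events are reassigned independently and
uniformly to the B QC-passing blastocysts (one multinomial draw per
permutation, 10,000 permutations). An event is one positive cell: a
variant transmitted to two blastocysts contributes two events. The
statistic is the maximum per-blastocyst count or the population SD
(ddof = 0; the p-value is identical under either ddof convention since
observed and permuted values share the scale factor). The p-value is
the plain tail fraction `#{permuted ≥ observed}/n_perm`; a `plus_one`
flag gives the (k+1)/(n+1) correction. Tail membership is decided with
a 1e-9 tolerance so permutations that reproduce the observed count
pattern are always counted as ties (the SD of an identical pattern can
differ in the last ulp). T = 0 returns a flagged degenerate result
with p = 1.

## Synthetic cohort generator

The generator emulates the structure of a three-donor IVF mosaicism
study and is itself first-class, tested code.

* **Lineage tree.** Each donor gets a complete binary tree of depth 8
  (256 leaves) whose leaf weights — the sperm-pool shares of the
  progenitor clades — are Dirichlet(1) distributed. A variant sits on
  one node and is carried by all sperm below it, so its true sperm AF
  is half the subtree weight (meiosis). Target AFs are drawn from the
  configured law and mapped to nodes by a Gaussian kernel on log-AF
  distance (width 0.3), which concentrates similar-AF variants on
  shared nodes and yields co-segregation. A fertilisation samples one
  leaf by weight and transmits each variant on the leaf's root path
  independently with probability 1/2, making the marginal transmission
  probability exactly the true AF. A flag switches to fully
  independent Bernoulli(AF) transmission (used by the coverage
  checks). Variants whose node lies at depth ≤ 2 predate the
  soma/germline split and are labelled shared (also present in soma at
  the same cell fraction); deeper nodes give sperm-only variants —
  reproducing, without hard-coding it, the empirical pattern that
  shared variants have higher AFs.
* **Defaults are the study conditions**: 3 donors; 12/13/30 gonadal
  variants; AFs log-uniform on [0.003, 0.25] (a long-tailed law
  spanning the observed range; mean ≈ 0.056); 15/3/3 soma-only
  variants (the first donor carries the clonal-hematopoiesis excess);
  120 control SNPs, half "rare" (het in exactly one donor, ref
  elsewhere) and half "common" (Hardy–Weinberg genotypes at alt-allele
  frequency 0.3, supplying the alt-hom parents the FN calibration
  needs); 10/8/14 blastocysts with 2 of the second donor's at 2% of
  normal coverage (they fail the 10% QC rule); negative-binomial depth
  (dispersion 5) with mean 5000× in tissues — ultra-deep amplicon
  coverage, enough to separate AF 0.003 from a ~0.001 noise ceiling
  about half the time, which is the realistic margin — and 100× in
  blastocysts; sequencing error 5e-4 per read.
* **WGA model.** A carrier blastocyst (always heterozygous here)
  drops the mutant allele with probability 0.06; otherwise its allele
  balance is Beta(5, 5) (frequent moderate imbalance, SD ≈ 0.15) and
  alt reads are binomial at that balance. Non-carriers show alt reads
  at the error rate. The recovered FN rate is therefore the dropout
  probability plus a small imbalance tail.
* **Mothers are treated as reference-homozygous** at all panel sites:
  egg-donor genomes are not simulated. This only affects common-SNP
  blastocyst genotypes (a child can inherit a maternal alt allele in
  reality); the FN calibration is immune because an alt-hom father
  makes the child a carrier regardless of the mother, and the het
  Mendelian rate stays at 1/2.
* **Determinism.** One seed sequence per cohort, spawned into
  per-donor substreams; identical seeds give byte-identical tables.

What passing tests on these cohorts do **not** show about real data:
real amplicon panels have locus-specific amplification bias and error
profiles (here noise is i.i.d. binomial), real lineage trees are not
balanced binary trees with Dirichlet clade sizes (the tree is a
minimal generator of qualitative co-segregation, not a calibrated
developmental model), indels and multi-allelic sites are absent, and
blastocyst aneuploidy/contamination are not modelled.

## Problem sizes used in the checks

The replicate-based checks run at deliberately small scale chosen as
the smallest sizes at which the targeted effects are well resolved:
the CI-coverage check uses 200 single-donor replicate cohorts
(12 variants × 10 blastocysts, 3,000 Monte Carlo draws each); the
co-segregation mechanism check uses 50 paired cohorts (30 variants at
AF 0.2 on a depth-2 tree — four progenitor clades — versus matched
independent cohorts); dropout recovery uses ~40 alt-hom SNPs × 40
blastocysts per grid point. The study-scale cohort runs at its natural
size.

## Numerical choices

* Clopper–Pearson bounds come from `scipy.stats.beta.ppf`; the test
  suite checks 1,000 random cases against statsmodels'
  `proportion_confint(method="beta")` at 1e-9.
* The Gaussian histogram fit initialises at the sample moments and
  falls back to them if the optimiser fails (pathological histograms,
  e.g. a single occupied bin); a degenerate all-equal draw vector
  short-circuits to (value, 0).
* Quantiles use the 'higher' method (see population threshold).
* Permutation tie handling uses a 1e-9 tolerance (see above).
* All RNG is `numpy.random.default_rng`; every stochastic API takes an
  explicit seed and results are reproducible bit-for-bit.

## Known limitations

* The expectation model assumes independent transmission; under
  strong lineage co-segregation its CI under-covers (this is
  demonstrated, not corrected).
* The population threshold is a single pooled scalar; a per-donor or
  per-locus threshold would adapt to donor-specific artefacts at the
  cost of fewer reference-homozygous observations each.
* FN/FP rates are global, not locus-specific; loci with systematic
  amplification bias are not down-weighted.
* The Gaussian-fit CI can include negative totals for small means;
  the verdict logic is unaffected (observed totals are ≥ 0).
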