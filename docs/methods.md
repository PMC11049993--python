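# Methods

## Count abstraction

Every tumor-informed mutation is represented by four integers at its locus:
variant-supporting consensus reads on the forward and reverse strand, and
non-supporting reads on each strand.  Strand is the orientation of the
original fragment as reported upstream; the package takes count tables as
given and only re-derives strand in the optional BAM extractor.  Multi-base
events (MNVs, and phased groups when no dedicated co-support count is
available) use the mean of per-position counts across the spanned loci,
rounded half away from zero so the likelihood sees integers.  Phased
variants may alternatively carry one dedicated count vector (fragments
supporting *all* constituent variants) as an extra row of the count table;
when present it takes precedence.  Catalogs use VCF coordinates (1-based);
panel intervals are 0-based half-open.

## Error model

The panel of normals is pooled by simple summation per (position, allele,
strand); the error rate is μ = (alt + c) / (total + 2c) with pseudocount
c = 0.5 (configurable).  Per-strand rates are the default because the Bayes
factor is strand-aware; a flag pools strands.  Overdispersion ρ is the
classical weighted method-of-moments (ANOVA-type) intraclass-correlation
estimate across PON samples, computed on strand-combined counts (one
biological replicate per donor) and truncated to [1e-6, 0.1].  Degenerate
loci (all-zero alt, fewer than two covered samples) collapse to the lower
bound.  The truncation range and pseudocount are package choices — stable
at low depth and in the style of the beta-binomial PON caller family —
not values taken from any measured dataset.

The context profile collapses the 12 strand-specific substitutions to 96
pyrimidine-centered trinucleotide classes (e.g. `A(C>T)G`); exceedance
summaries (fraction of sites above 0.001% / 0.01% error) are reported per
substitution, plus single-base insertion and deletion alleles.

## Bayes factor

H0: alt counts on each strand are beta-binomial noise at the pooled PON
rate (parameterized by mean p and intraclass correlation ρ, i.e. shapes
a = p·t, b = (1−p)·t with t = (1−ρ)/ρ).  H1: an additional variant
fraction ν, common to both strands ("AND" model), marginalized over a
uniform prior on (0, 1).  With prior odds 1 the posterior odds equal the
Bayes factor; larger m = more variant evidence.  An "OR" variant (mixture
of single-strand alternatives) exists for strand-artifact diagnostics.
Zero depth on either strand yields log m = 0 (uninformative).

Numerics: the marginal is a trapezoid sum over a log-spaced ν grid on
(1e-8, 1] — low allele fractions dominate and log spacing keeps the
quadrature accurate near zero.  The scalar scorer uses 2001 grid points.
The vectorized whole-panel scan uses 501 points: the difference to the
2001-point value is a constant ≈ +2.1e-4 per mutation for allele fractions
below ~50% (it cancels exactly in the rank statistic because observed and
random catalogs share the grid), and only grows where log m is already in
the hundreds.  Binomial coefficients are dropped throughout (they cancel
in every ratio).  The scan exploits that most panel sites have zero alt
reads (two `gammaln` calls per grid point) and handles small positive
counts by log-product corrections; a panel-wide scan of ~46,000
position-substitution pairs takes a few seconds.

## Rank score and calling

The integrated score is log s = Σ log m over the retained (non-blacklisted,
non-CHIP) catalog.  K random catalogs of the same size are drawn uniformly
*without replacement* from all modelable position-substitution pairs and
scored against the same sample's observed counts (each random catalog is a
sum of precomputed scan terms, which is what makes K = 100,000 cheap).
S = 1 − (r+1)/(K+1) with r the number of random scores *strictly* greater
than s; ties count as not larger, keeping S conservative.  A sample is
positive iff S > α strictly.

Calibration note: for catalogs made of substitutions the observed catalog
is exchangeable with the random catalogs, so S is uniform under the null —
the package's null-calibration test checks exactly this.  Catalogs
containing INDELs/MNVs are *conservative* under the null (indel error
rates sit below the substitution pool, so their null evidence is
stochastically smaller than random substitution catalogs); this biases
null S downward, never upward, and cancels in threshold training because
training and held-out negatives are generated from the same catalog pool.

## Threshold training

Per Monte-Carlo simulation (default 25): 100 patient scores (sampled
without replacement; with replacement plus a warning if fewer patients are
available) are positives, and 100 in-silico negatives pair a random
healthy control with a frequency-weighted catalog drawn without
replacement from the pooled cohort catalog, sized by the empirical
catalog-size distribution.  The per-simulation threshold is the k-th
smallest negative score with k = ceil((n+1)(1−FPR)) (k = 96 for n = 100 at
5% FPR): by exchangeability a fresh negative falls at or below the k-th of
n order statistics with probability k/(n+1) ≈ 95.0%, making the held-out
specificity unbiased without any distributional assumption.  (The naive
"smallest score with ≤5% of negatives above it" is the 95th order
statistic, whose expected specificity is 95/101 ≈ 94.1% — measurably
miscalibrated.)  α is the mean of the 25 thresholds, per the training
procedure; ROC AUC is reported per simulation (scikit-learn, midrank
ties).  Specificity validation repeats the negative generation on
independent controls (25 repetitions × 100 draws) and compares repetition
means to the training specificities with a Welch t-test (the unequal-
variance form; only "t-test" is prescribed).

The reference threshold α = 0.9797 from the original patient cohort is
kept as a documented constant; it is a property of that cohort's data and
is not recomputable from synthetic inputs.

## Limit of detection

Per-mutation LOD at specificity σ and power π: the count threshold c* is
the smallest integer with P(X ≥ c* | BB(d, μ, ρ)) ≤ 1−σ, and the LOD is
the smallest f (bisection to 1e-7) with P(X ≥ c* | BB(d, μ+f, ρ)) ≥ π.
Power defaults to 0.95 (the study states only the specificity, 0.99);
both are configurable.  μ = 0 makes any alt read decisive (c* = 1) and
ρ ≤ 1e-9 switches to exact binomial tails, which is also the closed-form
oracle used in tests.  When no c* exists below the depth the LOD is
reported as undefined.

Sample-level LOD: Monte-Carlo geometric bisection over the cAF.  Each
candidate evaluates the positive-call fraction over (default) 200 signal
replicates; to avoid re-simulating a full panel per replicate, a pool of
25 background panel profiles (with their panel scans and null rank
distributions) is recycled and only the signal at the catalog loci is
redrawn per replicate — random catalogs essentially never overlap the few
catalog loci, so the null distributions are unaffected.  Non-convergence
reports the widest bracketing interval.

The in-silico detection study draws per-mutation alt counts as
Poisson(depth × cAF) at fixed depth 20,000 (the limiting form of
depth-many Bernoulli draws at rate cAF) and scores each replicate twice:
full catalog and SNVs only.  The dilution benchmark spikes a 95-mutation
compound foreground at serially diluted AFs, bins foreground mutations by
*observed* AF, and reports per-bin ROC / precision-recall AUC of
foreground Bayes factors against all other panel substitutions, with a
normal-theory 95% CI over 20 repetitions, plus the Pearson correlation
between spiked and observed AFs (computed on square-root-transformed AFs
to keep the decades comparable).

## Synthetic cohorts

The generator emulates deep UMI-consensus targeted sequencing counts; it
does not model library conversion, fragment sizes, or read-level errors.

- Panel: iid sequence at a requested GC fraction (default 0.5), split into
  ~12 regions; flanking bases give every position a trinucleotide context.
- Error rates: per site-substitution, log10 rates are normal per
  substitution group — noisy (C>T, G>A, G>T: mean −4.23, sd 0.28, with a
  +0.35 log10 boost for N(C>T)G-type contexts and a compensating mean
  shift), intermediate (−5.0, 0.5), quiet (T>G, A>C, C>G, G>C: −5.39,
  0.5), deletions (−5.8), insertions (−6.4); per-site dispersion is
  log-normal around ρ ≈ 1e-3.  The noisy-group parameters were calibrated
  so the *estimated* rates of a default 46-sample PON at 9,086× depth show
  the target profile (>90% of C/G sites above 0.001%, ≈25% above 0.01%);
  because pooled-rate estimation noise blurs the site-rate distribution,
  the generating parameters are not the naive normal-quantile solution.
- Counts: per sample, per-position strand depths are Poisson around half
  the sample depth times a per-site capture-efficiency factor; alt counts
  are beta-binomial, independently per strand.  Per-sample mean depths are
  log-normal around a median of 9,086×.
- Catalogs: sizes from an empirical distribution with median 3, IQR 2
  (minimum 1); carrier probabilities 48% deletion, 22% insertion, 9% MNV;
  remaining slots SNVs at uniform panel positions.
- Plasma: background plus binomial signal at the sample cAF (default
  log-uniform in [0.01%, 1%]), split evenly across strands and added on
  top of background without displacement — negligible distortion at
  cAF ≪ 1.  PBMC: background plus a CHIP spike-in with prevalence 3.4%
  and AF uniform in (0.1%, 1%).

What the generator does not emulate — and what passing tests therefore do
not establish about real data: sample-to-sample noise-structure shifts
beyond depth scaling (the very deviation the rank score S exists to
absorb), correlated errors across neighboring sites, mapping and phasing
artifacts, germline contamination, and real CHIP mutational spectra.

## Problem sizes

Tests and the acceptance script scale the panel and Monte-Carlo counts to
desk size as the package's own choice of study conditions: threshold
training/validation runs use a 1,500–3,000 bp panel with K = 4,000–10,000
random catalogs (S resolution ≤ 2.5e-4, far below the thresholds
involved); the low-AF discrimination benchmark uses the full 15,465 bp
default panel; the null-calibration study uses 500 replicate samples on an
800 bp panel.  Cohort sizes (46 PON donors, 126 patients, 37 + 24
controls, 25 simulations × 100 + 100 labels) follow the study design.

## Known limitations

- The Bayes factor is structurally faithful (AND model, shared-ν
  marginalization, beta-binomial strands) but not bit-compatible with the
  original R implementation it descends from; tests pin it to an
  independent quadrature oracle instead.
- The blacklist recurrence rule (AF > 0.1% in ≥ 20% of healthy samples)
  and the CHIP posterior cutoff (0.95 at prior odds 1) are configurable
  package defaults; the original criteria are not public.
- Phased-variant co-support counting from reads is not implemented; phased
  events enter through count tables or the composite per-locus mean.
- The UMI consensus collapser is a minimal majority-rule implementation
  (families of ≥3 by UMI/start/end/strand, ties to reference) intended for
  testing the count extractor, not a production deduplicator.
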