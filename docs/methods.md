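# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind the package, and what the synthetic validation does and
does not establish.

## Site filtering

Filters run in a fixed cascade — INFO hard filters, biallelic restriction,
missingness, minor-allele frequency, Hardy–Weinberg — and each removed site
is attributed to the *first* rule it failed, so the report's counts plus the
kept count always equal the input count. All inequalities are strict in the
conventional orientation: QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0 fail a site; missingness must be
< 10% and MAF > 0.05 to keep one, so a site at exactly 10% missingness or
MAF exactly 0.05 is excluded. A missing INFO annotation never fails a site
(the variant-caller convention for sites where the annotation is
uncomputable). Spanning-deletion `*` alleles count as extra alleles and are
removed by the biallelic rule.

The Hardy–Weinberg test is the exact conditional (Levene) test: given the
allele counts, the probability of each possible heterozygote count is
P(h) = n! / (x_A! h! x_B!) · 2^h · n_A! n_B! / (2n)!, and the two-sided
p-value sums all outcomes no more probable than the observed one (no mid-p).
Distributions are cached by (n, n_A), making the per-site loop cheap at
cohort scale. Sites with p < 0.001 are removed. The test pools all samples
by default — one genome-wide SNP set feeds every downstream analysis — with
a per-subset option for users who prefer within-population testing; pooled
testing over differentiated populations also removes Wahlund-effect sites,
which is conservative for diversity estimates.

Genotype-quality masking (GQ ≥ 30) is a separate, genotype-level stage
applied only before the distance/PCA computations, where per-genotype
confidence matters most; it sets failing genotypes to missing rather than
dropping sites.

## Windowed diversity and differentiation

Windows start at multiples of the step (default 5,000/2,500 bp), truncated
at the chromosome end. Per-site diversity uses the unbiased estimator
2j(n−j)/(n(n−1)) with n the called allele copies at that site (n varies
with missingness; sites with fewer than two called copies contribute
nothing). Window π divides the summed site values by the window *span*, so
invariant and uncalled positions count as zero diversity — the convention
of the standard windowed-π tools; a per-variant-site alternative is a flag
away. Windows with no variant are reported as NaN and excluded from
medians, quantiles and rank-sum comparisons.

The F<sub>ST</sub> estimator is Weir & Cockerham (1984) for r = 2
populations, computed from per-population called-diploid counts n_i, allele
frequencies p_i and observed heterozygote fractions h_i through n̄, n_c,
p̄, s² and h̄. Sites are skipped when a population has no called genotype,
when n̄ ≤ 1, or when n_c ≤ 0 (all corrections then being undefined).
Window values are ratio-of-sums Σa/Σ(a+b+c) ("weighted"); windows whose
denominator is non-positive are excluded. Negative estimates are retained:
clamping at zero would bias the genome-wide distribution and therefore the
outlier threshold.

Distribution comparisons use the two-sided Mann–Whitney test as implemented
in scipy with automatic method selection: exact enumeration for small
untied samples, tie-corrected normal approximation otherwise.

## Sweep scan

The π ratio is ρ = (π_ref + ε)/(π_target + ε) with ε = 10⁻⁵ — below any
plausible per-bp diversity, so it only tames empty-window zeros without
reordering informative windows. The orientation puts the *target*
population (the one suspected of having swept) in the denominator, so
diversity loss inflates ρ; the direction is a parameter because a scan is
often run both ways. The outlier threshold is the ⌈q·W⌉-th order statistic
of the W usable windows (q = 0.95) with a strict inequality — reproducible
and tie-safe: a constant statistic flags nothing, and the flagged fraction
never exceeds 1−q. Windows missing either statistic are excluded from both
tails and from the intersection. Flagged windows that overlap or touch
book-ended are merged into maximal regions (no merge rule is canonical;
book-ended merging is the least surprising for half-open tiling windows),
with peak statistics the maxima over members. Gene overlap requires ≥ 1 bp
in half-open arithmetic. Enrichment is the upper-tail hypergeometric
P(X ≥ k) on user-supplied gene→category maps with Benjamini–Hochberg FDR
across categories.

## Sex-chromosome classification

Per 1-kb window, female and male group mean depths and
log2((F̄+δ)/(M̄+δ)). δ defaults to 0.1× the overall group-mean depth
(resolved at run time; an absolute override exists) — large enough to keep
zero-coverage windows finite, small enough (≲2 at typical depth) not to
move autosomal or X ratios. Windows with male mean depth below 1× are
unusable (their ratio is pseudocount-dominated, and the Y in females has no
signal at all). A chromosome needs ≥ 10 usable windows; its call comes from
the *median* window ratio — robust to isolated mismapping windows — with
bands |m| ≤ 0.35 → autosome, |m−1| ≤ 0.35 → X, m ≤ −1 → Y, else
undetermined. The ±0.35 half-width splits the gap between the expected
modes 0 and 1 symmetrically and tolerates Poisson noise at ≥10× depth;
both bands are parameters.

## Structure

Distance is 1 − IBS allele sharing over pairwise-complete sites: for a pair
with m sites called in both, share = Σ(2−|g_i−g_j|)/(2m). Neighbor joining
follows Saitou–Nei with the Q-criterion; ties break on the smallest index
pair in current node order, negative branch estimates are clamped to zero
for output with the raw value retained (patristic-distance checks use raw
lengths), and the result is an unrooted tree serialized with a
trifurcating root. PCA uses the Patterson normalization (center 2p̂, scale
√(2p̂(1−p̂)), monomorphic sites dropped, missing dosages mean-imputed) and
an eigendecomposition of the sample covariance; coordinates are
eigenvectors scaled by √eigenvalue, with arbitrary sign.

## Synthetic-data generator

The generator emulates exactly the structure the estimators assume:

- **Genotypes.** Per site, ancestral frequency ~ Uniform(0.05, 0.95); each
  population draws its frequency from the Balding–Nichols Beta with
  parameter F (F = 0 returns the ancestral frequency); individuals draw
  Binomial(2, p) dosages; admixed individuals draw each of their two gene
  copies from source k with probability q_k. Site positions are uniform at
  a configurable density (default 0.01/bp). Balding–Nichols was chosen over
  a coalescent simulator because it is parameterized directly by the
  differentiation level the windowed estimator should recover and is fast
  at desk scale. **No linkage is modeled** — windows aggregate independent
  sites. That is adequate here because every implemented statistic is
  site-decomposable, but it means passing tests say nothing about
  haplotype-based statistics or about the autocorrelation of window values
  along real chromosomes.
- **Sweeps.** p′ = (1−α)p + α·1[p ≥ 0.5] in the target population inside
  the swept interval: expected heterozygosity never increases in α, so the
  injected signal is a clean diversity loss plus frequency displacement,
  without the hitchhiking haplotype structure of a real sweep.
- **Coverage.** Depth ~ Poisson(d · c_s · G) per 1-kb window, with d the
  mean depth (default 17×, a typical resequencing depth), c_s a per-sample
  lognormal library factor (sd of log = 0.1 by default, 0 for pure-Poisson
  experiments), and dosage G: autosome 1; X ♀1/♂0.5; Y ♀b/♂0.5 with
  mismapping background b = 0.02. Real coverage has mappability and GC
  structure that this does not emulate; the classifier's median is designed
  to absorb exactly such window-level artifacts.
- **Determinism.** Each artifact (genotypes, coverage, genes) draws from
  its own SeedSequence stream derived from the config seed, so any single
  output is byte-reproducible in isolation.
- Missingness is independent Bernoulli per genotype (default 0 in
  validation runs, 2% in the worked example) — no depth-correlated or
  sample-correlated missingness.

Analytic calibration: within a population,
E[2p(1−p)] = 2(1−F)·(μ−μ²−Var(p_anc)) with μ, Var the ancestral-sampler
moments, so a target per-bp diversity fixes the site density in closed
form; the π-recovery check uses this with no fitted constants.

## Validation scales and tolerances

FST recovery runs 10+10 diploids on a 5-Mb genome at 0.04 sites/bp (~200k
sites, ~2,000 windows), a scale at which the median window estimate sits
within ±0.01 of F across seeds; diversity recovery targets 3×10⁻³/bp
within 10%; coverage recovery uses a 10-Mb chromosome (10,000 windows) at
17×, median F:M within 0.05 of 1 (autosome) and 0.1 of 2 (X), Y median
log2 well below −1. The sweep-recall check (α = 0.9, 200-kb interval on
5 Mb, intersection rule) asks ≥ 80% of fully-contained truth windows
flagged and ≤ 1% of outside windows; "truth windows" are those lying
entirely inside the swept interval, since boundary-straddling windows mix
swept and neutral sites and their classification is genuinely ambiguous.
These simulation scales keep the full validation suite in the
tens-of-seconds range on one core.

## Known limitations

- Two-population F<sub>ST</sub> only (r = 2); no haplotype or LD statistics.
- The enrichment stage assumes the supplied background equals the annotation
  universe; genes absent from the category map simply never enrich.
- The sex classifier needs both sexes present and ≥10 usable windows per
  chromosome; small scaffolds come back "undetermined" by design.
- NJ is O(n³) in sample count — fine for cohorts of hundreds, not for
  biobanks.
- The VCF writer emits minimal records (GT/GQ only, first-alt hets for
  multi-allelic dosages); it is a round-trip carrier for this pipeline's
  matrices, not a general-purpose VCF editor.
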