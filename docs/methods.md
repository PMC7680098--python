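# Methods

## Scope and model

`radclone` analyses cohorts genotyped by reduced-representation sequencing
(ddRAD-style), starting from per-sample, per-site reference/alternative
read depths (VCF FORMAT/AD). It answers three questions about a design in
which several plants are sampled from each of many "circles": what is each
sample's ploidy, are the samples of a circle clonal copies of one genet,
and are the diploids inbred. Only biallelic SNPs are carried; multi-allelic
sites are dropped and counted.

## Ploidy inference

**Allele-balance spectrum.** For one sample, the alternative-allele read
fraction f = alt/(ref+alt) is collected over sites with total depth ≥ 11,
keeping 0.05 < f < 0.95. At a variant present on one of k haplotypes
(simplex dosage), reads are drawn approximately Binomial(depth, 1/k), so
the spectrum of a diploid peaks at 0.5, of a tetraploid at 0.25, of an
octoploid at 0.125. Duplex and higher dosages add mass at m/k; in
rare-variant-dominated data the simplex peak is the global mode.

**Peak identification.** The spectrum is histogrammed over (0, 1) with
fixed 0.02-wide bins, and the mode is the center of the bin maximising the
counts summed over a centered 5-bin window. Raw-bin argmax is deliberately
avoided: read fractions are ratios of small integers, and at mean depth
~30 individual bins gain or lose whole atoms of probability (for example
6/30 = 0.20 while no common fraction falls in [0.24, 0.26)), which can
displace the raw mode a full bin from the underlying peak. The window is
fixed, so the estimator stays deterministic; ties resolve by raw bin
count, then toward the lower bin, so a symmetric double peak (0.25/0.75)
resolves to the sub-0.5 peak. Measured against simulation truth the
estimator's worst-case deviation from 1/ploidy is 0.03 (2n), 0.00 (4n) and
0.015 (8n) over 40 seeds at 5000 sites.

**Calling.** The ploidy call is the level k ∈ {2, 4, 8} whose simplex peak
1/k is nearest the mode. A mode above 0.7 (mirror-image peak) or an exact
tie is flagged ambiguous. Independently, a sample is classified polyploid
when strictly more than 1000 RAD loci carry ≥ 3 distinct haplotypes — a
count a diploid cannot generate except through error, and which cannot
separate 4n from 8n. The combined call keeps the spectrum's level when the
two lines agree on diploid-vs-polyploid (the spectrum resolves 4 vs 8),
defers to the haplotype classifier when the spectrum is ambiguous, and
otherwise keeps the spectrum call with a `discordant` flag. Spectra with
fewer than 50 retained sites are flagged low-confidence.

The depth threshold is "≥ 11" throughout (an "above 11" dialect exists in
related descriptions of such filters; the inclusive form is the default
and both are reachable via `min_depth`). The haplotype threshold 1000 is
absolute, not scaled to library size, with an override for small synthetic
libraries.

## Recoding and distances

Mixed-ploidy genotypes are compared on the ternary scale: with
t = `het_threshold` (default 0.05), f ≤ t → 0, f ≥ 1−t → 1, else 0.5; the
inequalities are strict in the sense that a het call requires *more* than
5% of reads from each allele. Sites must reach depth ≥ `min_depth` in
every analysed sample, so the matrix has no missing cells. Two optional
filters reproduce a stricter second tier: `conserved_only` restricts to
the per-site conserved-subset flag (a stand-in for loci mappable to a
conserved reference genome; an actual cross-species mapping is out of
scope), and `min_individuals_variant=2` drops sites whose non-reference
code occurs in fewer than two samples (one reading of "variant present in
at least two individuals"; the alternative reading — ALT allele in ≥ 2
samples — differs only for sites that are 0.5/1 mixtures of one sample).

Genetic distance is the raw Euclidean distance between recoded columns
(no per-site normalisation; a normalised variant is available by flag).
Clustering is agglomerative via scipy's nearest-neighbor chain; complete
linkage by default, average/single selectable. Agglomeration order at
exactly tied heights follows scipy's deterministic ordering rather than a
lexicographic rule; merge heights and cophenetic structure are checked
against an O(n³) brute-force oracle in the tests. Dendrograms export to
newick with branch lengths as differences of merge heights.

Clone pairs are sample pairs at distance ≤ ε. For error-free data clones
are exactly identical, so ε defaults to 0. For noisy data
`recommended_epsilon` reports (never silently applies) the 1st percentile
of the between-circle distance distribution. Exact-zero identity of clonal
replicates holds when every dosage class's expected allele fraction sits
far from the recoding thresholds relative to binomial noise: for diploids
the het fraction 0.5 is ~7σ from 0.05 at depth 11, but an octoploid
simplex fraction 0.125 is < 2σ from 0.05 even at depth 60, so error-free
clone identity is guaranteed (and tested) for diploid cohorts only.

## Clonality statistics

Per circle with ≥ 2 samples, the within minimum is the smallest pairwise
distance inside the circle; per unordered circle pair, the between minimum
is the smallest cross-circle sample distance (a 15 × 3 design gives 15 and
C(15,2) = 105 values). The two sets are compared by a two-sided Wilcoxon
rank-sum test: exact null when min(n, m) ≤ 10 without ties, otherwise the
normal approximation with tie and continuity corrections; fully degenerate
input returns p = 1 with a warning.

A caveat established during development and reflected in the tests: under
a *panmictic* (non-clonal) truth the two minimum-distance distributions
are **not** identical — a between value is the minimum over 9 sample pairs
(3 × 3) while a within value is the minimum over 3, so between minima are
stochastically smaller and the rank-sum comparison rejects far above
nominal level (~40% at α = 0.05 in simulation). The test is therefore
anti-conservative *against* clonality — clonality would push within minima
to 0, the opposite tail — and a significant p-value alone is weak evidence
either way; the decisive signatures are within-circle minima collapsing to
~0 and clone pairs at ε ≈ 0. The test suite checks the rank-sum
implementation's calibration on its true null (iid same-distribution
samples at the study sizes) and its power under a fully clonal truth.

Isolation by distance: OLS of between-circle minimum genetic distance on
Euclidean center-to-center distance, reporting slope, intercept and
Pearson r (r set to 0 with a `degenerate` flag when genetic distances have
zero variance). A Mantel-type permutation is deliberately not the primary
analysis; the regression mirrors the simple distance-decay reading.

## Inbreeding

For the diploid subset (k samples, L sites), each sample's
F = (O_hom − E_hom)/(L − E_hom), with O_hom the count of sites coded 0
or 1 and E_hom = Σ_sites [1 − 2p̂q̂·2k/(2k−1)], where p̂ is the subset
allele frequency with 0.5 codes counting half. The 2k/(2k−1) allele-count
correction makes the per-site expected heterozygosity unbiased (the
per-sample-count form k/(k−1) overcorrects by ~1/(2k−2)). The mean F's
95% CI is a t-interval over the k per-sample values by default; a
sample-resampling bootstrap is available. Monomorphic sites contribute
equally to O_hom, E_hom and L and cancel; a fully monomorphic site set is
an error.

## Synthetic cohorts

The generator emulates the analysis-relevant structure of the field
design and sequencing process; defaults are the reference study
conditions.

- **Design**: 15 circles × 3 samples (two "near" positions within ~2 m on
  the perimeter, one opposite), circle centers on a jittered grid with
  ≥ 10 m spacing; an optional bounded study area makes over-dense requests
  fail loudly.
- **Ploidy mix**: {2n: 0.50, 4n: 0.45, 8n: 0.05} — polyploids roughly half
  the cohort, octoploids rare.
- **Site frequencies**: default a truncated neutral-SFS-like draw
  (density ∝ 1/p on (0.05, 0.95)); `uniform` is available. The skew
  toward rare variants is what makes polyploid spectra simplex-dominated;
  under a uniform frequency draw duplex mass at 0.5 dominates and
  allele-balance ploidy inference is uninformative — a property of the
  statistic, not of the implementation.
- **Genotypes**: diploid dosage from Hardy-Weinberg with inbreeding
  parameter `selfing_F` (P(het) = 2pq(1−F), homozygotes gain Fpq each);
  allopolyploids as 2 or 4 independent diploid subgenomes. A configurable
  fraction of sites (default 0.03) carries a fixed difference between
  subgenomes: polyploids are permanently balanced there (dosage = k/2),
  while diploids are reference-fixed, since such a site is interspecific
  divergence rather than diploid-population polymorphism. Clonal circles
  copy one genet's genotype to all samples.
- **Reads**: total depth ~ Poisson(mean 30) per cell; alternative reads
  binomial in dosage/ploidy; each read miscalls with probability 0.005
  (symmetric flip).
- **Haplotype counts**: simulated at the summary level (the classifier
  consumes only counts): polyploids ≥ 2000 loci with ≥ 3 haplotypes,
  diploids 50–200 (the ~ten-fold gap), total library size ~ N(63096,
  15437²) truncated.

What the generator does **not** model: linkage and recombination,
allele/restriction-site dropout, shared population structure among
diploid genets (each genet is an independent draw), depth
overdispersion, and ascertainment of variant sites from the cohort
itself. Consequences worth noting: synthetic diploids are mutually about
as distant as they are from tetraploids unless the homoeolog fraction is
large, so the "clustering separates ploidy levels" property is
demonstrated at homoeolog_fixed_fraction = 0.3 (subgenome divergence
comparable to within-species polymorphism), not at the 0.03 default; and
passing tests show the statistics behave correctly under this idealised
model, not that real libraries meet its assumptions.

## Problem sizes and determinism

All stochastic tests fix seeds; identical configurations are bit-identical
by construction (single `numpy` Generator consumed in fixed order). The
test suite and the acceptance script use cohorts of 30–45 samples and
2000–10000 sites — large enough that binomial sampling error is small
against the tolerances (spectrum modes ±0.03, inbreeding ±0.05, ploidy
recovery ≥ 95% over 20 seeds), small enough to run in seconds. The
acceptance script's calibration cohorts use 5000 single-copy sites per
ploidy level at mean depth 30 (40 for the octoploid, whose peak at 0.125
needs the extra depth to clear the 0.05 filter cleanly).
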