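# Methods

## Problem setting

Reduced-representation genotyping (DArTseq and similar
genotyping-by-sequencing platforms) yields two marker classes: codominant
SNP genotypes (coded 0 = reference homozygote, 1 = heterozygote,
2 = alternate homozygote) and dominant presence/absence (PA) markers
scored per individual at restriction-site tags. In a species with
homomorphic sex chromosomes, a young or weakly differentiated
sex-determining region (SDR) reveals itself as loci whose marker state
co-segregates with phenotypic sex. `sexlink` finds such loci, quantifies
their informativeness, and localizes the SDR on a reference assembly.

## Marker quality control

A locus is retained only if it strictly exceeds every applicable
threshold:

| criterion            | default | applies to | source of the value |
|----------------------|---------|------------|---------------------|
| reproducibility      | > 0.95  | SNP + PA   | platform metadata |
| mean sequencing depth| > 5     | SNP + PA   | platform metadata |
| allele balance       | > 0.9   | SNP only   | platform metadata |
| call rate            | > 0.8   | SNP + PA   | recomputed from calls |

Call rate is always recomputed from the matrix, so it applies even when
platform metadata is absent. The other criteria obey a strictness
policy: `drop_if_unavailable` (default) or `pass_if_unavailable`.
Reproducibility on DArT exports is a fraction in [0, 1]; the default
0.95 marks the usual "high-reproducibility" cut and is fully
configurable. Filtering is idempotent and monotone in each threshold
(raising a threshold can only shrink the retained set) — both are
property-tested.

## Sex-linkage classification

For each locus the *carrier* state is: PA call = 1, or for SNPs
possession of the alternate allele (het or alt-hom, the default — a
Y- or W-linked allele appears heterozygous in the heterogametic sex;
`het_only` and `alt_hom_only` are selectable). Carrier fractions
(f♂, f♀) are computed over called individuals only.

Under the XY hypothesis a locus passes tier *t* ∈ {0.70, 0.80, 0.90,
1.00} iff f♂ ≥ t and f♀ ≤ 1 − t (inclusive comparisons, with a 1e-9
guard against floating-point error in 1 − t); the highest passed tier
wins. Tier 1.00 ("sex-specific") therefore demands the exact 1.0/0.0
pattern. ZW mirrors the rule with the sexes swapped, so relabeling every
sample's sex swaps the XY and ZW outputs exactly (property-tested).

Missing-data gate: classification additionally requires that at least
`min_called_fraction_per_sex` (default 0.8) of each sex is called at the
locus, so a locus called in one male cannot become "specific". The
carrier fractions themselves are still reported for gated loci.

Scans run pooled across the cohort and/or per population. Populations
with a single sex are skipped with a warning. Because the exact-pattern
test is much easier to pass in a 15-sample population than in the pooled
cohort, per-population specific counts generally exceed the pooled
count; the scan reports per-population counts, the pooled count, and
the cross-population union side by side without privileging one.

## Informativeness statistics

* **Cochran–Armitage trend test.** Binary carrier form on the 2×2
  sex × carrier table, equal to N(ad − bc)²/(R₁R₂C₁C₂); genotype form
  with scores (0, 1, 2) on the 2×3 table. No continuity correction;
  p from the χ²(1) upper tail. Degenerate margins (one sex absent, all
  carriers, no score variance) return NaN rather than a fabricated
  value. The implementation is cross-checked in the test suite against
  the closed form and a 10,000-replicate permutation null (mid-p, which
  respects the discreteness of the permutation distribution).
* **PIC and heterozygosity.** Botstein's PIC
  (1 − Σpᵢ² − ΣᵢΣ_{j>i} 2pᵢ²pⱼ²) and expected heterozygosity
  (1 − Σpᵢ²) are both reported, labeled explicitly: for a biallelic
  locus PIC is bounded by 0.375 while Hₑ reaches 0.50, so a printed
  range topping at 0.50 can only be Hₑ. SNP allele frequencies come
  from genotype counts; for dominant PA markers the presence/absence
  state frequencies are used (the allele frequency is not identifiable
  from a dominant marker without assuming Hardy–Weinberg proportions).
* **Hamming distances.** Distance between two individuals = proportion
  of mutually-called loci at which their calls differ; pairs with no
  mutually-called locus are undefined (NaN). Summaries are means ± sd
  over unordered male–female, male–male and female–female pairs,
  computed per tier locus set. On a noise-free specific locus set the
  between-sex mean is exactly 1.0 and the heterogametic within-sex mean
  exactly 0.0 — this structural identity is an acceptance test.
* **Kruskal–Wallis tier comparison.** Rank-based H with tie correction
  (scipy) comparing per-locus heterozygosity across tiers, per sex;
  the all-identical degenerate case returns (H = 0, p = 1).
* **Spurious-linkage model.** P_i = 0.5ⁿ is the probability that a null
  locus — each individual independently a carrier with probability ½ —
  shows a perfect sex pattern across the n individuals sequenced at the
  locus; L · P_i bounds the expected number of spurious discoveries
  among L loci (one-sided, male-patterned, by default; a two-sided
  option doubles it). At n = 75 and L = 23,509 these are 2.65 × 10⁻²³
  and 6.22 × 10⁻¹⁹. The model is validated empirically: 10⁶ simulated
  null loci over 10 individuals yield perfect patterns at a rate inside
  the 99% binomial CI of 2⁻¹⁰ (≈ 977 expected).

## Monte Carlo subsampling reproducibility

Each replicate draws `subsample_fraction` (default 10%) of the cohort
without replacement, stratified by sex with per-sex ceiling rounding
(40♂/35♀ at 10% → 4 + 4), re-computes carrier fractions in the
subsample, and re-classifies every locus. Reported per locus: the
fraction of replicates classifying it specific, and the fraction
reaching any linked tier. The default replicate count is 100,000;
tests and the bundled examples use hundreds to thousands, which is
plenty to resolve the frequencies they assert about. Unstratified and
with-replacement modes are available behind flags. A configuration
whose subsample cannot satisfy `min_per_sex` (default 2) fails before
any replicate runs. A single PCG64 stream seeded from `seed` drives
each run, so results are bit-reproducible and independent of locus
order.

## Chromosome mapping and the SDR interval

The package consumes precomputed BLAST tabular (outfmt 6) hits rather
than running an aligner, so tests need no external genome. Hits survive
only with identity > 95% and alignment length > 65 bp (strict, on the
percent scale); per locus the maximum bit score wins, with ties broken
by lower e-value, then longer alignment, then lexicographic subject id.
A locus's position is the midpoint of its subject interval — symmetric
and strand-independent. Minus-strand hits are normalized with a strand
flag and ordered coordinates.

The SDR interval is the min–max span of the placed loci of one tier on
one chromosome (1-based inclusive; span = end − start + 1, rendered to
one decimal in Mb). Region occupancy is reported as count and
percentage (3 decimals) of the chromosome's placed loci. Placements
export to BED6 (0-based half-open).

## Repeat composition

Repeat annotations (RepeatMasker `.out` or a simple 4-column TSV) roll
up to a fixed hierarchy: LTR retrotransposon → {Ty3/Gypsy, Ty1/Copia},
non-LTR retrotransposon → {LINE}, DNA transposon → {Helitron, Polinton,
TIR}, everything unrecognized → unclassified (remaining `DNA/*`
superfamilies such as hAT and TcMar count as TIR transposons). A
fragment belongs to a region iff its midpoint does — a single
unambiguous rule that makes counts additive over disjoint intervals.
Percentages divide by the grand total of top-level class fragments, the
only denominator under which the class rows of a composition table sum
to 100%.

## Synthetic data generator

`simulate_dataset` emulates the study design the package targets: 40
males and 35 females across five commercial populations, SNP + PA
matrices, and a planted SDR on one chromosome.

* specific loci: carrier state = heterogametic-sex indicator;
* linked loci at recombination fraction r: carrier with probability
  1 − r in the heterogametic sex, r in the other (so tiers 0.90 / 0.80 /
  0.70 correspond to r ≈ 0.1 / 0.2 / 0.3);
* autosomal loci: allele frequency ~ Uniform(0.05, 0.5); SNP genotypes
  are Hardy–Weinberg binomial draws, PA presence uses the dominant band
  probability 1 − (1 − p)²;
* noise: symmetric genotyping error per cell (PA: state flip; SNP: move
  to an adjacent genotype code, the heterozygote splitting evenly), then
  missingness per cell. Defaults: error 0.01, missingness 0.05.
* positions: planted loci uniform without replacement inside the SDR
  interval (defaults to the ~5.6 Mb candidate region on chromosome 9 of
  the Siamese fighting fish assembly); autosomal loci uniform on the
  other 20 chromosomes, deliberately excluded from the SDR chromosome so
  chromosome-count tests reconstruct the planted design exactly.
* scale: 2,000 SNP + 2,000 PA loci by default (a desk-scale stand-in
  for the ~23.5k-locus study panel), with 73 specific and 150 linked
  loci planted; all counts configurable, and the locus-bookkeeping
  acceptance test runs the generator at the full 11,673 + 11,836 panel
  size.

`sd_system="PSD"` models polygenic sex determination: three unlinked
"switch" SNP loci with weights (1.0, 0.6, 0.4) plus Gaussian noise
(σ = 0.5) form a liability score, and the top-liability individuals are
male (rank-thresholded so the configured sex counts hold exactly). In
PSD mode no fully sex-linked loci are planted — that is the point of the
model — and the switch loci are labeled in the truth table. This is a
deliberately minimal quantitative stand-in for a hypothesis the source
analysis states only verbally.

What the simulator does **not** model: linkage disequilibrium and
population structure (loci are independent given the design; the five
populations are labels, not drifted allele-frequency clusters), read
depth-dependent error, allelic dropout in heterozygotes, or batch
effects. Passing recovery tests therefore demonstrate correctness of
the screening arithmetic under the stated generative model, not
robustness to every artifact of real reduced-representation data.

`simulate_alignment_hits` writes one true hit per locus at its true
position (identity 99, length 69, bit score 130) plus optional decoys on
both sides of the filters; `simulate_repeat_annotation` places a
requested composition uniformly (by midpoint) in an interval, so the
composition round-trips exactly.

## Numerical and design choices

* Missing calls are −1 internally; readers accept "-", "" and "NA",
  writers emit "-". The two-row SNP dialect maps (ref, alt) presence
  pairs (1,0)/(1,1)/(0,1) to 0/1/2; a pair with a missing member, or the
  contradictory (0,0), is missing.
* All tier comparisons are inclusive; QC comparisons strict, as the
  thresholds are conventionally quoted.
* Kruskal–Wallis, χ² tails and rank statistics come from scipy;
  estimator plumbing from scikit-learn; everything the package is
  *about* (trend test, PIC, masked Hamming, tier classifier, simulator)
  is implemented here and oracle-tested.
* Determinism: every stochastic component takes an explicit seed and
  uses `numpy.random.default_rng` (PCG64); pipeline reruns with the same
  config produce byte-identical summaries.

## Known limitations

* Dominant PA markers cannot distinguish heterozygous from homozygous
  carriers, so PA "allele frequencies" are state frequencies and PA
  expected heterozygosity is an upper-bound-style summary, not an
  estimate under Hardy–Weinberg.
* The asymptotic χ²(1) p-value of the trend test is anticonservative at
  very small per-sex counts; the permutation cross-check in the tests
  quantifies the gap (≲ 0.06 worst-case at 30–60 individuals per sex).
* The spurious-linkage model assumes carrier probability exactly ½ and
  independence across individuals and loci; it is a back-of-envelope
  bound, not a calibrated error rate.
* Subsampling detection frequencies at 10% of a 75-fish cohort rest on
  8-individual subsamples; their absolute values are sensitive to the
  rounding and stratification conventions documented above.
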