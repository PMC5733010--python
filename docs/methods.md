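# Methods

This note documents the generative model behind `bsascan.simdata`, the
exact definitions used by the filters and the scan, the numerical and
design choices that were genuinely open, and what the simulation-based
tests do and do not establish about real data.

## The association statistic

At a biallelic SNP with bulk base-frequency vectors `f1, f2` over
(A, C, G, T), the scan computes `ED = ||f1 - f2||_2`, bounded by 0
(identical pools) and sqrt(2) (opposite fixation). For sites where only
two bases are observed, `ED = sqrt(2) |f1_x - f2_x|` for either allele
`x`, which the tests exploit as a closed-form oracle. Frequencies come
from all four observed base counts when per-base counts are available
(the simulator always writes them as the `BC` FORMAT extension); with
AD-only VCFs the unobserved bases get frequency 0, which is equivalent
for sites called biallelic.

ED is raised to a power before smoothing, default `p = 5`. The transform
is monotone, so it changes no per-site ordering; its purpose is to shrink
the noise floor relative to peaks before averaging. With `p = 1` the
pipeline scores raw ED, which is the scale on which a fitted background
threshold of roughly 0.3 arises under the default design (see
"Thresholds" below).

## Sliding-window fit, threshold, and regions

"Fitting" is the mean of powered ED over windows of width `W` (default
1 Mb) stepped by `W/100` (10 kb); no spline or loess is applied. Windows
holding fewer than `min_snps` SNPs (default 10) are *undefined* rather
than zero, so sparse stretches cannot fake troughs. Window centers run
from `W/2` to chromosome end minus `W/2`; each window covers
`[c - W/2, c + W/2)`.

The peak threshold is `tau = median + 3 * SD` over all defined fitted
values genome-wide, with the sample (n-1) SD, and the comparison is
strict (`> tau`, per "greater than"): a zero-variance track therefore
calls nothing. Maximal runs of consecutive windows above `tau` become one
region each; runs may bridge up to `gap_tolerance` undefined windows
(default 0), and a defined window at or below `tau` always ends a run.
Region boundaries are clipped to the first and last SNP inside the run's
window span — the statistic is SNP-supported, so regions are reported at
base-pair-resolved SNP extents, not bare window edges — and runs whose
clipped extents touch are merged. A repetitive-region mask can exclude
SNPs from the fit but is off by default.

## Filters

Proximity rules are evaluated on the raw sorted call set, each rule
against the *input* set (removals do not cascade), which makes the layer
idempotent and order-independent:

* indel–indel: both members of any same-chromosome pair with POS distance
  strictly below 10 bp;
* SNP cluster: a 5-bp window is offending when it holds more than two
  SNPs; every member SNP of any offending window is removed;
* SNP near indel: |POS difference| of at most 5 bp removes the SNP only.

Locus rules then keep only biallelic SNPs informative for ED:
"multiple mutations" is operationalised as more than two bases supported
by at least `min_alt_reads` reads (default 2) in either bulk, or an
explicitly multiallelic VCF row; zero depth in either bulk; and
joint fixation, i.e. minor-base frequency below `hom_threshold`
(default 0.05) in both bulks with the same major base. The two numeric
cut-offs have no published values; the defaults are the smallest
read-support that excludes singleton sequencing errors and a minor-base
cut comfortably above the per-base error rate at 23–28x depth.

A site matching several rules is counted once, under the first matching
rule in the documented order, so removal counts plus survivors always
equal the input count.

## The generative model

The simulator emulates the study design the scan targets: a single
heterozygous parent selfed to give an F2-like population segregating for
one biallelic locus, two phenotype-selected bulks, pooled sequencing.

* **Genome and markers.** Default ten 30-Mb chromosomes (a desk-scale
  stand-in for the ~283-Mb, 10-chromosome *Brassica rapa* genome), one
  marker every 3 kb, the causal locus at A06:15,000,000. The parent is
  heterozygous at every marker, so every marker segregates.
* **Meiosis.** Gametes recombine between adjacent markers with Haldane's
  map function `r = 0.5 (1 - exp(-2d))`, `d` in Morgans from physical
  distance times a uniform rate (default 4 cM/Mb, about the genome-wide
  average for *B. rapa*; configurable). Single-locus genotypes are 1:2:1
  in expectation.
* **Phenotype and bulks.** Default model: one dominant locus; the
  recessive bulk is homozygous by construction, the dominant bulk is
  1 AA : 2 Aa in expectation, so at the causal locus the expected bulk
  allele frequencies are (0, 1) versus (2/3, 1/3), giving the
  infinite-depth anchor `ED = (2/3) sqrt(2) ~ 0.9428`. Bulks of 25 plants
  are drawn without replacement and phenotyping is exact by default (a
  misclassification rate is exposed). The default population is 200
  plants: the historical design sowed 125 seeds, but with n = 125 the
  recessive class (mean 31) fails to fill a 25-plant bulk in roughly one
  draw in ten, so the default is sized for near-certain fillability; the
  Mendelian 3:1 arithmetic itself is tested at n = 125.
* **Sequencing.** Depth is Poisson per site and bulk (defaults 23 and 28).
  Each read draws its source haplotype uniformly from the 2 x 25 pooled
  chromosomes and is miscalled to a uniformly chosen other base with
  probability 0.001. Reads are independent across sites — adequate for a
  per-site statistic, but it means read-level haplotype information is
  absent. A configurable fraction of markers is emitted as 1-bp indels
  (default 2%) and a configurable rate as dense artifact clusters (three
  SNPs within 5 bp, or indel pairs under 10 bp; default 1%) purely to
  exercise the filters.
* **Null trait.** `causal_chrom=None` assigns phenotypes at random with
  P(dominant) = 0.75, keeping the 3:1 bulk design while severing the
  genotype–phenotype link.
* **Determinism.** All stages draw from generators keyed on
  `(stream, seed)`, so one config reproduces byte-identical VCF and
  fixture files.

The annotation fixture tiles non-overlapping genes along the genome (one
per 100 kb by default, so candidate regions hold tens of genes), plants
one pathway enriched inside a chosen interval (default 1 Mb around the
causal locus: 4 of its 10 members inside), and flags a known subset of
genes as differentially expressed, including two inside the causal
interval.

## Thresholds and what the simulations show

Under the full default design the scan recovers the causal position in
20/20 seeded replicates, and the raw-ED (p = 1) fitted track on a matched
null dataset has `median + 3 SD` around 0.28–0.37 across seeds —
bracketing the threshold of 0.35 reported for the real cross this design
emulates, which supports the noise calibration of the read model.

The null scan also exposes a real property of the method, not of the
implementation: with 25-plant bulks, each pool's allele frequency has
standard deviation `sqrt(0.5 / (2*25)) ~ 0.071` at every locus from plant
sampling alone, so the between-bulk difference (SD ~ 0.1) forms
chromosome-scale "drift waves" whose correlation decays only over tens of
centimorgans. Window averaging removes read noise but not these waves,
and their genome-wide maximum sits about five sample-SDs above the median
— so a median + 3 SD rule calls at least one (spurious) region in
essentially every null replicate at this bulk size. Shrinking that false
positive rate requires larger bulks or a calibrated null (e.g. simulation
-based thresholds), both outside this design. Consequently, passing tests
demonstrate localisation power and faithful arithmetic, not genome-wide
error control; on real data the threshold should be read as a peak
ranking device, with the causal region expected to dominate the track as
it does in every simulated replicate.

Simplifications to keep in mind when transferring conclusions to real
data: uniform marker density and recombination rate, no repetitive-region
artifacts or mapping bias, site-independent reads, a single fully
penetrant locus, and no depth overdispersion beyond Poisson.

## Numerical and interface conventions

Internal coordinates and VCF are 1-based inclusive; BED output is 0-based
half-open (the printed interval 1,824,886–2,347,097 becomes
`A06 1824885 2347097`, and its length rounds to 0.52 Mb). ED tables print
six decimal places; enrichment uses `scipy.stats.fisher_exact`
(one-sided, greater), verified against direct hypergeometric tail
summation to 1e-10, with raw P < 0.05 significance by default and an
optional Benjamini–Hochberg flag. Zero-depth sites reaching the statistic
raise a contract error rather than being silently skipped: depth
filtering is the filter layer's job. Scaled-down problem sizes in the
test suite (3–20 Mb genomes, 500-replicate Monte-Carlo checks, 20-replicate
recovery experiments) are the package's chosen validation sizes; the
experiment functions accept any size.
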