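# Methods

This note documents the models, parameter choices and numerical conventions
behind `csdscan`, and what the simulation-based tests do and do not show
about real data.

## Inheritance model

Clonal lines descend asexually from a single diploid founder via
central-fusion automixis: meiosis proceeds normally, then two central
products fuse. The simulator (`csdscan.simcohort`) implements the minimal
model with these ingredients:

* **Crossovers** per chromosome per meiosis are Poisson with mean
  `crossover_rate` (default 1.0) and uniformly placed. No genetic map is
  assumed; both choices are configurable.
* **Co-inheritance fidelity**: with probability `coinheritance_fidelity`
  (default 0.97) the reciprocally recombined chromatids of a crossover are
  co-inherited and heterozygosity survives the breakpoint. Otherwise the
  offspring receives one recombined and one non-recombined homolog:
  every site distal to the breakpoint (toward the higher coordinate, a
  configurable convention — coordinates carry no orientation in the model)
  becomes homozygous for one maternal allele chosen with equal probability.
  The resulting LOH tract runs from the breakpoint to the chromosome end;
  once a chromosome has lost heterozygosity distally, later crossovers on
  it are ignored, so tracts are single and contiguous per chromosome per
  meiosis. The default fidelity makes LOH rare, as it must be for a clonal
  lineage with CSD to persist, while still producing diploid males at a
  realistic rate (a couple of percent of offspring are diploid males, and
  diploid males are a minority of all males).
* **Haploid males** arise with probability `haploid_male_rate` (default
  0.05) as single, possibly recombinant meiotic products.
* **Sex**: haploids are male. A diploid is female iff heterozygous at the
  CSD locus (any locus, under the multi-locus rule), operationalized as
  carrying at least one heterozygous SNP inside the locus interval;
  `stochastic_male_rate` (default 0.02) flips locus-heterozygous diploids
  to male, modeling the non-genetic diploid males observed in real
  colonies (where roughly a third of diploid males retain heterozygosity
  at the mapped locus).
* **Founders** carry ancestral heterozygosity in blocks (exponential block
  length, default mean 100 kb, het fraction 0.6) to mimic line-specific
  homozygous regions. A founder must be heterozygous at every CSD locus —
  a homozygous founder would have produced no daughters — so planting the
  locus overrides the drawn mask there. For multi-line cohorts,
  `plant_balanced_alleles` gives each line two of *k* distinct locus
  haplotypes and densifies the SNP scaffold inside the locus (default 4×),
  reflecting the higher variant density that anciently diverged, balanced
  alleles carry.

## Read model

Per site and sample, depth is negative-binomial with mean 25 and
overdispersion 0.05 (variance = mean + 0.05·mean²), matching a typical
short-read whole-genome resequencing profile; reads split between the true
alleles with per-read miscall probability 1e-4. The genotype caller is
deliberately naive — both alleles seen in ≥ 1 read → heterozygous, else
homozygous for the observed allele, zero depth → missing — because the
downstream filters are the paper of record for call quality here. Two
consequences worth knowing:

* At depth *d*, a true heterozygote is miscalled homozygous with
  probability 2·0.5^d (binomial sampling), ≈ 3e-3 per sample-site at 15×
  and negligible at 30×. "Noiseless" tests therefore run at depth ≥ 30.
* Haploid samples inside configured `collapsed_regions` emit heterozygous
  diploid-coded calls, providing the signal the haploid-heterozygosity
  filter removes.

## Filters

Applied in order, each idempotent and logged: restrict to biallelic SNPs;
drop sites heterozygous in any haploid male (collapsed repeats); drop sites
where any heterozygous sample has minor-allele depth fraction < 0.25 (the
denominator is the summed depth of the two called alleles, not DP) or any
homozygous sample has reads on a non-called allele; drop sites with > 20%
missing calls. Filters are applied across all loaded samples by default.
Note the allelic-depth rule's site-level veto scales with cohort size: with
hundreds of samples nearly every site acquires one unlucky heterozygote, so
the filter set is calibrated for mapping panels of a few dozen genomes.

## Scan

The ancestral-heterozygosity test uses only diploids (haploids carry one
allele by construction), ignores missing calls, and requires ≥ 2 genotyped
diploids per site. The CSD index, permutation null (labels shuffled within
colonies once per permutation and shared across sites, preserving
between-site correlation of the null; default 1,000 permutations, plain
proportion estimator with an add-one option), BH step-up FDR and windowed
means (50 kb / 15 kb) follow the definitions in the README. Empty windows
are reported as missing and never contribute to peaks.

Peak calling thresholds the windowed mean FDR-corrected values (default
0.05) and merges runs of consecutive significant windows; the pipeline
allows one interrupting non-significant window per run (`peak_max_gap=1`),
since a single miscalled site can lift one window above threshold without
breaking the underlying signal. Because LOH tracts run to the chromosome
end, the homozygosity plateau distal to the locus and the ramp proximal to
it also reach significance; candidates are therefore ranked by smallest
peak q, then by the largest window-mean CSD index over windows contained in
the run, then leftmost. The locus itself is refined by the LOH-segment
intersection, not by the scan resolution.

## LOH

Segmentation is rule-based run-length scanning (default: ≥ 10 homozygous
informative SNPs per run, ≤ 1 interrupting heterozygous SNP; missing calls
are skipped), not an HMM: the transparent rule keeps every boundary
auditable and its two parameters exposed. Segment intervals span the first
to last homozygous SNP (half-open), claiming nothing beyond observed
markers; accordingly, simulation tests compare called segments against
true tracts clipped to the span of informative markers. The cross-male
intersection counts per-position segment support, excludes positions where
any diploid female is homozygous, and returns the leftmost maximal-support
interval. Allele identity is assigned against an explicitly chosen
reference haploid (the CLI defaults to the first haploid of the mapping
line; a deterministic choice aids testing), restricted to ancestrally
heterozygous SNPs — without that restriction, line-homozygous sites would
trivially match the reference haploid and drown the signal — with a 90%
majority rule and `mixed` otherwise. Depth classification compares the
segment's mean normalized depth (per-sample genome-wide median of
filter-passing sites as denominator) against a copy-neutral band
[0.8, 1.2] and a deletion band [0.3, 0.7]; fewer than 5 depth-bearing
sites, or a mean in neither band, yields `ambiguous`. Ordinal coordinates
rank the informative SNPs 1..K per chromosome for density-independent
displays.

## Nucleotide diversity

Per site, D = n/(n−1)·(1 − Σpᵢ²) over pooled allele copies of the selected
lines' diploids (two copies per genotyped diploid, missing calls dropped);
windowed π divides the summed D by the window width in bp (5 kb / 1 kb
defaults; an accessible-sites denominator would be a straightforward
variant but per-bp is the convention the window sizes imply). Pooling
across lines is the default rather than averaging per-line π. Haplotype
divergence windows count per-100 bp differences of pre-aligned sequences
against a named reference; N columns and gap-gap columns are skipped,
gap-vs-base counts as a difference by default (configurable). The peak
report takes the argmax window and the contiguous run above the genome-wide
99.9th percentile.

## Contingency statistics

`cohort_contingency` always reports the Pearson chi-square both without
(17.00 on the counts 22/92 vs 0/78) and with Yates continuity correction
(15.15), plus df and the Fisher exact p. For small 2×2 tables, reported
chi-square values in the literature are frequently ambiguous about the
correction used and may match neither exact formula; presenting the pair
side by side documents such discrepancies instead of chasing one number.

## Problem sizes and determinism

Simulated genomes are two chromosomes of ~1 Mb at SNP density 1e-3/bp
(~2,200 sites, ~900 informative after filtering) — large enough that
windows, blocks and tracts have realistic multiplicity, small enough that
the full pipeline runs in seconds. Recovery experiments use ascertained
mapping panels (16 diploid males, 19 diploid females, 2 haploid males,
mirroring how rare diploid males are collected in practice) and 200
permutations; calibration uses 500. All randomness flows from one integer
seed through named substreams (`_util.stream`), so any stage reproduces in
isolation and repeated runs are byte-identical, VCF output included.

## What passing tests do not show

The simulator draws crossovers uniformly, gives every chromosome the same
SNP density outside planted loci, models read depth as exchangeable across
sites, and plants a locus that is ancestrally heterozygous in every line by
construction. Real data add alignment artifacts beyond collapsed repeats,
reference bias, segmental duplications, population structure within lines,
and genotyping error that is correlated along the genome — none of which
the recovery and calibration results speak to. The scan's mapping
resolution is also intrinsically one-sided here: with tracts running to
chromosome ends, only proximal breakpoints delimit the locus, and the
distal boundary comes entirely from the female-heterozygosity constraint.
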