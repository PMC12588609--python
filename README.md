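# csdscan

Homozygosity mapping of **complementary sex determination (CSD)** loci in
clonal, automictically reproducing lineages — ants and other haplodiploid
insects in which heterozygosity at a sex locus triggers female development
while hemi- or homozygosity permits male development.

## The problem

In a clonal line reproducing by **central-fusion automixis**, two haploid
products of a single meiosis fuse, so offspring inherit their mother's
genotype almost intact. Heterozygosity is occasionally lost when the
reciprocally recombined chromatids of a crossover fail to be co-inherited:
every site distal to the breakpoint then becomes homozygous for one maternal
allele (a contiguous, copy-neutral **loss of heterozygosity**, LOH). If the
species uses CSD, an LOH tract spanning the sex locus turns a would-be female
into a diploid male. Diploid males are therefore natural mapping material:
the CSD locus is the region where **every diploid female is heterozygous and
diploid males are homozygous** — for either allele, so ordinary association
mapping (which looks for one allele tracking the phenotype) cannot find it.

## The statistic

For each SNP that is putatively *ancestrally heterozygous* in the mapping
line (at least one diploid heterozygous; all other diploids heterozygous for
the same two alleles or homozygous for one of them), the **CSD index** is

```
index(s) = 0                                   if any diploid female is homozygous at s
         = (# homozygous diploid males) /
           (# genotyped diploid males)         otherwise
```

Significance comes from a permutation null that shuffles sex labels **within
colonies** (preserving genetic structure), with
`p = #(permuted index >= observed)/n_perm`, Benjamini–Hochberg FDR
correction, and sliding-window summaries (50 kb windows, 15 kb step).
Candidate windows are corroborated by intersecting per-male LOH segments
(restricted to SNPs heterozygous in all females), classifying each sample's
allele against a reference haploid male, checking copy number via read depth
normalized by the genome-wide median, and testing for the elevated
nucleotide diversity (π in 5 kb windows, 1 kb step) that balancing selection
should maintain at a CSD locus.

The package also ships a full **cohort simulator** (central-fusion meiosis
with crossover co-inheritance fidelity, planted CSD loci, haploid males,
stochastic diploid males, overdispersed read depths, collapsed-repeat
artifacts) emitting standard VCF + TSV, so the entire pipeline is testable
with no external data.

## Worked example

Run the whole pipeline on a simulated mapping panel (19 diploid females,
16 diploid males, 2 haploid males; one 50 kb CSD locus planted at
chr1:500,000–550,000):

```sh
csdscan all --simulate --seed 11 --n-perm 500 --out demo_out
```

prints

```
{"n_sites_filtered": 1497, "n_informative_sites": 897}
candidate chr1:465000-965000 (peak q=0)
candidate chr1:150000-470000 (peak q=0)
```

and `demo_out/report.json` contains

```
"loh_intersection": {"chrom": "chr1", "start": 500898, "end": 550113,
                     "support": 16, ...}
"intersection_class_counts": {
    "female": {"heterozygous": 19, "allele1": 0, "allele2": 0, ...},
    "male":   {"heterozygous": 0,  "allele1": 8, "allele2": 8, ...}}
```

Reading this output: the scan flags a broad significant region (the
windowed permutation q-values cannot separate the locus from the
homozygosity plateau its LOH tracts create, because tracts run from their
breakpoint to the chromosome end), but the **intersection of the 16 males'
LOH segments, restricted to female-heterozygous SNPs, recovers the planted
locus to within one marker spacing** (500,898–550,113 vs the true
500,000–550,000). All 19 females are heterozygous there, and the males are
homozygous for one or the other allele — homozygosity per se, not a
particular allele, makes a male.

Individual stages are available as subcommands (`simulate`, `filter`,
`anchet`, `scan`, `loh`, `pi`, `figures`); `csdscan <cmd> --help` lists the
options, whose defaults are the analysis defaults documented in
`docs/methods.md`.

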