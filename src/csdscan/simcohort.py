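"""Synthetic clonal-ant cohorts under central-fusion automixis.

The generator emulates the statistical structure a homozygosity-mapping
analysis of complementary sex determination (CSD) relies on:

* clonal lines descended from single diploid founders, with line-specific
  blocks of ancestral heterozygosity;
* central-fusion automixis: two central meiotic products fuse, so maternal
  heterozygosity is preserved except when a crossover's reciprocally
  recombined chromatids fail to be co-inherited, which converts every site
  distal to the breakpoint to homozygosity for one maternal allele
  (a contiguous, copy-neutral loss-of-heterozygosity tract);
* a planted CSD locus: diploids heterozygous at the locus develop female,
  hemizygous/homozygous individuals develop male, with an optional rate of
  non-genetic ("stochastic") diploid males;
* haploid males arising from unfused meiotic products;
* sequencing noise: overdispersed depths, rare base miscalls, and collapsed
  repeat regions that emit spurious heterozygous calls in haploids.

Cohorts are emitted as VCFv4.2 (GT/AD/DP) plus a metadata TSV and
machine-readable truth files, so every downstream stage of the pipeline is
exercisable without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stream
from .variants import HAPLOID_PAD, MISSING, VariantTable

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# parameter types


@dataclass
class FounderGenome:
    """A clonal line founder: SNP scaffold plus ancestral heterozygosity.

    ``snp_positions`` are sorted 1-based positions per chromosome;
    ``anc_het_mask`` marks sites heterozygous in the founder and
    ``founder_alleles`` holds the ordered allele-index pair per site
    (distinct at heterozygous sites, identical at homozygous ones).
    """

    chrom_lengths: dict
    snp_positions: dict
    anc_het_mask: dict
    founder_alleles: dict
    ref_base: dict = field(default_factory=dict)
    alt_base: dict = field(default_factory=dict)

    def validate(self) -> None:
        for c, pos in self.snp_positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
            al = self.founder_alleles[c]
            het = self.anc_het_mask[c]
            if np.any(al[het, 0] == al[het, 1]):
                raise ValueError("heterozygous site with identical alleles")
            if np.any(al[~het, 0] != al[~het, 1]):
                raise ValueError("homozygous site with distinct alleles")


@dataclass
class CSDModel:
    """Where and how heterozygosity determines sex.

    ``loci`` are 0-based half-open intervals; under rule ``"single"`` a
    diploid develops female iff heterozygous at the (single) locus, under
    ``"multi"`` heterozygosity at at least one locus suffices.
    ``stochastic_male_rate`` is the probability that a locus-heterozygous
    diploid nevertheless develops male (non-genetic diploid males).
    """

    loci: list
    rule: str = "single"
    stochastic_male_rate: float = 0.0

    def __post_init__(self):
        if self.rule not in ("single", "multi"):
            raise ValueError("rule must be 'single' or 'multi'")
        if self.rule == "multi" and len(self.loci) < 2:
            raise ValueError("multi-locus rule requires >=2 loci")
        if self.rule == "single" and len(self.loci) != 1:
            raise ValueError("single-locus rule requires exactly 1 locus")
        if not 0.0 <= self.stochastic_male_rate <= 1.0:
            raise ValueError("stochastic_male_rate must be in [0,1]")


@dataclass
class MeiosisParams:
    """Central-fusion meiosis parameters.

    ``crossover_rate`` is the expected crossover count per chromosome per
    meiosis (Poisson); ``coinheritance_fidelity`` is the probability that the
    reciprocally recombined chromatids of a crossover are co-inherited (no
    heterozygosity loss); ``haploid_male_rate`` is the probability that an
    offspring arises from a single unfused haploid product.
    """

    crossover_rate: float = 1.0
    coinheritance_fidelity: float = 0.97
    haploid_male_rate: float = 0.05

    def __post_init__(self):
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be >= 0")
        for name in ("coinheritance_fidelity", "haploid_male_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class ReadModel:
    """Sequencing model for emitted genotype calls.

    Depth is negative-binomial with the given mean and overdispersion
    (variance = mean + dispersion * mean^2; dispersion 0 gives Poisson).
    ``base_error`` is the per-read miscall probability.  ``collapsed_regions``
    (list of (chrom, start, end), 0-based half-open) emit spurious
    heterozygous calls in haploid samples, mimicking repeats collapsed in
    the reference assembly.
    """

    mean_depth: float = 25.0
    depth_dispersion: float = 0.05
    base_error: float = 1e-4
    collapsed_regions: list = field(default_factory=list)

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


@dataclass
class Individual:
    sample_id: str
    sex: str
    ploidy: int
    colony: str
    clonal_line: str
    genotype: dict  # chrom -> (n,2) int8 for diploids, (n,) for haploids
    loh_tracts: list  # (chrom, start, end, allele_column)


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort."""

    individuals: pd.DataFrame  # sample_id, sex, ploidy, colony, clonal_line
    loh_tracts: pd.DataFrame  # sample_id, chrom, start, end, allele
    csd: CSDModel
    founders: dict  # line -> FounderGenome


@dataclass
class LineConfig:
    name: str = "A"
    n_colonies: int = 4
    offspring_per_colony: int = 40


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults describe a desk-scale genome (two chromosomes of ~1 Mb, SNP
    density 1e-3/bp) with a single 50 kb CSD locus mid-chromosome-1 and
    meiosis parameters chosen so that losses of heterozygosity are rare and
    diploid males a small minority of males, as observed in clonal raider
    ant colonies.
    """

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 1_000_000}
    )
    snp_density: float = 1e-3
    anc_het_fraction: float = 0.6
    het_block_bp: float | None = 100_000.0
    lines: list = field(default_factory=lambda: [LineConfig()])
    csd: CSDModel = field(
        default_factory=lambda: CSDModel(loci=[("chr1", 500_000, 550_000)])
    )
    meiosis: MeiosisParams = field(default_factory=MeiosisParams)
    reads: ReadModel = field(
        default_factory=lambda: ReadModel(
            collapsed_regions=[("chr2", 700_000, 710_000)]
        )
    )
    csd_alleles_k: int | None = None  # number of balanced locus alleles across lines
    locus_density_multiplier: float = 4.0  # SNP-density boost in balanced loci


# ---------------------------------------------------------------------------
# founder simulation


def simulate_founder(
    chrom_lengths: dict,
    snp_density: float,
    anc_het_fraction: float,
    seed: int,
    het_block_bp: float | None = None,
    scaffold: FounderGenome | None = None,
    line: str = "A",
    dense_regions: list | None = None,
) -> FounderGenome:
    """Draw a founder genome: SNP scaffold plus ancestral heterozygosity.

    SNP positions are uniform (then sorted and deduplicated).  The
    ancestral-heterozygosity mask is Bernoulli(``anc_het_fraction``) per
    site, or, if ``het_block_bp`` is given, constant within contiguous
    blocks of exponentially distributed length to mimic the line-specific
    homozygous regions of real clonal lineages.  Passing ``scaffold`` reuses
    an existing site scaffold (positions and ref/alt bases) so several
    founders share coordinates.
    """
    if not chrom_lengths or any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("need at least one chromosome of positive length")
    if snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    if not 0.0 <= anc_het_fraction <= 1.0:
        raise ValueError("anc_het_fraction must be in [0,1]")

    rng = stream(seed, "founder", line)
    positions, ref_base, alt_base = {}, {}, {}
    if scaffold is not None:
        positions = scaffold.snp_positions
        ref_base = scaffold.ref_base
        alt_base = scaffold.alt_base
    else:
        scaffold_rng = stream(seed, "scaffold")
        for c, length in chrom_lengths.items():
            n = scaffold_rng.poisson(snp_density * length)
            raw = scaffold_rng.integers(1, length + 1, size=n)
            # regions of elevated divergence (e.g. balanced, anciently
            # diverged haplotypes) carry proportionally more variant sites
            extra = []
            for region in dense_regions or []:
                rc, rs, re_, mult = region
                if rc != c or mult <= 1:
                    continue
                k = scaffold_rng.poisson(snp_density * (mult - 1) * (re_ - rs))
                extra.append(scaffold_rng.integers(rs + 1, re_ + 1, size=k))
            pos = np.unique(np.concatenate([raw] + extra) if extra else raw)
            positions[c] = pos.astype(np.int64)
            rb = scaffold_rng.integers(0, 4, size=pos.size)
            ab = (rb + scaffold_rng.integers(1, 4, size=pos.size)) % 4
            ref_base[c] = BASES[rb]
            alt_base[c] = BASES[ab]

    het_mask, alleles = {}, {}
    for c, length in chrom_lengths.items():
        pos = positions[c]
        if het_block_bp is None:
            het = rng.random(pos.size) < anc_het_fraction
        else:
            het = np.zeros(pos.size, dtype=bool)
            start = 0.0
            while start < length:
                block_len = rng.exponential(het_block_bp)
                block_het = rng.random() < anc_het_fraction
                if block_het:
                    het |= (pos - 1 >= start) & (pos - 1 < start + block_len)
                start += block_len
        al = np.zeros((pos.size, 2), dtype=np.int8)
        hom_alt = (~het) & (rng.random(pos.size) < 0.5)
        al[hom_alt] = 1
        al[het, 1] = 1
        het_mask[c] = het
        alleles[c] = al
    fg = FounderGenome(
        chrom_lengths=dict(chrom_lengths),
        snp_positions=positions,
        anc_het_mask=het_mask,
        founder_alleles=alleles,
        ref_base=ref_base,
        alt_base=alt_base,
    )
    fg.validate()
    return fg


def plant_csd_locus(founder: FounderGenome, csd: CSDModel) -> None:
    """Force ancestral heterozygosity across the CSD loci of a founder.

    A clonal line can only persist if its founder is heterozygous at every
    CSD locus (homozygous founders would have produced no daughters), so
    planting the locus overrides the drawn mask inside each locus interval.
    """
    for chrom, start, end in csd.loci:
        if chrom not in founder.snp_positions:
            raise ValueError(f"CSD locus on unknown chromosome {chrom}")
        length = founder.chrom_lengths[chrom]
        if not (0 <= start < end <= length):
            raise ValueError("CSD locus outside chromosome bounds")
        pos = founder.snp_positions[chrom]
        inside = (pos - 1 >= start) & (pos - 1 < end)
        if not inside.any():
            raise ValueError(f"CSD locus {chrom}:{start}-{end} contains no SNPs")
        founder.anc_het_mask[chrom][inside] = True
        founder.founder_alleles[chrom][inside] = (0, 1)


def plant_balanced_alleles(
    founders: dict, csd: CSDModel, k: int, seed: int
) -> dict:
    """Give each line two of ``k`` balanced locus haplotypes.

    Emulates balancing selection at a CSD locus: ``k`` distinct haplotype
    patterns (binary allele patterns over the locus SNPs) segregate across
    lines; each founder carries two distinct patterns, so every founder is
    heterozygous at the locus while pooled diversity across lines is
    elevated.  Returns the pattern dictionary per locus.
    """
    if k < 2:
        raise ValueError("need k >= 2 balanced alleles")
    rng = stream(seed, "balanced-alleles")
    patterns_by_locus = {}
    for locus in csd.loci:
        chrom, start, end = locus
        any_founder = next(iter(founders.values()))
        pos = any_founder.snp_positions[chrom]
        inside = np.flatnonzero((pos - 1 >= start) & (pos - 1 < end))
        pats = rng.integers(0, 2, size=(k, inside.size)).astype(np.int8)
        # ensure pairwise distinct patterns
        for i in range(1, k):
            while any(np.array_equal(pats[i], pats[j]) for j in range(i)):
                pats[i] = rng.integers(0, 2, size=inside.size)
        patterns_by_locus[locus] = pats
        for line, fg in founders.items():
            i, j = rng.choice(k, size=2, replace=False)
            fg.anc_het_mask[chrom][inside] = pats[i] != pats[j]
            fg.founder_alleles[chrom][inside, 0] = pats[i]
            fg.founder_alleles[chrom][inside, 1] = pats[j]
            if not (pats[i] != pats[j]).any():  # pragma: no cover - distinct by construction
                raise RuntimeError("balanced alleles produced identical patterns")
    return patterns_by_locus


# ---------------------------------------------------------------------------
# meiosis


def reproduce_central_fusion(
    mother_genotype: dict,
    chrom_lengths: dict,
    params: MeiosisParams,
    rng: np.random.Generator,
    positions: dict,
) -> tuple:
    """One central-fusion meiosis: offspring genotype, true LOH tracts, ploidy.

    With probability ``haploid_male_rate`` a single (possibly recombinant)
    haploid product is returned.  Otherwise two central products fuse: per
    chromosome the crossover count is Poisson(``crossover_rate``) with
    uniform breakpoints; each crossover's reciprocal chromatids are
    co-inherited with probability ``coinheritance_fidelity``, in which case
    heterozygosity is preserved across the breakpoint.  The first
    non-co-inherited crossover on a chromosome converts every site distal to
    its breakpoint (toward the higher coordinate, by convention) to
    homozygosity for one maternal allele chosen with equal probability,
    producing one contiguous LOH tract from the breakpoint to the chromosome
    end.

    Returns ``(genotype, loh_tracts, ploidy)``; ``loh_tracts`` entries are
    ``(chrom, start, end, allele_column)`` with 0-based half-open intervals.
    """
    first = next(iter(mother_genotype.values()))
    if first.ndim != 2:
        raise ValueError("mother must be diploid")

    haploid = rng.random() < params.haploid_male_rate
    genotype, tracts = {}, []
    for c, length in chrom_lengths.items():
        mg = mother_genotype[c]
        pos = positions[c]
        n_co = rng.poisson(params.crossover_rate)
        breakpoints = np.sort(rng.uniform(0, length, size=n_co))
        if haploid:
            # a single meiotic product: mosaic of the two maternal columns
            col = int(rng.integers(0, 2))
            hap = np.empty(pos.size, dtype=np.int8)
            segment_start = 0.0
            for bp in list(breakpoints) + [float(length)]:
                seg = (pos - 1 >= segment_start) & (pos - 1 < bp)
                hap[seg] = mg[seg, col]
                col = 1 - col
                segment_start = bp
            genotype[c] = hap
            continue
        child = mg.copy()
        for bp in breakpoints:
            if rng.random() < params.coinheritance_fidelity:
                continue  # reciprocal chromatids co-inherited: no LOH
            col = int(rng.integers(0, 2))
            start = int(np.floor(bp))
            distal = pos - 1 >= start
            child[distal, 0] = mg[distal, col]
            child[distal, 1] = mg[distal, col]
            tracts.append((c, start, int(length), col))
            break  # everything distal is already homozygous
        genotype[c] = child
    return genotype, tracts, (1 if haploid else 2)


def assign_sex(
    genotype: dict,
    ploidy: int,
    model: CSDModel,
    rng: np.random.Generator,
    positions: dict,
) -> str:
    """Sex from ploidy and CSD-locus genotype.

    Haploids are male.  A diploid is heterozygous at a locus if any SNP
    inside the locus interval carries two distinct alleles; heterozygosity
    at the single locus (rule ``"single"``) or at >=1 locus (rule
    ``"multi"``) triggers female development, flipped to male with
    probability ``stochastic_male_rate``.  Homozygosity at all loci gives a
    male.
    """
    if ploidy == 1:
        return "male"
    het_any = False
    for chrom, start, end in model.loci:
        if chrom not in genotype:
            raise ValueError(f"genotype does not cover locus chromosome {chrom}")
        pos = positions[chrom]
        inside = (pos - 1 >= start) & (pos - 1 < end)
        if not inside.any():
            raise ValueError(f"locus {chrom}:{start}-{end} has no SNPs in genotype")
        g = genotype[chrom]
        if (g[inside, 0] != g[inside, 1]).any():
            het_any = True
            break
    if het_any:
        if model.stochastic_male_rate > 0 and rng.random() < model.stochastic_male_rate:
            return "male"
        return "female"
    return "male"


# ---------------------------------------------------------------------------
# read simulation


def emit_genotype_calls(
    individuals: list,
    founder: FounderGenome,
    read_model: ReadModel,
    seed: int,
) -> VariantTable:
    """Simulate read depths and genotype calls for a list of individuals.

    Per site and sample, total depth is negative-binomial; reads split
    between the true alleles with ``base_error`` cross-contamination.  The
    caller is intentionally naive: both alleles observed in >=1 read gives a
    heterozygous call, otherwise the observed allele is called homozygous
    (hemizygous for haploids); zero depth gives a missing call.  Haploid
    samples inside ``collapsed_regions`` behave like heterozygotes: reads
    come from both pseudo-alleles and the emitted call is diploid-coded.
    """
    chroms_order = list(founder.chrom_lengths)
    chrom_arr, pos_arr, ref_arr, alt_list = [], [], [], []
    for c in chroms_order:
        pos = founder.snp_positions[c]
        chrom_arr.extend([c] * pos.size)
        pos_arr.extend(pos.tolist())
        ref_arr.extend(founder.ref_base[c].tolist())
        alt_list.extend([(b,) for b in founder.alt_base[c]])
    n_sites = len(pos_arr)
    n_samples = len(individuals)
    gt = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int16)
    ad = np.zeros((n_sites, n_samples, 2), dtype=np.int32)
    dp = np.zeros((n_sites, n_samples), dtype=np.int32)

    # per-chromosome slices into the site axis
    offsets, off = {}, 0
    for c in chroms_order:
        k = founder.snp_positions[c].size
        offsets[c] = (off, off + k)
        off += k

    for j, ind in enumerate(individuals):
        rng = stream(seed, "reads", ind.sample_id)
        # stack true alleles into (n_sites, 2); haploids replicated, then
        # flagged so the call is emitted single-allele
        true = np.empty((n_sites, 2), dtype=np.int8)
        haploid_site = np.zeros(n_sites, dtype=bool)
        for c in chroms_order:
            a, b = offsets[c]
            g = ind.genotype[c]
            if g.ndim == 1:
                true[a:b, 0] = g
                true[a:b, 1] = g
                haploid_site[a:b] = True
            else:
                true[a:b] = g
        if ind.ploidy == 1:
            for chrom, start, end in read_model.collapsed_regions:
                if chrom not in offsets:
                    continue
                a, b = offsets[chrom]
                pos = founder.snp_positions[chrom]
                inside = (pos - 1 >= start) & (pos - 1 < end)
                idx = np.arange(a, b)[inside]
                # collapsed repeat: haploid emits both alleles
                true[idx, 0] = 0
                true[idx, 1] = 1
                haploid_site[idx] = False

        if read_model.mean_depth <= 0:
            continue
        if read_model.depth_dispersion > 0:
            r = 1.0 / read_model.depth_dispersion
            p = r / (r + read_model.mean_depth)
            depth = rng.negative_binomial(r, p, size=n_sites)
        else:
            depth = rng.poisson(read_model.mean_depth, size=n_sites)

        e = read_model.base_error
        het_true = true[:, 0] != true[:, 1]
        # probability a read supports allele index 1 (site-wise alt status is
        # whatever allele occupies slot 1 when het; for hom sites it is the
        # non-carried allele arriving by miscall only)
        p_second = np.where(het_true, 0.5, e)
        reads_second = rng.binomial(depth, p_second)
        reads_first = depth - reads_second

        # map slot counts onto (ref, alt) allele indices
        a_first = true[:, 0]
        a_second = np.where(het_true, true[:, 1], 1 - true[:, 0])
        site_idx = np.arange(n_sites)
        ad[site_idx, j, a_first] += reads_first
        ad[site_idx, j, a_second] += reads_second
        dp[:, j] = depth

        ref_reads = ad[:, j, 0]
        alt_reads = ad[:, j, 1]
        both = (ref_reads > 0) & (alt_reads > 0)
        only_ref = (ref_reads > 0) & (alt_reads == 0)
        only_alt = (alt_reads > 0) & (ref_reads == 0)
        gt[both, j, 0] = 0
        gt[both, j, 1] = 1
        gt[only_ref, j, 0] = 0
        gt[only_alt, j, 0] = 1
        single = (only_ref | only_alt) & haploid_site
        pair = (only_ref | only_alt) & ~haploid_site
        gt[single, j, 1] = HAPLOID_PAD
        gt[pair, j, 1] = gt[pair, j, 0]

    return VariantTable(
        chrom=np.asarray(chrom_arr, dtype=object),
        pos=np.asarray(pos_arr, dtype=np.int64),
        ref=np.asarray(ref_arr, dtype=object),
        alt=alt_list,
        samples=[ind.sample_id for ind in individuals],
        gt=gt,
        ad=ad,
        dp=dp,
        contig_lengths=dict(founder.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _founders_for(config: CohortConfig, seed: int) -> dict:
    founders = {}
    scaffold = None
    dense = None
    if config.csd_alleles_k is not None:
        dense = [
            (c, s, e, config.locus_density_multiplier) for (c, s, e) in config.csd.loci
        ]
    for lc in config.lines:
        fg = simulate_founder(
            config.chrom_lengths,
            config.snp_density,
            config.anc_het_fraction,
            seed,
            het_block_bp=config.het_block_bp,
            scaffold=scaffold,
            line=lc.name,
            dense_regions=dense,
        )
        if scaffold is None:
            scaffold = fg
        founders[lc.name] = fg
    if config.csd_alleles_k is not None:
        plant_balanced_alleles(founders, config.csd, config.csd_alleles_k, seed)
    else:
        for fg in founders.values():
            plant_csd_locus(fg, config.csd)
    return founders


def _offspring(
    founder: FounderGenome,
    config: CohortConfig,
    line: str,
    colony: str,
    ident: str,
    seed: int,
) -> Individual:
    rng = stream(seed, "meiosis", ident)
    genotype, tracts, ploidy = reproduce_central_fusion(
        founder.founder_alleles,
        founder.chrom_lengths,
        config.meiosis,
        rng,
        founder.snp_positions,
    )
    sex = assign_sex(genotype, ploidy, config.csd, rng, founder.snp_positions)
    return Individual(
        sample_id=ident,
        sex=sex,
        ploidy=ploidy,
        colony=colony,
        clonal_line=line,
        genotype=genotype,
        loh_tracts=tracts,
    )


def build_cohort(config: CohortConfig, seed: int) -> tuple:
    """Simulate a full cohort in memory.

    Every colony's offspring are drawn by central-fusion meiosis from the
    line founder and sexed by the CSD model, so cohort composition (numbers
    of females, diploid males, haploid males) is emergent.

    Returns ``(VariantTable, metadata DataFrame, SimTruth)``.
    """
    founders = _founders_for(config, seed)
    individuals = []
    for lc in config.lines:
        fg = founders[lc.name]
        for ci in range(lc.n_colonies):
            colony = f"{lc.name}-c{ci + 1}"
            for oi in range(lc.offspring_per_colony):
                ident = f"{colony}-{oi + 1:03d}"
                individuals.append(
                    _offspring(fg, config, lc.name, colony, ident, seed)
                )
    return _finalize(individuals, founders, config, seed)


def build_mapping_panel(
    config: CohortConfig,
    seed: int,
    n_diploid_males: int = 16,
    n_diploid_females: int = 19,
    n_haploid_males: int = 2,
    max_meioses: int = 200_000,
) -> tuple:
    """Simulate an ascertained mapping panel from the first configured line.

    Mapping panels in colony studies are not random broods: rare diploid
    males are collected opportunistically until enough accumulate.  This
    generator mirrors that by drawing meioses from the line founder until
    the requested numbers of diploid males, diploid females and haploid
    males have been observed, cycling colonies so each colony contains a
    mix of sexes.

    Returns ``(VariantTable, metadata DataFrame, SimTruth)``.
    """
    founders = _founders_for(config, seed)
    lc = config.lines[0]
    fg = founders[lc.name]
    want = {
        ("male", 2): n_diploid_males,
        ("female", 2): n_diploid_females,
        ("male", 1): n_haploid_males,
    }
    got = {k: 0 for k in want}
    individuals = []
    for i in range(max_meioses):
        colony = f"{lc.name}-c{(len(individuals) % lc.n_colonies) + 1}"
        ind = _offspring(fg, config, lc.name, colony, f"m{i + 1:06d}", seed)
        key = (ind.sex, ind.ploidy)
        if key in want and got[key] < want[key]:
            got[key] += 1
            ind.sample_id = f"{colony}-{len(individuals) + 1:03d}"
            individuals.append(ind)
        if all(got[k] >= want[k] for k in want):
            break
    else:
        raise RuntimeError(
            f"mapping panel incomplete after {max_meioses} meioses: {got}"
        )
    only_line = [lc_ for lc_ in config.lines if lc_.name == lc.name]
    sub = dataclasses.replace(config, lines=only_line)
    return _finalize(individuals, {lc.name: fg}, sub, seed)


def _finalize(individuals, founders, config, seed) -> tuple:
    any_founder = next(iter(founders.values()))
    vt = emit_genotype_calls(individuals, any_founder, config.reads, seed)
    meta = pd.DataFrame(
        {
            "sample_id": [i.sample_id for i in individuals],
            "sex": [i.sex for i in individuals],
            "ploidy": [i.ploidy for i in individuals],
            "colony": [i.colony for i in individuals],
            "clonal_line": [i.clonal_line for i in individuals],
        }
    )
    tracts = pd.DataFrame(
        [
            {
                "sample_id": ind.sample_id,
                "chrom": c,
                "start": s,
                "end": e,
                "allele": a,
            }
            for ind in individuals
            for (c, s, e, a) in ind.loh_tracts
        ],
        columns=["sample_id", "chrom", "start", "end", "allele"],
    )
    truth = SimTruth(
        individuals=meta.copy(), loh_tracts=tracts, csd=config.csd, founders=founders
    )
    return vt, meta, truth


# ---------------------------------------------------------------------------
# writers


def write_vcf(vt: VariantTable, meta: pd.DataFrame, path) -> None:
    """Write a VariantTable as deterministic VCFv4.2 text (GT, AD, DP)."""
    path = Path(path)
    ploidy = dict(zip(meta["sample_id"], meta["ploidy"]))
    if vt.contig_lengths:
        contigs = dict(vt.contig_lengths)
    else:
        contigs = {}
        for c, p in zip(vt.chrom, vt.pos):
            contigs[c] = max(contigs.get(c, 0), int(p) + 1)
    lines = ["##fileformat=VCFv4.2", "##source=csdscan-simcohort"]
    for c, m in contigs.items():
        lines.append(f"##contig=<ID={c},length={m}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(vt.samples),
    ]
    have_ad = vt.ad is not None
    have_dp = vt.dp is not None
    fmt = "GT" + (":AD" if have_ad else "") + (":DP" if have_dp else "")
    for i in range(vt.n_sites):
        alt = ",".join(vt.alt[i]) if vt.alt[i] else "."
        fields = [
            str(vt.chrom[i]),
            str(int(vt.pos[i])),
            ".",
            str(vt.ref[i]),
            alt,
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for j, s in enumerate(vt.samples):
            g0, g1 = int(vt.gt[i, j, 0]), int(vt.gt[i, j, 1])
            if g0 < 0:
                gt_s = "." if ploidy.get(s) == 1 else "./."
            elif g1 == HAPLOID_PAD:
                gt_s = str(g0)
            else:
                gt_s = f"{g0}/{g1}"
            cell = gt_s
            if have_ad:
                cell += ":" + ",".join(str(int(x)) for x in vt.ad[i, j])
            if have_dp:
                cell += ":" + str(int(vt.dp[i, j]))
            fields.append(cell)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_truth(truth: SimTruth, outdir) -> None:
    """Write truth files: LOH tracts, planted loci and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.loh_tracts.to_csv(outdir / "loh_tracts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for (c, s, e) in truth.csd.loci]
    ).to_csv(outdir / "planted_loci.tsv", sep="\t", index=False)
    echo = [
        f"rule={truth.csd.rule}",
        f"stochastic_male_rate={truth.csd.stochastic_male_rate}",
        f"n_individuals={len(truth.individuals)}",
    ]
    (outdir / "sim_config.txt").write_text("\n".join(echo) + "\n")


def simulate_cohort(config: CohortConfig, seed: int, outdir) -> tuple:
    """Simulate a cohort and write VCF + metadata TSV + truth files.

    Returns the in-memory ``(VariantTable, metadata, SimTruth)`` triple in
    addition to writing ``cohort.vcf``, ``metadata.tsv`` and the truth files
    under ``outdir``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        vt, meta, truth = build_cohort(config, seed)
        write_vcf(vt, meta, outdir / "cohort.vcf")
        write_metadata(meta, outdir / "metadata.tsv")
        write_truth(truth, outdir)
    except OSError as err:
        raise OSError(f"failed writing cohort under {outdir}: {err}") from err
    return vt, meta, truth
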