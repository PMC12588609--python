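"""Packaged worked-example cohorts.

`table1_panel` builds, deterministically, the mapping-panel configuration of
the reference worked example: 19 diploid females all heterozygous at the
candidate locus, 16 diploid males of which 5 retain heterozygosity, 2 are
homozygous for the reference haploid's allele and 9 for the alternate
allele, plus one haploid reference male.  It is constructed synthetically
(genotypes planted, noiseless reads) so the classification path recovers
the expected class counts exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simcohort
from .simcohort import (
    CohortConfig,
    CSDModel,
    FounderGenome,
    Individual,
    MeiosisParams,
    ReadModel,
    SimTruth,
)

LOCUS = ("chr1", 500_000, 546_000)  # 46 kb candidate interval
CHROM_LENGTHS = {"chr1": 1_200_000}


def table1_panel(seed: int = 0):
    """Build the worked-example mapping panel.

    Returns ``(vt, meta, truth)``.  At the locus every female is
    heterozygous; 11 of the 16 diploid males carry a loss of heterozygosity
    covering the full locus (2 homozygous for the reference haploid's
    allele, 9 for the alternate allele); 5 diploid males are heterozygous
    (non-genetic males).  The reference haploid male carries the founder's
    first allele column genome-wide.
    """
    founder = simcohort.simulate_founder(
        CHROM_LENGTHS, snp_density=1e-3, anc_het_fraction=1.0, seed=seed
    )
    csd = CSDModel(loci=[LOCUS], rule="single", stochastic_male_rate=0.0)
    simcohort.plant_csd_locus(founder, csd)
    chrom, locus_start, locus_end = LOCUS
    pos = founder.snp_positions[chrom]
    length = CHROM_LENGTHS[chrom]

    rng = np.random.default_rng(seed + 12345)
    individuals = []

    def diploid(ident, colony, sex, tract=None):
        g = founder.founder_alleles[chrom].copy()
        tracts = []
        if tract is not None:
            start, col = tract
            distal = pos - 1 >= start
            g[distal, 0] = founder.founder_alleles[chrom][distal, col]
            g[distal, 1] = g[distal, 0]
            tracts.append((chrom, start, length, col))
        individuals.append(
            Individual(ident, sex, 2, colony, "A", {chrom: g}, tracts)
        )

    for i in range(19):
        diploid(f"A-f{i + 1:02d}", f"A-c{i % 4 + 1}", "female")
    for i in range(5):  # heterozygous (non-genetic) diploid males
        diploid(f"A-m{i + 1:02d}", f"A-c{i % 4 + 1}", "male")
    # LOH tract starts upstream of the locus so every tract covers it fully;
    # staggered starts make the male intersection strictly smaller than any
    # single tract
    starts = np.sort(rng.integers(300_000, locus_start - 1_000, size=11))
    for i, st in enumerate(starts):
        col = 0 if i < 2 else 1  # 2 males match the reference haploid
        diploid(f"A-m{i + 6:02d}", f"A-c{i % 4 + 1}", "male", tract=(int(st), col))
    hap = Individual(
        "A-hap01",
        "male",
        1,
        "A-c1",
        "A",
        {chrom: founder.founder_alleles[chrom][:, 0].copy()},
        [],
    )
    individuals.append(hap)

    reads = ReadModel(mean_depth=30, depth_dispersion=0.0, base_error=0.0)
    vt = simcohort.emit_genotype_calls(individuals, founder, reads, seed)
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
            {"sample_id": ind.sample_id, "chrom": c, "start": s, "end": e, "allele": a}
            for ind in individuals
            for (c, s, e, a) in ind.loh_tracts
        ],
        columns=["sample_id", "chrom", "start", "end", "allele"],
    )
    truth = SimTruth(
        individuals=meta.copy(), loh_tracts=tracts, csd=csd, founders={"A": founder}
    )
    return vt, meta, truth


def recovery_config() -> CohortConfig:
    """Study conditions for locus-recovery experiments.

    A single mapping line with one planted 50 kb locus, central-fusion
    meiosis with imperfect co-inheritance, no non-genetic diploid males and
    default sequencing noise.
    """
    return CohortConfig(
        csd=CSDModel(loci=[("chr1", 500_000, 550_000)], stochastic_male_rate=0.0),
        meiosis=MeiosisParams(
            crossover_rate=1.0, coinheritance_fidelity=0.97, haploid_male_rate=0.05
        ),
    )
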