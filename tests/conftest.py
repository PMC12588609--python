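import numpy as np
import pandas as pd
import pytest

from csdscan import fixtures, simcohort
from csdscan.variants import HAPLOID_PAD, MISSING, VariantTable


@pytest.fixture(scope="session")
def table1():
    """The worked-example mapping panel (19 F het; males 5 het / 2+9 hom)."""
    return fixtures.table1_panel(seed=0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A cohort with error-free reads and real LOH tracts."""
    cfg = fixtures.recovery_config()
    cfg.reads = simcohort.ReadModel(mean_depth=30, depth_dispersion=0.0, base_error=0.0)
    cfg.meiosis = simcohort.MeiosisParams(
        crossover_rate=1.0, coinheritance_fidelity=0.9, haploid_male_rate=0.05
    )
    return simcohort.build_mapping_panel(cfg, seed=7)


def make_vt(records, samples, ad=None, dp=None, contig_lengths=None):
    """Hand-build a VariantTable from (chrom, pos, ref, alt, genotypes) rows.

    ``genotypes`` per record is a list of per-sample allele pairs, single
    allele ints (haploid), or None (missing).
    """
    chrom, pos, ref, alt, gts = [], [], [], [], []
    for rec in records:
        c, p, r, a, g = rec
        chrom.append(c)
        pos.append(p)
        ref.append(r)
        alt.append(tuple(a) if not isinstance(a, str) else (a,))
        row = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for j, call in enumerate(g):
            if call is None:
                continue
            if isinstance(call, int):
                row[j] = (call, HAPLOID_PAD)
            else:
                row[j] = call
        gts.append(row)
    return VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=alt,
        samples=list(samples),
        gt=np.stack(gts) if gts else np.empty((0, len(samples), 2), np.int16),
        ad=None if ad is None else np.asarray(ad, dtype=np.int32),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        contig_lengths=contig_lengths,
    )


def make_meta(samples, sexes, ploidies, colonies=None, lines=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "sex": sexes,
            "ploidy": ploidies,
            "colony": colonies if colonies is not None else ["c1"] * n,
            "clonal_line": lines if lines is not None else ["A"] * n,
        }
    )
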