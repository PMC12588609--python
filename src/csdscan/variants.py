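"""Genotype matrices from multi-sample VCFs plus site-level quality filters.

The central container is :class:`VariantTable`: a sites x samples matrix of
called allele pairs with per-allele read depths.  Haploid calls occupy a
single allele slot (the second slot holds the :data:`HAPLOID_PAD` sentinel);
heterozygous diploid-coded calls in haploid samples are retained as-is
because one of the filters keys off them (they flag collapsed repeats in the
reference assembly).

Filters implemented here mirror the preprocessing a homozygosity-mapping
analysis of clonal cohorts needs:

* drop sites heterozygous in any haploid male (collapsed-repeat artifacts),
* drop sites with implausible allelic depths (heterozygous calls with a
  minor-depth fraction below 0.25, or homozygous calls with any reads on a
  non-called allele),
* restrict to biallelic SNPs,
* drop sites with excessive missingness.

All filters are idempotent, never reorder sites or samples, and report how
many sites they removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
HAPLOID_PAD = -2

SEXES = ("female", "male")


@dataclass
class FilterReport:
    name: str
    n_input: int
    n_removed: int

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class VariantTable:
    """Sites x samples genotype matrix with allelic depths.

    Attributes
    ----------
    chrom, pos, ref, alt :
        Per-site arrays; ``pos`` is 1-based and strictly increasing within
        each chromosome; ``alt`` holds tuples of alternate alleles.
    samples :
        Sample names, in column order.
    gt :
        ``(n_sites, n_samples, 2)`` int16 allele indices; ``MISSING`` for no
        call, ``HAPLOID_PAD`` in the second slot for single-allele calls.
    ad :
        ``(n_sites, n_samples, k)`` int32 per-allele read depths, ``-1``
        where absent, or ``None`` if the VCF carried no AD.
    dp :
        ``(n_sites, n_samples)`` int32 total depth, ``-1`` missing, or
        ``None``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list
    samples: list
    gt: np.ndarray
    ad: np.ndarray | None = None
    dp: np.ndarray | None = None
    contig_lengths: dict | None = None
    filter_log: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    @property
    def is_missing(self) -> np.ndarray:
        return self.gt[:, :, 0] < 0

    @property
    def is_het(self) -> np.ndarray:
        g0, g1 = self.gt[:, :, 0], self.gt[:, :, 1]
        return (g0 >= 0) & (g1 >= 0) & (g0 != g1)

    @property
    def is_hom(self) -> np.ndarray:
        """Homozygous or hemizygous (single-allele) non-missing call."""
        g0, g1 = self.gt[:, :, 0], self.gt[:, :, 1]
        return (g0 >= 0) & ((g1 == g0) | (g1 == HAPLOID_PAD))

    def take_sites(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        positions = np.flatnonzero(idx) if idx.dtype == bool else idx
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=[self.alt[i] for i in positions],
            gt=self.gt[idx],
            ad=None if self.ad is None else self.ad[idx],
            dp=None if self.dp is None else self.dp[idx],
            filter_log=list(self.filter_log),
        )

    def chroms(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)


def load_metadata(path_or_df) -> pd.DataFrame:
    """Load and validate a sample metadata table.

    Expects columns ``sample_id, sex, ploidy, colony, clonal_line``; sex in
    {female, male}, ploidy in {1, 2}.
    """
    if isinstance(path_or_df, pd.DataFrame):
        meta = path_or_df.copy()
    else:
        meta = pd.read_csv(path_or_df, sep="\t", dtype=str)
    required = ["sample_id", "sex", "ploidy", "colony", "clonal_line"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta["ploidy"] = meta["ploidy"].astype(int)
    if not meta["ploidy"].isin([1, 2]).all():
        raise ValueError("ploidy must be 1 or 2")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unrecognized sex labels: {sorted(bad_sex)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    return meta.reset_index(drop=True)


def load_vcf(path, metadata) -> tuple:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Parameters
    ----------
    path :
        VCF path (plain or bgzipped); must carry GT.  AD/DP are optional;
        their absence disables the depth filters downstream.
    metadata :
        Path to a metadata TSV or a DataFrame (see :func:`load_metadata`).
        Every VCF sample must have exactly one metadata row.

    Returns
    -------
    (VariantTable, DataFrame)
    """
    from cyvcf2 import VCF

    meta = load_metadata(metadata)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    meta_ids = set(meta["sample_id"])
    extra_vcf = [s for s in samples if s not in meta_ids]
    extra_meta = sorted(meta_ids - set(samples))
    if extra_vcf or extra_meta:
        raise ValueError(
            "sample mismatch between VCF and metadata; "
            f"in VCF only: {extra_vcf}; in metadata only: {extra_meta}"
        )
    # metadata rows reordered to VCF column order
    meta = meta.set_index("sample_id").loc[samples].reset_index()

    chroms, poss, refs, alts = [], [], [], []
    gts, ads, dps = [], [], []
    have_ad = have_dp = True
    max_alleles = 2
    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(tuple(v.ALT))
        max_alleles = max(max_alleles, 1 + len(v.ALT))
        row = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for j, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1]]  # last element is phased flag
            if len(alleles) == 1:
                row[j, 0] = alleles[0] if alleles[0] >= 0 else MISSING
                row[j, 1] = HAPLOID_PAD if alleles[0] >= 0 else MISSING
            else:
                a0, a1 = alleles[0], alleles[1]
                if a0 < 0 or a1 < 0:
                    row[j] = MISSING
                else:
                    row[j, 0], row[j, 1] = a0, a1
        gts.append(row)
        try:
            ad = v.format("AD") if have_ad else None
        except KeyError:
            ad = None
        if ad is None:
            have_ad = False
        else:
            ads.append(np.asarray(ad, dtype=np.int32))
        try:
            dp = v.format("DP") if have_dp else None
        except KeyError:
            dp = None
        if dp is None:
            have_dp = False
        else:
            dps.append(np.asarray(dp, dtype=np.int32).reshape(-1))

    n_sites = len(poss)
    gt = (
        np.stack(gts)
        if n_sites
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    ad_arr = None
    if have_ad and n_sites:
        ad_arr = np.full((n_sites, len(samples), max_alleles), -1, dtype=np.int32)
        for i, a in enumerate(ads):
            k = min(a.shape[1], max_alleles)
            ad_arr[i, :, :k] = a[:, :k]
        ad_arr[ad_arr < 0] = -1
    dp_arr = None
    if have_dp and n_sites:
        dp_arr = np.stack(dps)
        dp_arr[dp_arr < 0] = -1
    if not have_ad:
        log.warning("VCF has no AD field: allelic-depth filters unavailable")
    contig_lengths = None
    try:
        if vcf.seqnames and vcf.seqlens:
            contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        contig_lengths = None
    vt = VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=alts,
        samples=samples,
        gt=gt,
        ad=ad_arr,
        dp=dp_arr,
        contig_lengths=contig_lengths,
    )
    return vt, meta


def _apply(vt: VariantTable, keep: np.ndarray, name: str) -> tuple:
    report = FilterReport(name, vt.n_sites, int((~keep).sum()))
    out = vt.take_sites(keep)
    out.filter_log.append(report)
    return out, report


def filter_haploid_het_sites(vt: VariantTable, meta: pd.DataFrame) -> tuple:
    """Remove sites at which any haploid sample is called heterozygous.

    A true haploid cannot be heterozygous; such calls indicate repeats
    collapsed in the reference assembly.  With no haploid samples present the
    table is returned unchanged (with a warning).
    """
    hap_cols = [vt.sample_index(s) for s, p in zip(meta["sample_id"], meta["ploidy"]) if p == 1]
    if not hap_cols:
        warnings.warn("no haploid samples: haploid-het filter is a no-op")
        return _apply(vt, np.ones(vt.n_sites, dtype=bool), "haploid_het")
    bad = vt.is_het[:, hap_cols].any(axis=1)
    return _apply(vt, ~bad, "haploid_het")


def filter_allelic_depth(vt: VariantTable, min_het_minor_fraction: float = 0.25) -> tuple:
    """Remove sites with allele depths inconsistent with their calls.

    A site fails if any heterozygous-called sample has
    ``minor_depth / (depth of the two called alleles) < min_het_minor_fraction``,
    or any homozygous-called sample has nonzero depth on a non-called allele.
    Samples with missing calls (or missing AD) are ignored per site.  The
    minor-fraction denominator is the summed depth of the two called alleles,
    not DP, so the statistic is a function of the genotype call.
    """
    if vt.ad is None:
        raise ValueError("allelic-depth filter requires AD in the VCF")
    n, s, k = vt.ad.shape
    ad = np.where(vt.ad < 0, 0, vt.ad)
    g0 = np.clip(vt.gt[:, :, 0], 0, k - 1)
    g1 = np.clip(vt.gt[:, :, 1], 0, k - 1)
    d0 = np.take_along_axis(ad, g0[:, :, None], axis=2)[:, :, 0]
    d1 = np.take_along_axis(ad, g1[:, :, None], axis=2)[:, :, 0]

    het = vt.is_het
    tot = d0 + d1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.minimum(d0, d1) / np.where(tot > 0, tot, 1)
    bad_het = het & (tot > 0) & (frac < min_het_minor_fraction)

    hom = vt.is_hom
    total_ad = ad.sum(axis=2)
    bad_hom = hom & (total_ad - d0 > 0)  # hom/hemizygous: d0 is the called allele's depth

    bad = (bad_het | bad_hom).any(axis=1)
    return _apply(vt, ~bad, "allelic_depth")


def restrict_to_biallelic_snps(vt: VariantTable) -> tuple:
    """Keep single-base sites with at most two alleles observed in calls."""
    keep = np.ones(vt.n_sites, dtype=bool)
    for i in range(vt.n_sites):
        if len(vt.ref[i]) != 1 or any(len(a) != 1 for a in vt.alt[i]):
            keep[i] = False
            continue
        g = vt.gt[i]
        observed = np.unique(g[g >= 0])
        if observed.size > 2:
            keep[i] = False
    return _apply(vt, keep, "biallelic_snp")


def filter_missingness(vt: VariantTable, max_missing_frac: float = 0.2) -> tuple:
    """Drop sites with more than ``max_missing_frac`` missing calls."""
    frac = vt.is_missing.mean(axis=1) if vt.n_samples else np.zeros(vt.n_sites)
    return _apply(vt, frac <= max_missing_frac, "missingness")


def write_site_mask(vt: VariantTable, path) -> None:
    """Write the retained sites as a TSV (chrom, pos)."""
    pd.DataFrame({"chrom": vt.chrom, "pos": vt.pos}).to_csv(path, sep="\t", index=False)


def write_filter_report(vt: VariantTable, path) -> None:
    rows = [
        {"filter": r.name, "n_input": r.n_input, "n_removed": r.n_removed, "n_output": r.n_output}
        for r in vt.filter_log
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
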