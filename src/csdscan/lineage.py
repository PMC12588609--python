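"""Ancestral heterozygosity within a clonal line.

All members of a clonal line descend asexually from one diploid founder, so
a site segregating in the line today was heterozygous in that founder.  A
site is flagged putatively ancestrally heterozygous when at least one
diploid line member is heterozygous and every other non-missing diploid is
either heterozygous for the same two alleles or homozygous for one of them.
Haploid samples carry a single allele by construction and are excluded from
the test; missing calls are ignored rather than vetoing a site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import windows
from .variants import VariantTable


@dataclass
class AncestralHetMask:
    """Per-site ancestral-heterozygosity flags for one clonal line."""

    clonal_line: str
    chrom: np.ndarray
    pos: np.ndarray
    flag: np.ndarray  # bool per site
    alleles: np.ndarray  # (n,2) int16, ancestral pair; -1 where unflagged

    @property
    def n_flagged(self) -> int:
        return int(self.flag.sum())


def call_ancestral_het(
    vt: VariantTable,
    meta: pd.DataFrame,
    clonal_line: str,
    min_diploids: int = 2,
) -> AncestralHetMask:
    """Flag putatively ancestrally heterozygous sites in one clonal line.

    A site is flagged iff, among the line's diploids with non-missing calls
    (at least ``min_diploids`` of them), at least one is heterozygous, all
    heterozygotes share the same unordered allele pair, and every homozygote
    carries one of those two alleles.
    """
    rows = meta[(meta["clonal_line"] == clonal_line) & (meta["ploidy"] == 2)]
    if rows.empty:
        raise ValueError(f"clonal line {clonal_line!r} has no diploid samples")
    cols = [vt.sample_index(s) for s in rows["sample_id"]]

    g = vt.gt[:, cols, :]  # (n_sites, n_dip, 2)
    called = g[:, :, 0] >= 0
    lo = np.minimum(g[:, :, 0], g[:, :, 1])
    hi = np.maximum(g[:, :, 0], g[:, :, 1])
    het = called & (lo != hi)

    big = np.int16(np.iinfo(np.int16).max)
    lo_f = np.where(het, lo, big)
    hi_f = np.where(het, hi, big)
    pair_lo = lo_f.min(axis=1)
    pair_hi = hi_f.min(axis=1)
    # all heterozygotes must share one unordered pair
    same_pair = (
        np.where(het, lo, pair_lo[:, None]) == pair_lo[:, None]
    ).all(axis=1) & (
        np.where(het, hi, pair_hi[:, None]) == pair_hi[:, None]
    ).all(axis=1)

    hom = called & (lo == hi)
    hom_ok = (
        ~hom
        | (np.where(hom, lo, pair_lo[:, None]) == pair_lo[:, None])
        | (np.where(hom, lo, pair_hi[:, None]) == pair_hi[:, None])
    ).all(axis=1)

    n_called = called.sum(axis=1)
    flag = (het.any(axis=1)) & same_pair & hom_ok & (n_called >= min_diploids)

    alleles = np.full((vt.n_sites, 2), -1, dtype=np.int16)
    alleles[flag, 0] = pair_lo[flag]
    alleles[flag, 1] = pair_hi[flag]
    return AncestralHetMask(
        clonal_line=clonal_line,
        chrom=vt.chrom.copy(),
        pos=vt.pos.copy(),
        flag=flag,
        alleles=alleles,
    )


def windowed_site_counts(
    mask: AncestralHetMask,
    window_bp: int,
    step_bp: int,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Count flagged sites in sliding windows (0-based half-open).

    ``chrom_lengths`` defaults to the maximum observed position per
    chromosome.
    """
    out = []
    chrom_order = list(dict.fromkeys(mask.chrom))
    for c in chrom_order:
        on_c = mask.chrom == c
        pos0 = mask.pos[on_c & mask.flag] - 1
        length = (
            chrom_lengths[c]
            if chrom_lengths is not None
            else int(mask.pos[on_c].max()) if on_c.any() else 0
        )
        for start, end in windows(int(length), window_bp, step_bp):
            n = int(((pos0 >= start) & (pos0 < end)).sum())
            out.append({"chrom": c, "start": int(start), "end": int(end), "count": n})
    return pd.DataFrame(out, columns=["chrom", "start", "end", "count"])


def write_mask(mask: AncestralHetMask, path) -> None:
    """Write the flagged sites as TSV (chrom, pos, allele1, allele2)."""
    df = pd.DataFrame(
        {
            "chrom": mask.chrom[mask.flag],
            "pos": mask.pos[mask.flag],
            "allele1": mask.alleles[mask.flag, 0],
            "allele2": mask.alleles[mask.flag, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_windowed_bedgraph(counts: pd.DataFrame, path) -> None:
    counts[["chrom", "start", "end", "count"]].to_csv(
        path, sep="\t", index=False, header=False
    )
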