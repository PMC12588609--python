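"""Windowed nucleotide diversity and haplotype divergence tracks.

Loci under balancing selection (as complementary-sex-determination loci
should be) are expected to accumulate many old, divergent alleles, visible
as a peak of nucleotide diversity when genotypes are pooled across clonal
lines.  Per site the mean pairwise difference is

    D = n/(n-1) * (1 - sum_i p_i^2)

with ``n`` called allele copies and ``p_i`` the allele frequencies; the
windowed statistic divides the summed per-site D by the window width in bp.
A companion operation counts per-window differences between pre-aligned
haplotype sequences and a reference haplotype, as used to display the
divergent alleles recovered from haploid-male assemblies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import windows
from .variants import VariantTable


def site_diversity(allele_counts) -> float:
    """Unbiased mean pairwise difference at one site.

    ``allele_counts`` are the per-allele copy counts of the called alleles.
    Equals the average over all C(n,2) pairs of copies of the probability
    that the pair differs; 0 at monoallelic sites.  Requires n >= 2.
    """
    counts = np.asarray(allele_counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("site diversity needs at least two allele copies")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _pooled_counts(vt: VariantTable, meta: pd.DataFrame, lines) -> np.ndarray:
    """Per-site allele counts pooled over the selected lines' diploids."""
    rows = meta[meta["ploidy"] == 2]
    if lines is not None:
        rows = rows[rows["clonal_line"].isin(list(lines))]
    if rows.empty:
        raise ValueError("no diploid samples in the selected lines")
    cols = [vt.sample_index(s) for s in rows["sample_id"]]
    g = vt.gt[:, cols, :].astype(np.int64)  # (sites, samples, 2)
    n_alleles = max(2, int(g.max()) + 1 if g.size else 2)
    counts = np.zeros((vt.n_sites, n_alleles), dtype=np.int64)
    flat = g.reshape(vt.n_sites, -1)
    for a in range(n_alleles):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts


def site_diversity_track(vt: VariantTable, meta: pd.DataFrame, lines=None) -> np.ndarray:
    """Per-site D over pooled diploid genotypes; NaN where <2 copies called."""
    counts = _pooled_counts(vt, meta, lines)
    n = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = (counts / np.where(n > 0, n, 1)[:, None]) ** 2
        d = n / (n - 1) * (1.0 - p2.sum(axis=1))
    d[n < 2] = np.nan
    return d


def windowed_pi(
    vt: VariantTable,
    meta: pd.DataFrame,
    lines=None,
    window_bp: int = 5_000,
    step_bp: int = 1_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity in sliding windows (differences per bp).

    Allele counts are pooled across the selected lines' diploid genotypes
    (each diploid contributes two copies; missing calls are dropped per
    site).  The window statistic is the summed per-site D over variant
    sites in the window divided by the window width in bp, so windows with
    no segregating sites report 0.
    """
    d = site_diversity_track(vt, meta, lines)
    d = np.where(np.isfinite(d), d, 0.0)
    if chrom_lengths is None:
        chrom_lengths = vt.contig_lengths
    out = []
    for c in dict.fromkeys(vt.chrom):
        on_c = vt.chrom == c
        pos0 = vt.pos[on_c] - 1
        vals = d[on_c]
        length = (
            chrom_lengths[c]
            if chrom_lengths is not None
            else (int(vt.pos[on_c].max()) if on_c.any() else 0)
        )
        for start, end in windows(int(length), window_bp, step_bp):
            in_w = (pos0 >= start) & (pos0 < end)
            width = end - start
            out.append(
                {
                    "chrom": c,
                    "start": int(start),
                    "end": int(end),
                    "pi": float(vals[in_w].sum()) / width if width else 0.0,
                    "n_sites": int((vals[in_w] > 0).sum()),
                }
            )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "pi", "n_sites"])


# ---------------------------------------------------------------------------
# haplotype divergence


def load_haplotypes_fasta(path) -> dict:
    """Read aligned haplotypes from FASTA into a name -> sequence dict."""
    from Bio import SeqIO

    haps = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in haps.values()}
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes")
    if len(lengths) != 1:
        raise ValueError("haplotypes must be aligned to equal length")
    return haps


def haplotype_diff_windows(
    haps: dict,
    reference_name: str,
    window_bp: int = 100,
    count_gap_vs_base: bool = True,
) -> pd.DataFrame:
    """Count per-window differences of each haplotype against a reference.

    Sequences must be pre-aligned to the reference coordinate frame
    (equal lengths over {A,C,G,T,N,-}).  Positions with N in either
    sequence are skipped; gap-vs-gap columns are skipped; gap-vs-base
    columns count as differences when ``count_gap_vs_base`` (the default),
    else are skipped.  Windows are non-overlapping.
    """
    if reference_name not in haps:
        raise KeyError(f"reference {reference_name!r} not among haplotypes")
    ref = np.frombuffer(haps[reference_name].encode(), dtype="S1")
    out = []
    for name, seq in haps.items():
        if name == reference_name:
            continue
        if len(seq) != ref.size:
            raise ValueError(f"haplotype {name!r} length differs from reference")
        alt = np.frombuffer(seq.encode(), dtype="S1")
        skip = (ref == b"N") | (alt == b"N") | ((ref == b"-") & (alt == b"-"))
        diff = (ref != alt) & ~skip
        if not count_gap_vs_base:
            diff &= ~((ref == b"-") | (alt == b"-"))
        for start in range(0, ref.size, window_bp):
            end = min(start + window_bp, ref.size)
            out.append(
                {
                    "haplotype": name,
                    "start": start,
                    "end": end,
                    "n_diff": int(diff[start:end].sum()),
                }
            )
    return pd.DataFrame(out, columns=["haplotype", "start", "end", "n_diff"])


def peak_overlap_report(
    pi_track: pd.DataFrame,
    candidate: tuple | None,
    quantile: float = 0.999,
) -> dict:
    """Locate the diversity peak and test overlap with a candidate interval.

    Reports the argmax window, whether it intersects ``candidate``
    (``(chrom, start, end)``), and the contiguous run of windows around the
    argmax exceeding the genome-wide ``quantile`` of window values.
    """
    if pi_track.empty:
        return {"peak": None, "overlaps_candidate": False, "peak_interval": None}
    values = pi_track["pi"].to_numpy()
    i_max = int(np.nanargmax(values))
    peak = pi_track.iloc[i_max]
    thr = float(np.nanquantile(values, quantile))
    overlaps = False
    if candidate is not None:
        c, s, e = candidate
        overlaps = (
            peak["chrom"] == c and peak["start"] < e and peak["end"] > s
        )
    sub = pi_track[pi_track["chrom"] == peak["chrom"]].sort_values("start")
    above = (sub["pi"] >= thr).to_numpy()
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    k = int(np.flatnonzero(starts == peak["start"])[0])
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi + 1 < len(sub) and above[hi + 1]:
        hi += 1
    interval = None
    # a flat track has no peak to report
    if above[k] and values[i_max] > float(np.nanmin(values)):
        interval = (str(peak["chrom"]), int(starts[lo]), int(ends[hi]))
    return {
        "peak": (str(peak["chrom"]), int(peak["start"]), int(peak["end"]), float(peak["pi"])),
        "threshold": thr,
        "overlaps_candidate": bool(overlaps),
        "peak_interval": interval,
    }
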