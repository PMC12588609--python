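"""Loss-of-heterozygosity calling, segmentation, and copy-number checks.

A loss of heterozygosity (LOH) is an ancestrally heterozygous SNP that has
become homozygous in a focal diploid.  Per-sample LOH flags are segmented
into runs (rule-based run-length segmentation with a configurable error
tolerance rather than an HMM: the contract is the segments themselves and a
transparent rule keeps every boundary auditable), intersected across
diploid males to find the region whose homozygosity best separates the
sexes, assigned an allele identity against a reference haploid male, and
classified as copy-neutral or deleted from normalized read depth
(copy-neutral LOH is the signature of crossover-associated heterozygosity
loss under central-fusion automixis; deletions halve relative depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import AncestralHetMask
from .variants import HAPLOID_PAD, VariantTable


@dataclass
class LOHSegment:
    """One sample's contiguous run of lost heterozygosity."""

    sample_id: str
    chrom: str
    start: int  # 0-based half-open; bounds coincide with flanking SNPs
    end: int
    n_snps: int
    allele_class: str | None = None  # allele1 | allele2 | mixed
    mean_normalized_depth: float | None = None
    depth_class: str | None = None  # copy_neutral | deletion | ambiguous

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


def loh_mask(vt: VariantTable, anc_mask: AncestralHetMask, sample: str) -> tuple:
    """Per-site LOH flags for one diploid sample.

    Returns ``(loh, artifact)`` boolean arrays over all sites of ``vt``:
    ``loh`` is true exactly at ancestrally heterozygous sites where the
    sample's non-missing call is homozygous for one of the two ancestral
    alleles; homozygosity for a third allele is flagged in ``artifact``
    as a putative genotyping error instead.
    """
    j = vt.sample_index(sample)
    g = vt.gt[:, j, :]
    if (g[:, 1] == HAPLOID_PAD).any():
        raise ValueError(f"sample {sample!r} has haploid calls; LOH needs a diploid")
    hom = (g[:, 0] >= 0) & (g[:, 0] == g[:, 1])
    anc = anc_mask.flag
    matches = (g[:, 0] == anc_mask.alleles[:, 0]) | (g[:, 0] == anc_mask.alleles[:, 1])
    loh = anc & hom & matches
    artifact = anc & hom & ~matches
    return loh, artifact


def sample_state(vt: VariantTable, anc_mask: AncestralHetMask, sample: str) -> np.ndarray:
    """Call state over ancestrally het sites: 1 LOH-hom, 0 het, -1 missing/other."""
    loh, _ = loh_mask(vt, anc_mask, sample)
    j = vt.sample_index(sample)
    het = vt.is_het[:, j]
    state = np.full(vt.n_sites, -1, dtype=np.int8)
    state[anc_mask.flag & het] = 0
    state[loh] = 1
    return state


def segment_runs(
    state: np.ndarray,
    positions: np.ndarray,
    min_snps: int = 10,
    max_err: int = 1,
    sample_id: str = "",
    chrom: str = "",
) -> list:
    """Segment per-site states into maximal runs of homozygosity.

    ``state`` holds 1 (homozygous/LOH), 0 (heterozygous) or -1 (missing,
    skipped) per site at sorted ``positions`` (1-based) on one chromosome.
    A run may absorb at most ``max_err`` interrupting heterozygous sites
    and must contain at least ``min_snps`` homozygous sites.  The reported
    interval spans the first to the last homozygous SNP of the run,
    half-open at ``last + 1``; trailing heterozygous sites are never
    included.
    """
    if min_snps < 1 or max_err < 0:
        raise ValueError("require min_snps >= 1 and max_err >= 0")
    keep = state >= 0
    st = state[keep]
    pos = np.asarray(positions)[keep]
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    segments = []
    n = st.size
    i = 0
    while i < n:
        if st[i] != 1:
            i += 1
            continue
        # extend a run from the i-th hom site, tolerating up to max_err hets
        errs = 0
        last_hom = i
        j = i + 1
        while j < n:
            if st[j] == 1:
                last_hom = j
            else:
                errs += 1
                if errs > max_err:
                    break
            j += 1
        n_hom = int((st[i : last_hom + 1] == 1).sum())
        if n_hom >= min_snps:
            segments.append(
                LOHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(pos[i] - 1),
                    end=int(pos[last_hom]),
                    n_snps=n_hom,
                )
            )
        i = last_hom + 1
    return segments


def call_sample_segments(
    vt: VariantTable,
    anc_mask: AncestralHetMask,
    sample: str,
    min_snps: int = 10,
    max_err: int = 1,
) -> list:
    """Run-length LOH segmentation for one diploid sample, per chromosome."""
    state = sample_state(vt, anc_mask, sample)
    segments = []
    for c in dict.fromkeys(vt.chrom):
        on_c = vt.chrom == c
        segments.extend(
            segment_runs(
                state[on_c],
                vt.pos[on_c],
                min_snps=min_snps,
                max_err=max_err,
                sample_id=sample,
                chrom=c,
            )
        )
    return segments


def intersect_loh_across_males(
    segments: list,
    female_hom_pos: dict | None = None,
) -> tuple:
    """Find the interval covered by LOH segments in the most diploid males.

    ``segments`` is a flat list of :class:`LOHSegment` across samples;
    ``female_hom_pos`` optionally maps chromosome -> 1-based positions of
    ancestrally heterozygous SNPs at which any diploid female is homozygous
    (such positions cannot belong to a locus whose heterozygosity is
    required for female development, so they split candidate intervals).

    Returns ``(chrom, start, end, support, member_ids)`` for the leftmost
    maximal-support interval, or ``None`` if there are no segments.
    """
    if not segments:
        return None
    best = None
    for c in dict.fromkeys(s.chrom for s in segments):
        segs = [s for s in segments if s.chrom == c]
        bounds = set()
        for s in segs:
            bounds.add(s.start)
            bounds.add(s.end)
        excl = np.asarray(
            female_hom_pos.get(c, []) if female_hom_pos else [], dtype=np.int64
        )
        for p in excl:
            bounds.add(int(p) - 1)
            bounds.add(int(p))
        bounds = sorted(bounds)
        prev_hi = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if excl.size and np.any((excl - 1 >= lo) & (excl - 1 < hi)):
                prev_hi = None  # a female is homozygous inside: excluded
                continue
            support = sum(1 for s in segs if s.start <= lo and s.end >= hi)
            if support == 0:
                prev_hi = None
                continue
            if best is not None and support == best[3] and c == best[0] and lo == prev_hi == best[2]:
                best[2] = hi  # extend a contiguous equal-support run
            elif best is None or support > best[3]:
                best = [c, lo, hi, support]
            prev_hi = hi
    if best is None:
        return None
    c, lo, hi, support = best
    members = sorted(
        {s.sample_id for s in segments if s.chrom == c and s.start < hi and s.end > lo}
    )
    return (c, lo, hi, support, members)


def assign_allele(
    vt: VariantTable,
    chrom: str,
    start: int,
    end: int,
    sample: str,
    reference_haploid: str,
    min_agreement: float = 0.9,
    site_flags: np.ndarray | None = None,
) -> str:
    """Classify a sample's genotype over an interval against a reference haploid.

    Homozygous calls matching the reference haploid's allele count toward
    ``allele1``, the alternate allele toward ``allele2``; the sample-level
    class is the majority over homozygous sites when agreement reaches
    ``min_agreement``, else ``mixed``.  Samples heterozygous at every
    informative site are ``heterozygous``; samples with no informative
    calls are ``unclassified``.  ``site_flags`` (typically the line's
    ancestral-heterozygosity flags) restricts the classification to
    informative SNPs; without it, sites homozygous in the whole line would
    trivially match the reference haploid and drown out the signal.
    """
    j = vt.sample_index(sample)
    r = vt.sample_index(reference_haploid)
    in_iv = (vt.chrom == chrom) & (vt.pos - 1 >= start) & (vt.pos - 1 < end)
    if site_flags is not None:
        in_iv &= site_flags
    ref_allele = vt.gt[:, r, 0]
    usable = in_iv & (ref_allele >= 0)
    if not usable.any():
        raise ValueError(
            f"reference haploid {reference_haploid!r} has no calls in "
            f"{chrom}:{start}-{end}"
        )
    g = vt.gt[:, j, :]
    hom = usable & (g[:, 0] >= 0) & (g[:, 0] == g[:, 1])
    het = usable & (g[:, 0] >= 0) & (g[:, 1] >= 0) & (g[:, 0] != g[:, 1])
    n_match = int((hom & (g[:, 0] == ref_allele)).sum())
    n_alt = int((hom & (g[:, 0] != ref_allele)).sum())
    if n_match + n_alt == 0:
        return "heterozygous" if het.any() else "unclassified"
    frac = n_match / (n_match + n_alt)
    if frac >= min_agreement:
        return "allele1"
    if 1 - frac >= min_agreement:
        return "allele2"
    return "mixed"


def classify_cohort_at_locus(
    vt: VariantTable,
    meta: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    reference_haploid: str,
    site_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate per-diploid genotype classes over an interval.

    Returns a DataFrame (sample_id, sex, class) mirroring the layout of a
    mapping table: heterozygous / homozygous allele 1 / homozygous allele 2
    per diploid female and diploid male.
    """
    rows = []
    for _, r in meta[meta["ploidy"] == 2].iterrows():
        cls = assign_allele(
            vt, chrom, start, end, r["sample_id"], reference_haploid,
            site_flags=site_flags,
        )
        rows.append({"sample_id": r["sample_id"], "sex": r["sex"], "class": cls})
    return pd.DataFrame(rows)


def class_counts(classes: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-sample classes into the sexes x classes count table."""
    order = ["heterozygous", "allele1", "allele2", "mixed", "unclassified"]
    tab = (
        classes.groupby(["sex", "class"]).size().unstack(fill_value=0)
    )
    for c in order:
        if c not in tab.columns:
            tab[c] = 0
    return tab[order]


# ---------------------------------------------------------------------------
# depth


def normalized_depth(vt: VariantTable) -> np.ndarray:
    """Per-site, per-sample depth divided by the sample's genome-wide median.

    Normalization uses only the sites present in ``vt`` (i.e. sites passing
    the upstream filters); missing depths become NaN.
    """
    if vt.dp is None:
        raise ValueError("depth classification requires DP")
    dp = vt.dp.astype(float)
    dp[dp < 0] = np.nan
    med = np.nanmedian(dp, axis=0)
    if np.any(~(med > 0)):
        bad = [vt.samples[i] for i in np.flatnonzero(~(med > 0))]
        raise ValueError(f"non-positive median depth for samples: {bad}")
    return dp / med


def depth_classify(
    ndepth: np.ndarray,
    vt: VariantTable,
    segment: LOHSegment,
    neutral_band: tuple = (0.8, 1.2),
    deletion_band: tuple = (0.3, 0.7),
    min_sites: int = 5,
) -> LOHSegment:
    """Classify a segment as copy-neutral, deleted, or ambiguous.

    The mean normalized depth of the segment's sample across sites inside
    the segment is compared against the two bands; fewer than ``min_sites``
    sites with depth gives ``ambiguous``.  Returns the segment with
    ``mean_normalized_depth`` and ``depth_class`` filled in.
    """
    j = vt.sample_index(segment.sample_id)
    in_iv = (
        (vt.chrom == segment.chrom)
        & (vt.pos - 1 >= segment.start)
        & (vt.pos - 1 < segment.end)
    )
    vals = ndepth[in_iv, j]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_sites:
        segment.mean_normalized_depth = float(vals.mean()) if vals.size else np.nan
        segment.depth_class = "ambiguous"
        return segment
    mean = float(vals.mean())
    segment.mean_normalized_depth = mean
    if neutral_band[0] <= mean <= neutral_band[1]:
        segment.depth_class = "copy_neutral"
    elif deletion_band[0] <= mean <= deletion_band[1]:
        segment.depth_class = "deletion"
    else:
        segment.depth_class = "ambiguous"
    return segment


# ---------------------------------------------------------------------------
# ordinal coordinates


def ordinalize_sites(anc_mask: AncestralHetMask, chrom: str) -> pd.DataFrame:
    """Rank the ancestrally het SNPs of one chromosome 1..K by position."""
    on_c = (anc_mask.chrom == chrom) & anc_mask.flag
    pos = anc_mask.pos[on_c]
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ordinal": np.arange(1, pos.size + 1)})


def ordinalize_segments(segments: list, anc_mask: AncestralHetMask) -> pd.DataFrame:
    """Re-express segments in ordinal SNP coordinates (half-open ranks).

    A segment covering the SNPs ranked ``a..b`` maps to ``[a, b+1)``.  This
    makes per-sample losses comparable across regions of unequal SNP
    density, as in stacked-bar LOH displays.
    """
    rows = []
    for c in dict.fromkeys(s.chrom for s in segments):
        ranks = ordinalize_sites(anc_mask, c)
        pos = ranks["pos"].to_numpy()
        for s in segments:
            if s.chrom != c:
                continue
            inside = (pos - 1 >= s.start) & (pos - 1 < s.end)
            if not inside.any():
                continue
            covered = ranks.loc[inside, "ordinal"]
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "chrom": c,
                    "ordinal_start": int(covered.min()),
                    "ordinal_end": int(covered.max()) + 1,
                    "n_snps": s.n_snps,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "ordinal_start", "ordinal_end", "n_snps"]
    )


def segments_to_frame(segments: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "allele_class": s.allele_class,
                "mean_normalized_depth": s.mean_normalized_depth,
                "depth_class": s.depth_class,
            }
            for s in segments
        ],
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "n_snps",
            "allele_class",
            "mean_normalized_depth",
            "depth_class",
        ],
    )
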