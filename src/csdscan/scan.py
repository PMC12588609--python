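"""The CSD-index genome scan and its significance machinery.

The CSD index of a SNP is 0 if any diploid female is homozygous there;
otherwise it equals the proportion of diploid males that are homozygous.
A locus whose heterozygosity triggers female development must be
heterozygous in every female, while diploid males may have lost
heterozygosity there, so high index values point at candidate
complementary-sex-determination loci.

Significance comes from a permutation null that respects colony structure:
sex labels of diploid individuals are shuffled uniformly within each colony
(the shuffle is shared across sites within a permutation, preserving the
between-site correlation of the null), and the per-site p-value is the
proportion of permutations whose index is at least the observed one.
Benjamini-Hochberg step-up FDR control, sliding-window summaries, peak
calling, per-site Fisher exact tests and the cohort-level contingency
statistic complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._util import stream, windows
from .lineage import AncestralHetMask
from .variants import VariantTable


@dataclass
class CandidateLocus:
    """A run of significant windows merged into one candidate interval."""

    chrom: str
    start: int
    end: int
    peak_value: float
    n_windows: int
    peak_index: float | None = None
    support: int | None = None
    sample_classes: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


def _diploid_columns(vt: VariantTable, meta: pd.DataFrame) -> tuple:
    dip = meta[meta["ploidy"] == 2]
    cols = np.array([vt.sample_index(s) for s in dip["sample_id"]], dtype=int)
    is_female = (dip["sex"] == "female").to_numpy()
    colonies = dip["colony"].to_numpy()
    return cols, is_female, colonies


def hom_matrix(vt: VariantTable, cols: np.ndarray) -> np.ndarray:
    """Per-site, per-sample call state: 1 hom, 0 het, -1 missing (int8)."""
    h = np.full((vt.n_sites, len(cols)), -1, dtype=np.int8)
    het = vt.is_het[:, cols]
    hom = vt.is_hom[:, cols]
    h[het] = 0
    h[hom] = 1
    return h


def _index_from_hom(h: np.ndarray, is_female: np.ndarray) -> np.ndarray:
    """Vectorized CSD index over the site axis.

    NaN where no diploid female or no diploid male is genotyped.
    """
    f = h[:, is_female]
    m = h[:, ~is_female]
    female_called = (f >= 0).sum(axis=1)
    male_called = (m >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = (m == 1).sum(axis=1) / male_called
    idx[(f == 1).any(axis=1)] = 0.0
    idx[(female_called == 0) | (male_called == 0)] = np.nan
    return idx


def csd_index(vt: VariantTable, meta: pd.DataFrame, sites=None) -> np.ndarray:
    """Per-site CSD index over the diploids of ``meta``.

    ``sites`` optionally restricts to an index array or boolean mask; the
    returned array always spans the requested sites, NaN where no genotyped
    diploid of either sex is available (such sites are skipped by the scan).
    """
    cols, is_female, _ = _diploid_columns(vt, meta)
    if not is_female.any() or is_female.all():
        raise ValueError("need at least one diploid female and one diploid male")
    h = hom_matrix(vt, cols)
    if sites is not None:
        h = h[np.asarray(sites)]
    return _index_from_hom(h, is_female)


def permutation_null(
    vt: VariantTable,
    meta: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    sites=None,
    add_one: bool = False,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation p-values for the CSD index, shuffling sex within colonies.

    Each permutation redraws the sex labels of diploid individuals by
    shuffling them uniformly within each colony (per-colony sex counts are
    preserved) and recomputes the index at every site under the shared
    shuffled labels.  ``p = #(permuted >= observed) / n_perm``; with
    ``add_one`` the positively biased estimator ``(k+1)/(n_perm+1)`` is
    used, which cannot return zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols, is_female, colonies = _diploid_columns(vt, meta)
    if pd.isna(colonies).any():
        raise ValueError("missing colony labels for diploid samples")
    h = hom_matrix(vt, cols)
    if sites is not None:
        h = h[np.asarray(sites)]
    if observed is None:
        observed = _index_from_hom(h, is_female)

    rng = stream(seed, "permutation")
    colony_members = [np.flatnonzero(colonies == c) for c in pd.unique(colonies)]
    count = np.zeros(h.shape[0], dtype=np.int64)
    labels = is_female.copy()
    for _ in range(n_perm):
        for members in colony_members:
            labels[members] = is_female[members][rng.permutation(members.size)]
        perm_idx = _index_from_hom(h, labels)
        with np.errstate(invalid="ignore"):
            count += (perm_idx >= observed - 1e-12).astype(np.int64)
    if add_one:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    p[~np.isfinite(observed)] = np.nan
    return p


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order of sites preserved.

    NaN inputs propagate to NaN and are excluded from the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qf = np.empty(m)
    qf[order] = np.minimum(ranked, 1.0)
    q[finite] = qf
    return q


@dataclass
class ScanTrack:
    """Per-site scan results over the ancestrally heterozygous SNPs."""

    chrom: np.ndarray
    pos: np.ndarray
    index: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_females: int
    n_males: int
    site_idx: np.ndarray  # indices into the source VariantTable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "index": self.index,
                "p": self.p,
                "q": self.q,
            }
        )


def csd_scan(
    vt: VariantTable,
    meta: pd.DataFrame,
    mask: AncestralHetMask,
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> ScanTrack:
    """Full per-site scan restricted to ancestrally heterozygous SNPs."""
    sites = np.flatnonzero(mask.flag)
    if sites.size == 0:
        raise ValueError("no informative sites: ancestral-het mask is empty")
    cols, is_female, _ = _diploid_columns(vt, meta)
    observed = csd_index(vt, meta, sites=sites)
    p = permutation_null(
        vt, meta, n_perm=n_perm, seed=seed, sites=sites, add_one=add_one,
        observed=observed,
    )
    q = bh_fdr(p)
    return ScanTrack(
        chrom=vt.chrom[sites],
        pos=vt.pos[sites],
        index=observed,
        p=p,
        q=q,
        n_females=int(is_female.sum()),
        n_males=int((~is_female).sum()),
        site_idx=sites,
    )


def windowed_mean(
    chrom: np.ndarray,
    pos: np.ndarray,
    values: np.ndarray,
    window_bp: int = 50_000,
    step_bp: int = 15_000,
    chrom_lengths: dict | None = None,
    statistic: str = "value",
) -> pd.DataFrame:
    """Mean of a per-site statistic in sliding windows.

    Windows tile each chromosome (0-based half-open, clipped at the end);
    windows without finite-valued sites report NaN.
    """
    values = np.asarray(values, dtype=float)
    out = []
    for c in dict.fromkeys(chrom):
        on_c = chrom == c
        pos0 = pos[on_c] - 1
        vals = values[on_c]
        length = (
            chrom_lengths[c]
            if chrom_lengths is not None
            else (int(pos[on_c].max()) if on_c.any() else 0)
        )
        for start, end in windows(int(length), window_bp, step_bp):
            in_w = (pos0 >= start) & (pos0 < end)
            v = vals[in_w]
            v = v[np.isfinite(v)]
            out.append(
                {
                    "chrom": c,
                    "start": int(start),
                    "end": int(end),
                    statistic: float(v.mean()) if v.size else np.nan,
                    "n_sites": int(v.size),
                }
            )
    return pd.DataFrame(out, columns=["chrom", "start", "end", statistic, "n_sites"])


def call_peak(
    track: pd.DataFrame,
    threshold: float = 0.05,
    statistic: str | None = None,
    max_gap: int = 0,
) -> list:
    """Merge maximal runs of consecutive sub-threshold windows into loci.

    ``track`` is a windowed table (as from :func:`windowed_mean`) of mean
    p- or q-values; windows with no sites never contribute.  Each maximal
    run of consecutive significant windows becomes one
    :class:`CandidateLocus` spanning the union of its significant windows,
    with ``peak_value`` the smallest window value inside the run.  A run
    may absorb up to ``max_gap`` interrupting non-significant windows
    (a single miscalled site can lift one window above threshold without
    breaking the underlying signal); the default 0 keeps runs strictly
    consecutive.
    """
    if statistic is None:
        statistic = [c for c in track.columns if c not in ("chrom", "start", "end", "n_sites")][0]
    loci = []
    for c, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        sig = ((sub[statistic] <= threshold) & (sub["n_sites"] > 0)).to_numpy()
        vals = sub[statistic].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n = len(sub)
        i = 0
        while i < n:
            if not sig[i]:
                i += 1
                continue
            gaps = 0
            last_sig = i
            j = i + 1
            while j < n:
                if sig[j]:
                    last_sig = j
                else:
                    gaps += 1
                    if gaps > max_gap:
                        break
                j += 1
            n_sig = int(sig[i : last_sig + 1].sum())
            run_vals = vals[i : last_sig + 1][sig[i : last_sig + 1]]
            loci.append(
                CandidateLocus(
                    chrom=c,
                    start=int(starts[i]),
                    end=int(ends[last_sig]),
                    peak_value=float(run_vals.min()),
                    n_windows=n_sig,
                )
            )
            i = last_sig + 1
    return loci


def attach_peak_index(loci: list, index_track: pd.DataFrame) -> list:
    """Record each candidate's maximal window mean CSD index.

    ``index_track`` is a windowed mean-index table (from
    :func:`windowed_mean` with ``statistic="index"``).  A strong permutation
    signal is necessary but not sufficient to single out the locus: the
    proximal ramp and the distal plateau of crossover-associated
    homozygosity reach significance too, so candidates are disambiguated by
    where male homozygosity is greatest.
    """
    for l in loci:
        # runs are unions of their constituent windows, so only windows fully
        # inside the run belong to it
        sub = index_track[
            (index_track["chrom"] == l.chrom)
            & (index_track["start"] >= l.start)
            & (index_track["end"] <= l.end)
            & (index_track["n_sites"] > 0)
        ]
        l.peak_index = float(sub["index"].max()) if not sub.empty else np.nan
    return loci


def rank_candidates(loci: list) -> list:
    """Rank candidates: smallest peak value, then largest peak index, then
    leftmost position on remaining ties."""
    def key(l):
        idx = l.peak_index if l.peak_index is not None and np.isfinite(l.peak_index) else -1.0
        return (l.peak_value, -idx, l.chrom, l.start)

    return sorted(loci, key=key)


def fisher_homozygosity_scan(
    vt: VariantTable,
    meta: pd.DataFrame,
    sites=None,
) -> tuple:
    """Two-sided Fisher exact test of homozygosity by sex, per site.

    The 2x2 table is [hom, het] x [diploid male, diploid female]; sites with
    no genotyped males or no genotyped females get NaN.  Returns (p, q).
    """
    cols, is_female, _ = _diploid_columns(vt, meta)
    h = hom_matrix(vt, cols)
    if sites is not None:
        h = h[np.asarray(sites)]
    m = h[:, ~is_female]
    f = h[:, is_female]
    hom_m = (m == 1).sum(axis=1)
    het_m = (m == 0).sum(axis=1)
    hom_f = (f == 1).sum(axis=1)
    het_f = (f == 0).sum(axis=1)
    p = np.full(h.shape[0], np.nan)
    for i in range(h.shape[0]):
        if hom_m[i] + het_m[i] == 0 or hom_f[i] + het_f[i] == 0:
            continue
        table = [[hom_m[i], het_m[i]], [hom_f[i], het_f[i]]]
        p[i] = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
    return p, bh_fdr(p)


@dataclass
class ContingencyResult:
    """Pearson chi-square (with and without Yates correction) plus Fisher exact.

    Both corrected and uncorrected statistics are always reported because
    chi-square values reported for small 2x2 tables are often ambiguous
    about the correction used, and the two can bracket a reported value
    without either matching it exactly.
    """

    table: np.ndarray
    chi2: float
    p: float
    chi2_yates: float
    p_yates: float
    df: int
    fisher_p: float

    def summary(self) -> str:
        return (
            f"Pearson chi2={self.chi2:.2f} (p={self.p:.3g}); "
            f"Yates chi2={self.chi2_yates:.2f} (p={self.p_yates:.3g}); "
            f"df={self.df}; Fisher exact p={self.fisher_p:.3g}"
        )


def cohort_contingency(counts) -> ContingencyResult:
    """Chi-square and Fisher exact tests on a 2x2 count table.

    ``counts`` is the 2x2 table, e.g. per-line (haploid, diploid) male
    counts.  Reports the Pearson statistic with df=(r-1)(c-1), both without
    and with the Yates continuity correction, alongside the Fisher exact
    p-value.
    """
    t = np.asarray(counts, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    chi2, p, df, _ = scipy.stats.chi2_contingency(t, correction=False)
    chi2_y, p_y, _, _ = scipy.stats.chi2_contingency(t, correction=True)
    fisher_p = scipy.stats.fisher_exact(t, alternative="two-sided")[1]
    return ContingencyResult(
        table=t,
        chi2=float(chi2),
        p=float(p),
        chi2_yates=float(chi2_y),
        p_yates=float(p_y),
        df=int(df),
        fisher_p=float(fisher_p),
    )
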