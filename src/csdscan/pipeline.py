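"""End-to-end orchestration: filter -> ancestral het -> scan -> LOH -> pi.

`run_pipeline` executes the stages in order on a loaded (or freshly
simulated) cohort, writes every stage's tables under one output directory,
and returns a report dictionary.  Figures are optional and never affect
numeric outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, lineage, loh, scan, simcohort, variants

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters, with mapping-study defaults.

    Window defaults: 50 kb / 15 kb for the scan summary, 5 kb / 1 kb for
    nucleotide diversity, 300 kb / 300 kb for ancestral-het site counts;
    allelic-depth minor fraction 0.25; alpha 0.05 on the FDR-corrected
    track; permutations 1000.
    """

    vcf: str | None = None
    metadata: str | None = None
    simulate: simcohort.CohortConfig | None = None
    # "panel" emulates an ascertained mapping panel (fixed numbers of diploid
    # males/females); "brood" draws colonies of offspring with emergent sexes
    simulate_mode: str = "brood"
    mapping_line: str = "A"
    seed: int = 0
    n_perm: int = 1000
    add_one_p: bool = False
    scan_window_bp: int = 50_000
    scan_step_bp: int = 15_000
    scan_statistic: str = "p"  # per-site statistic averaged per window: p|q|index
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    peak_max_gap: int = 1
    min_het_minor_fraction: float = 0.25
    max_missing_frac: float = 0.2
    min_diploids: int = 2
    anchet_window_bp: int = 300_000
    anchet_step_bp: int = 300_000
    loh_min_snps: int = 10
    loh_max_err: int = 1
    neutral_band: tuple = (0.8, 1.2)
    deletion_band: tuple = (0.3, 0.7)
    pi_window_bp: int = 5_000
    pi_step_bp: int = 1_000
    pi_lines: list | None = None
    reference_haploid: str | None = None  # default: first haploid of the mapping line
    outdir: str = "csdscan_out"
    extra: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        if config.simulate_mode == "panel":
            vt, meta, truth = simcohort.build_mapping_panel(
                config.simulate, config.seed
            )
        else:
            vt, meta, truth = simcohort.build_cohort(config.simulate, config.seed)
        return vt, meta, truth
    if config.vcf is None or config.metadata is None:
        raise ValueError("either simulate or vcf+metadata must be provided")
    vt, meta = variants.load_vcf(config.vcf, config.metadata)
    return vt, meta, None


def apply_filters(vt, meta, config: PipelineConfig):
    """Site filters in order: biallelic, haploid-het, allelic depth, missingness."""
    vt, _ = variants.restrict_to_biallelic_snps(vt)
    vt, _ = variants.filter_haploid_het_sites(vt, meta)
    if vt.ad is not None:
        vt, _ = variants.filter_allelic_depth(vt, config.min_het_minor_fraction)
    else:
        log.warning("no AD: skipping allelic-depth filter")
    vt, _ = variants.filter_missingness(vt, config.max_missing_frac)
    if vt.n_sites == 0:
        raise ValueError("no sites after filtering")
    return vt


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``config.outdir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "mapping_line": config.mapping_line}

    def stage(name, fn, *a, **kw):
        log.info("stage %s", name)
        try:
            return fn(*a, **kw)
        except Exception as err:
            raise StageError(name, err) from err

    vt, meta, truth = stage("load", _load_inputs, config)
    report["n_sites_input"] = vt.n_sites
    report["n_samples"] = vt.n_samples
    if truth is not None:
        simcohort.write_vcf(vt, meta, outdir / "cohort.vcf")
        simcohort.write_metadata(meta, outdir / "metadata.tsv")
        simcohort.write_truth(truth, outdir)

    vt = stage("filter", apply_filters, vt, meta, config)
    variants.write_filter_report(vt, outdir / "filter_report.tsv")
    report["filters"] = [
        {"name": r.name, "n_input": r.n_input, "n_removed": r.n_removed}
        for r in vt.filter_log
    ]
    report["n_sites_filtered"] = vt.n_sites
    log.info("%d sites after filtering", vt.n_sites)

    mask = stage(
        "anchet",
        lineage.call_ancestral_het,
        vt,
        meta,
        config.mapping_line,
        config.min_diploids,
    )
    lineage.write_mask(mask, outdir / "ancestral_het_sites.tsv")
    counts = lineage.windowed_site_counts(
        mask, config.anchet_window_bp, config.anchet_step_bp, vt.contig_lengths
    )
    lineage.write_windowed_bedgraph(counts, outdir / "ancestral_het_counts.bedgraph")
    report["n_informative_sites"] = mask.n_flagged
    if mask.n_flagged == 0:
        report["candidates"] = []
        report["note"] = "no informative sites: scan skipped"
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report

    track = stage(
        "scan",
        scan.csd_scan,
        vt,
        meta,
        mask,
        n_perm=config.n_perm,
        seed=config.seed,
        add_one=config.add_one_p,
    )
    track.to_frame().to_csv(outdir / "csd_scan.tsv", sep="\t", index=False)
    per_site = {"index": track.index, "p": track.p, "q": track.q}[config.scan_statistic]
    wtrack = scan.windowed_mean(
        track.chrom,
        track.pos,
        per_site,
        window_bp=config.scan_window_bp,
        step_bp=config.scan_step_bp,
        chrom_lengths=vt.contig_lengths,
        statistic=config.scan_statistic,
    )
    wtrack.to_csv(outdir / f"windowed_{config.scan_statistic}.bedgraph", sep="\t", index=False)
    # peak calling on the FDR-corrected per-site track by default
    wq = scan.windowed_mean(
        track.chrom,
        track.pos,
        track.q,
        window_bp=config.scan_window_bp,
        step_bp=config.scan_step_bp,
        chrom_lengths=vt.contig_lengths,
        statistic="q",
    )
    widx = scan.windowed_mean(
        track.chrom,
        track.pos,
        track.index,
        window_bp=config.scan_window_bp,
        step_bp=config.scan_step_bp,
        chrom_lengths=vt.contig_lengths,
        statistic="index",
    )
    loci = scan.call_peak(wq, threshold=config.fdr_alpha, max_gap=config.peak_max_gap)
    scan.attach_peak_index(loci, widx)
    loci = scan.rank_candidates(loci)
    fisher_p, fisher_q = stage(
        "fisher", scan.fisher_homozygosity_scan, vt, meta, track.site_idx
    )
    pd.DataFrame(
        {"chrom": track.chrom, "pos": track.pos, "fisher_p": fisher_p, "fisher_q": fisher_q}
    ).to_csv(outdir / "fisher_scan.tsv", sep="\t", index=False)

    # LOH stage
    hap_rows = meta[
        (meta["ploidy"] == 1) & (meta["clonal_line"] == config.mapping_line)
    ]
    reference_haploid = config.reference_haploid
    if reference_haploid is None and not hap_rows.empty:
        reference_haploid = hap_rows["sample_id"].iloc[0]

    dip_males = meta[
        (meta["ploidy"] == 2)
        & (meta["sex"] == "male")
        & (meta["clonal_line"] == config.mapping_line)
    ]["sample_id"].tolist()
    segments = []
    for s in dip_males:
        segments.extend(
            stage(
                "loh",
                loh.call_sample_segments,
                vt,
                mask,
                s,
                config.loh_min_snps,
                config.loh_max_err,
            )
        )
    if vt.dp is not None and segments:
        ndepth = loh.normalized_depth(vt)
        for seg in segments:
            loh.depth_classify(
                ndepth, vt, seg, config.neutral_band, config.deletion_band
            )
    female_hom = _female_hom_positions(vt, meta, mask, config.mapping_line)
    intersection = loh.intersect_loh_across_males(segments, female_hom)
    if reference_haploid is not None:
        for seg in segments:
            seg.allele_class = loh.assign_allele(
                vt, seg.chrom, seg.start, seg.end, seg.sample_id,
                reference_haploid, site_flags=mask.flag,
            )
    loh.segments_to_frame(segments).to_csv(
        outdir / "loh_segments.tsv", sep="\t", index=False
    )
    _write_segments_bed(segments, outdir / "loh_segments.bed")
    for c in dict.fromkeys(vt.chrom):
        odf = loh.ordinalize_segments([s for s in segments if s.chrom == c], mask)
        if not odf.empty:
            odf.to_csv(outdir / f"loh_ordinal_{c}.tsv", sep="\t", index=False)
    report["n_loh_segments"] = len(segments)
    report["n_males_with_loh"] = len({s.sample_id for s in segments})
    report["loh_intersection"] = (
        None
        if intersection is None
        else {
            "chrom": intersection[0],
            "start": intersection[1],
            "end": intersection[2],
            "support": intersection[3],
            "members": intersection[4],
        }
    )
    # the summary class table lives on the LOH-intersection region,
    # where every diploid female is expected to retain heterozygosity
    if intersection is not None and reference_haploid is not None:
        iclasses = loh.classify_cohort_at_locus(
            vt, meta, intersection[0], intersection[1], intersection[2],
            reference_haploid, site_flags=mask.flag,
        )
        iclasses.to_csv(outdir / "intersection_classes.tsv", sep="\t", index=False)
        itab = loh.class_counts(iclasses)
        report["intersection_class_counts"] = {
            str(sex): {k: int(v) for k, v in row.items()}
            for sex, row in itab.iterrows()
        }

    # per-sample classes at the top candidate
    candidates = []
    for locus in loci:
        entry = {
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "peak_q": locus.peak_value,
            "n_windows": locus.n_windows,
        }
        if reference_haploid is not None:
            classes = loh.classify_cohort_at_locus(
                vt, meta, locus.chrom, locus.start, locus.end,
                reference_haploid, site_flags=mask.flag,
            )
            locus.sample_classes = dict(zip(classes["sample_id"], classes["class"]))
            tab = loh.class_counts(classes)
            entry["class_counts"] = {
                str(sex): {k: int(v) for k, v in row.items()}
                for sex, row in tab.iterrows()
            }
        candidates.append(entry)
    report["candidates"] = candidates
    if candidates and reference_haploid is not None:
        top = loci[0]
        classes = loh.classify_cohort_at_locus(
            vt, meta, top.chrom, top.start, top.end, reference_haploid,
            site_flags=mask.flag,
        )
        classes.to_csv(outdir / "candidate_classes.tsv", sep="\t", index=False)
        _write_candidates_bed(loci, outdir / "candidates.bed")

    # diversity stage
    pi = stage(
        "pi",
        diversity.windowed_pi,
        vt,
        meta,
        config.pi_lines,
        config.pi_window_bp,
        config.pi_step_bp,
        vt.contig_lengths,
    )
    pi.to_csv(outdir / "pi_windows.bedgraph", sep="\t", index=False)
    cand_iv = None
    if candidates:
        cand_iv = (candidates[0]["chrom"], candidates[0]["start"], candidates[0]["end"])
    report["pi_peak"] = diversity.peak_overlap_report(pi, cand_iv)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    manifest = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "python": sys.version.split()[0],
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _female_hom_positions(vt, meta, mask, line) -> dict:
    """1-based positions of informative SNPs homozygous in any diploid female."""
    females = meta[
        (meta["ploidy"] == 2) & (meta["sex"] == "female") & (meta["clonal_line"] == line)
    ]["sample_id"]
    cols = [vt.sample_index(s) for s in females]
    if not cols:
        return {}
    hom_any = vt.is_hom[:, cols].any(axis=1) & mask.flag
    out = {}
    for c in dict.fromkeys(vt.chrom):
        pos = vt.pos[(vt.chrom == c) & hom_any]
        if pos.size:
            out[c] = pos
    return out


def _write_segments_bed(segments, path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample_id}\n")


def _write_candidates_bed(loci, path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\tcandidate\t{l.peak_value:.4g}\n")


# ---------------------------------------------------------------------------
# figures


def make_figures(outdir) -> list:
    """Render the report bundle's plots; returns the written paths.

    Reads only the data files the pipeline wrote, so re-running with the
    same inputs reproduces identical plots; numeric outputs are untouched.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written = []

    scan_path = next(iter(outdir.glob("windowed_*.bedgraph")), None)
    if scan_path is not None:
        wt = pd.read_csv(scan_path, sep="\t")
        stat = [c for c in wt.columns if c not in ("chrom", "start", "end", "n_sites")][0]
        chroms = list(dict.fromkeys(wt["chrom"]))
        fig, axes = plt.subplots(
            len(chroms), 1, figsize=(8, 2.2 * len(chroms)), squeeze=False
        )
        cands = None
        bed = outdir / "candidates.bed"
        if bed.exists() and bed.stat().st_size:
            cands = pd.read_csv(
                bed, sep="\t", header=None, names=["chrom", "start", "end", "name", "v"]
            )
        for ax, c in zip(axes[:, 0], chroms):
            sub = wt[wt["chrom"] == c]
            ax.plot(sub["start"] / 1e6, sub[stat], lw=0.8, color="0.2")
            ax.axhline(0.05, color="goldenrod", lw=0.8)
            ax.set_ylabel(f"mean {stat}")
            ax.set_title(c, fontsize=9)
            if cands is not None:
                for _, r in cands[cands["chrom"] == c].iterrows():
                    ax.axvspan(r["start"] / 1e6, r["end"] / 1e6, color="green", alpha=0.25)
        axes[-1, 0].set_xlabel("position (Mb)")
        fig.tight_layout()
        p = outdir / "scan_karyoplot.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    # stacked ordinal LOH matrix
    ord_paths = sorted(outdir.glob("loh_ordinal_*.tsv"))
    fig, ax = plt.subplots(figsize=(8, 3))
    y = 0
    for op in ord_paths:
        odf = pd.read_csv(op, sep="\t")
        for _, r in odf.iterrows():
            ax.plot([r["ordinal_start"], r["ordinal_end"]], [y, y], color="k", lw=2)
            y += 1
    ax.set_xlabel("ordinal SNP position")
    ax.set_ylabel("LOH segments")
    ax.set_title("losses of heterozygosity (ordinal coordinates)")
    p = outdir / "loh_stacked.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    pi_path = outdir / "pi_windows.bedgraph"
    if pi_path.exists():
        pi = pd.read_csv(pi_path, sep="\t")
        chroms = list(dict.fromkeys(pi["chrom"]))
        fig, axes = plt.subplots(
            len(chroms), 1, figsize=(8, 2.2 * len(chroms)), squeeze=False
        )
        for ax, c in zip(axes[:, 0], chroms):
            sub = pi[pi["chrom"] == c]
            ax.plot(sub["start"] / 1e6, sub["pi"], lw=0.8, color="steelblue")
            ax.set_ylabel("pi / bp")
            ax.set_title(c, fontsize=9)
        axes[-1, 0].set_xlabel("position (Mb)")
        fig.tight_layout()
        p = outdir / "pi_track.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
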