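"""Configuration-driven orchestration of the full analysis.

Runs the stages in dependency order — read → hard-filter → polarize →
windowed statistics → CLR scan → evidence combination → segregation →
diversity profile → neutral loci — writing TSV/JSON outputs plus a run
metadata file that echoes the resolved configuration.  Defaults equal the
study's stated parameters (50 kb scan bins, top 5% evidence quantiles,
100 kb / 500 b diversity windows, 1 kb neutral loci every 50 kb with
10 kb CDS and 100 b CNE flanks).
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import popgen, sweep
from .annotation import read_annotation
from .core import DG_GROUPS, apply_hard_filters, polarize_by_outgroup
from .io import read_cohort
from .neutral import build_mask, export_loci, sample_loci
from .segregation import candidate_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved inputs and parameters for one pipeline run."""

    vcf: str
    groups: str
    fasta: str
    gff: Optional[str] = None
    beds: dict = field(default_factory=dict)
    outdir: str = "tailsweep_out"
    seed: int = 0
    # scan
    scan_bin: int = 50_000
    scan_radius: int = 100_000
    scan_grid_step: int = 10_000
    top_quantile: float = 0.05
    n_alpha: int = 15
    evidence_mode: str = "intersection"
    # diversity profile
    div_window: int = 100_000
    div_step: int = 500
    profile_region: Optional[str] = None   # "chrom:start-end", 1-based inclusive
    # segregation
    min_call_rate: float = 1.0
    dominance: bool = False
    # neutral loci
    locus_len: int = 1_000
    locus_spacing: int = 50_000
    cds_flank: int = 10_000
    cne_flank: int = 100
    thin: int = 3
    # population pair for Fst
    fst_pop1: tuple = DG_GROUPS
    fst_pop2: tuple = ("OUTGROUP",)


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into 0-based half-open coords."""
    chrom, span = region.rsplit(":", 1)
    start, end = span.replace(",", "").split("-")
    return chrom, int(start) - 1, int(end)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict also written as JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict = {}
    summary: dict = {"stages": stage_counts}

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("read")
    gm, groups = read_cohort(config.vcf, config.groups)
    reference = Fasta(config.fasta)
    chrom_lengths = {name: len(reference[name]) for name in reference.keys()}
    annotation = read_annotation(config.beds or None, config.gff)
    stage_counts["input_sites"] = gm.n_sites
    stage_counts["samples"] = gm.n_samples

    _stage("hard_filters")
    passed, failed = apply_hard_filters(gm.sites)
    failed_keys = {(s.chrom, s.pos, s.alt) for s, _ in failed}
    keep = [i for i, s in enumerate(gm.sites)
            if (s.chrom, s.pos, s.alt) not in failed_keys]
    gm_f = gm.subset_sites(keep)
    stage_counts["hard_filter_pass"] = len(passed)
    stage_counts["hard_filter_fail"] = len(failed)
    pd.DataFrame(
        [(s.chrom, s.pos, ",".join(map(str, reasons))) for s, reasons in failed],
        columns=["chrom", "pos", "criteria"],
    ).to_csv(outdir / "hard_filter_failures.tsv", sep="\t", index=False)

    _stage("polarize")
    polarized = polarize_by_outgroup(gm_f, groups, focal=DG_GROUPS)
    n_pol = sum(p.polarized for p in polarized)
    stage_counts["polarized_sites"] = n_pol
    stage_counts["unpolarized_sites"] = len(polarized) - n_pol

    _stage("window_stats")
    dg_samples = groups.members(*DG_GROUPS)
    tajd_frames, fst_frames = [], []
    for chrom in gm_f.chroms():
        L = chrom_lengths[chrom]
        tajd_frames.append(popgen.windowed_tajimas_d(
            gm_f, chrom, 0, L, config.scan_bin, samples=dg_samples))
        fst_frames.append(popgen.windowed_fst(
            gm_f, groups, config.fst_pop1, config.fst_pop2, chrom, 0, L,
            config.scan_bin))
    tajd = pd.concat(tajd_frames, ignore_index=True)
    fst = pd.concat(fst_frames, ignore_index=True)
    popgen.write_window_tsv(tajd, outdir / "tajimas_d_windows.tsv")
    popgen.write_window_tsv(fst, outdir / "fst_windows.tsv")

    _stage("clr_scan")
    clr_frames = []
    for chrom in gm_f.chroms():
        chrom_pol = [p for p in polarized if p.site.chrom == chrom]
        grid = list(range(config.scan_grid_step // 2, chrom_lengths[chrom],
                          config.scan_grid_step))
        alpha_grid = sweep.default_alpha_grid(config.scan_radius, config.n_alpha)
        track = sweep.clr_scan(chrom_pol, grid, alpha_grid, config.scan_radius)
        track.insert(0, "chrom", chrom)
        clr_frames.append(track)
    clr = pd.concat(clr_frames, ignore_index=True)

    _stage("combine_evidence")
    bins, thresholds = sweep.combine_evidence(
        clr, fst, tajd, config.scan_bin, config.top_quantile, config.evidence_mode)
    bins, gene_union = sweep.genes_in_bins(bins, annotation)
    sweep.write_scan_outputs(clr, bins, thresholds, outdir)
    stage_counts["candidate_bins"] = len(bins)
    stage_counts["candidate_genes"] = len(gene_union)
    summary["candidate_genes"] = gene_union

    _stage("segregation")
    report = candidate_report(gm_f, groups, annotation, reference,
                              min_call_rate=config.min_call_rate,
                              dominance=config.dominance)
    report.nt_table.to_csv(outdir / "nt_candidates.tsv", sep="\t", index=False)
    report.st_table.to_csv(outdir / "st_candidates.tsv", sep="\t", index=False)
    stage_counts["segregation"] = report.stage_counts

    _stage("diversity_profile")
    if config.profile_region:
        chrom, start, end = parse_region(config.profile_region)
    else:
        chrom = gm_f.chroms()[0]
        start, end = 0, chrom_lengths[chrom]
    profile, mean_pi = popgen.diversity_profile(
        gm_f, chrom, start, end, config.div_window, config.div_step,
        samples=dg_samples, chrom_length=chrom_lengths[chrom])
    popgen.write_window_tsv(profile, outdir / "diversity_profile.tsv")
    stage_counts["diversity_region_mean_pi"] = mean_pi

    _stage("neutral_loci")
    mask = build_mask(annotation, chrom_lengths, config.cds_flank, config.cne_flank)
    mask.to_bed(outdir / "mask.bed")
    loci = sample_loci(mask, chrom_lengths, config.locus_len, config.locus_spacing)
    pd.DataFrame(loci, columns=["chrom", "start", "end"]).to_csv(
        outdir / "neutral_loci.tsv", sep="\t", index=False)
    n_written, n_dropped = export_loci(
        loci, gm_f, reference, gm_f.samples, outdir / "neutral_loci.txt",
        thin=config.thin)
    stage_counts["neutral_loci_sampled"] = len(loci)
    stage_counts["neutral_loci_exported"] = n_written
    stage_counts["neutral_loci_dropped"] = n_dropped

    meta = {"config": _jsonable(asdict(config)), "thresholds": thresholds}
    summary.update(meta)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, Path):
        return str(obj)
    return obj
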