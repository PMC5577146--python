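"""Neutral-locus preparation for demographic inference.

Builds the masking cascade (assembly gaps, low-MQ tracts, repeats, coding
sequence with 10 kb flanks, conserved non-coding elements with 100 b flanks,
regulatory regions, CpG islands), samples fixed-length loci on a deterministic
anchor grid (1 kb every 50 kb by default), and exports per-sample consensus
sequences — heterozygotes as IUPAC ambiguity codes — in a multi-locus text
format suitable for coalescent samplers such as G-PhoCS.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .annotation import GenomeAnnotation
from .core import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .io import fetch_sequence

logger = logging.getLogger(__name__)

DEFAULT_CDS_FLANK = 10_000
DEFAULT_CNE_FLANK = 100
DEFAULT_LOCUS_LEN = 1_000
DEFAULT_SPACING = 50_000

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
}

#: mask provenance classes, in cascade order
MASK_SOURCES = ("gap", "lowMQ", "repeat", "CDS", "CNE", "regulatory", "CpG")


def merge_intervals(intervals):
    """Union of half-open intervals; returns a sorted non-overlapping list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class MaskSet:
    """Per-chromosome merged masked intervals with label provenance."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    provenance: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def masked_length(self, chrom: str) -> int:
        return sum(e - s for s, e in self.intervals.get(chrom, []))

    def is_masked(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any masked interval."""
        ivs = self.intervals.get(chrom, [])
        i = bisect_right([s for s, _ in ivs], start)
        # interval i-1 may cover start; interval i may begin before end
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return i < len(ivs) and ivs[i][0] < end

    def labels_at(self, chrom: str, start: int, end: int) -> list[str]:
        return sorted({lab for s, e, lab in self.provenance.get(chrom, [])
                       if s < end and e > start})

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    labels = ",".join(self.labels_at(chrom, s, e))
                    fh.write(f"{chrom}\t{s}\t{e}\t{labels}\n")


def build_mask(
    annotation: GenomeAnnotation,
    chrom_lengths: dict[str, int],
    cds_flank: int = DEFAULT_CDS_FLANK,
    cne_flank: int = DEFAULT_CNE_FLANK,
) -> MaskSet:
    """Union of all putatively non-neutral sequence classes, flanks clipped at bounds."""
    flanks = {"CDS": cds_flank, "CNE": cne_flank}
    raw: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_lengths}
    present = set(annotation.classes())
    for cls in MASK_SOURCES:
        if cls not in present:
            logger.info("build_mask: annotation class %s absent, contributes nothing", cls)
            continue
        pad = flanks.get(cls, 0)
        for chrom, s, e, _name in annotation.intervals(cls):
            if chrom not in chrom_lengths:
                continue
            L = chrom_lengths[chrom]
            raw[chrom].append((max(0, s - pad), min(L, e + pad), cls))
    mask = MaskSet()
    for chrom, items in raw.items():
        mask.provenance[chrom] = sorted(items)
        mask.intervals[chrom] = merge_intervals([(s, e) for s, e, _ in items])
    return mask


def sample_loci(
    mask: MaskSet,
    chrom_lengths: dict[str, int],
    locus_len: int = DEFAULT_LOCUS_LEN,
    spacing: int = DEFAULT_SPACING,
) -> list[tuple[str, int, int]]:
    """Deterministic anchor-grid locus sampling.

    Each chromosome is scanned left to right with anchors every ``spacing``
    bp; at each anchor the first fully unmasked ``locus_len`` window starting
    at or after the anchor and ending at or before the next anchor (and the
    chromosome end) is accepted, otherwise the anchor yields nothing.
    """
    if locus_len >= spacing:
        raise ValueError("locus length must be smaller than the anchor spacing")
    loci: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        ivs = mask.intervals.get(chrom, [])
        starts = [s for s, _ in ivs]
        for anchor in range(0, L, spacing):
            limit = min(anchor + spacing, L)
            s = anchor
            while s + locus_len <= limit:
                i = bisect_right(starts, s)
                blocker = None
                if i > 0 and ivs[i - 1][1] > s:
                    blocker = ivs[i - 1]
                elif i < len(ivs) and ivs[i][0] < s + locus_len:
                    blocker = ivs[i]
                if blocker is None:
                    loci.append((chrom, s, s + locus_len))
                    break
                s = blocker[1]
    return loci


def thin_loci(loci, k: int):
    """Keep every k-th locus starting from the first (k=1 is the identity)."""
    if k < 1:
        raise ValueError("thinning factor must be >= 1")
    return list(loci)[::k]


def locus_sequences(
    locus: tuple[str, int, int],
    gm: GenotypeMatrix,
    reference,
    samples,
) -> dict[str, str] | None:
    """Per-sample consensus sequences for one locus, or None if an indel overlaps.

    SNV substitution rules per diploid call: hom-alt → alternate base, het →
    IUPAC ambiguity code, missing → N.  A locus where any requested sample
    carries a non-reference or missing call at an indel site is dropped
    (substitution would change the locus length).
    """
    chrom, start, end = locus
    ref_seq = list(fetch_sequence(reference, chrom, start, end))
    idx = [i for i, s in enumerate(gm.sites)
           if s.chrom == chrom and start < s.pos <= end]
    sample_idx = gm.sample_indices(samples)
    seqs = {name: list(ref_seq) for name in samples}
    for i in idx:
        site = gm.sites[i]
        calls = gm.calls[i, sample_idx]
        if site.vclass != "SNV":
            if np.any(calls != HOM_REF):
                logger.warning("locus %s:%d-%d overlaps indel at pos %d; dropped",
                               chrom, start, end, site.pos)
                return None
            continue
        off = site.pos - 1 - start
        for name, call in zip(samples, calls):
            if call == HOM_REF:
                continue
            if call == HOM_ALT:
                seqs[name][off] = site.alt
            elif call == HET:
                seqs[name][off] = _IUPAC[frozenset((site.ref, site.alt))]
            elif call == MISSING:
                seqs[name][off] = "N"
    return {name: "".join(chars) for name, chars in seqs.items()}


def export_loci(
    loci,
    gm: GenotypeMatrix,
    reference,
    samples,
    path,
    thin: int = 1,
) -> tuple[int, int]:
    """Write loci as a multi-locus sequence text file; returns (written, dropped).

    Layout: first line is the locus count; each locus contributes a header
    ``name n_samples length`` followed by one ``sample<space>sequence`` line
    per sample.
    """
    kept = thin_loci(loci, thin)
    blocks, dropped = [], 0
    for locus in kept:
        seqs = locus_sequences(locus, gm, reference, samples)
        if seqs is None:
            dropped += 1
            continue
        chrom, start, end = locus
        lines = [f"{chrom}_{start}_{end} {len(samples)} {end - start}"]
        lines += [f"{name} {seq}" for name, seq in seqs.items()]
        blocks.append("\n".join(lines))
    with open(path, "w") as fh:
        fh.write(f"{len(blocks)}\n")
        for block in blocks:
            fh.write(block + "\n")
    return len(blocks), dropped


def read_loci(path) -> list[tuple[str, dict[str, str]]]:
    """Re-read an exported multi-locus file (inverse of :func:`export_loci`)."""
    lines = [l.rstrip("\n") for l in open(path)]
    n = int(lines[0])
    out = []
    i = 1
    for _ in range(n):
        name, n_samples, _length = lines[i].split()
        seqs = {}
        for j in range(int(n_samples)):
            sample, seq = lines[i + 1 + j].split()
            seqs[sample] = seq
        out.append((name, seqs))
        i += 1 + int(n_samples)
    return out
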