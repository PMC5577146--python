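"""Standard-format I/O: multi-sample VCF, sample-group tables, FASTA access.

Multi-allelic VCF records are split on read into per-alternate biallelic
sites; genotypes carrying a third allele are recoded as missing for that
split site, since every downstream statistic is biallelic.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .core import (
    GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, SampleGroups, VariantSite,
)

_QC_INFO_KEYS = ("MQ0", "DP", "QD", "FS")


def read_groups(path) -> SampleGroups:
    """Read a two-column TSV ``sample<TAB>label`` into a SampleGroups map."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"malformed group-table line: {line!r}")
        sample, label = fields
        if sample in mapping:
            raise ValueError(f"sample {sample!r} listed twice in group table")
        mapping[sample] = label
    return SampleGroups(mapping)


def _recode_against_alt(a0: int, a1: int, k: int) -> int:
    """Recode one diploid genotype against alternate allele index ``k``."""
    if a0 < 0 or a1 < 0:
        return MISSING
    if any(a not in (0, k) for a in (a0, a1)):
        return MISSING  # carries a third allele
    return (a0 == k) + (a1 == k)


def read_vcf(vcf_path) -> GenotypeMatrix:
    """Parse a multi-sample VCF into a GenotypeMatrix (multi-allelics split per alt)."""
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        gts = v.genotypes
        for g in gts:
            if len(g) != 3:  # [a0, a1, phased]
                raise ValueError(
                    f"malformed (non-diploid) genotype at {v.CHROM}:{v.POS}"
                )
        qc = {}
        if v.QUAL is not None:
            qc["QUAL"] = float(v.QUAL)
        for key in _QC_INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                qc[key] = float(val) if key in ("QD", "FS") else int(val)
        for k, alt in enumerate(v.ALT, start=1):
            codes = np.array(
                [_recode_against_alt(g[0], g[1], k) for g in gts], dtype=np.int8
            )
            sites.append(
                VariantSite(v.CHROM, v.POS, v.REF, alt, qc=qc or None)
            )
            rows.append(codes)
    order = _sort_order(sites)
    sites = [sites[i] for i in order]
    calls = (
        np.array([rows[i] for i in order], dtype=np.int8)
        if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, calls)


def _sort_order(sites: Sequence[VariantSite]) -> list[int]:
    chrom_rank: dict[str, int] = {}
    for s in sites:
        chrom_rank.setdefault(s.chrom, len(chrom_rank))
    return sorted(range(len(sites)), key=lambda i: (chrom_rank[sites[i].chrom], sites[i].pos))


def read_cohort(vcf_path, groups_path) -> tuple[GenotypeMatrix, SampleGroups]:
    """Read VCF + group table; every VCF sample must appear in the group table."""
    gm = read_vcf(vcf_path)
    groups = read_groups(groups_path)
    groups.validate_against(gm)
    return gm, groups


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contigs: Optional[dict] = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file.

    Site qc metrics round-trip through QUAL and INFO (MQ0/DP/QD/FS).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality 0">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i, site in enumerate(gm.sites):
            qc = site.qc or {}
            qual = qc.get("QUAL")
            qual_s = "." if qual is None else f"{qual:g}"
            info_items = []
            for key in _QC_INFO_KEYS:
                if key in qc:
                    info_items.append(f"{key}={qc[key]:g}")
            info_s = ";".join(info_items) or "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[i])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t"
                f"{qual_s}\t.\t{info_s}\tGT\t{gts}\n"
            )


def write_groups(groups: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        for sample, label in groups.mapping.items():
            fh.write(f"{sample}\t{label}\n")


def fetch_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Fetch an upper-case reference slice [start, end) from a pyfaidx Fasta or a dict."""
    seq = reference[chrom][start:end]
    return str(seq).upper()


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
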