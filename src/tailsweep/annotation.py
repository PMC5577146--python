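"""Genome annotation: named interval sets and strand-aware gene models.

Interval classes (CpG islands, regulatory regions, repeats, conserved
non-coding elements, assembly gaps, low-mapping-quality tracts) come from BED
files; gene/CDS models come from GFF3.  Everything is stored 0-based half-open
internally; the GFF3 1-based closed convention is converted on read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

INTERVAL_CLASSES = (
    "CDS", "gene", "intron", "CpG", "regulatory", "repeat", "CNE", "gap", "lowMQ",
)


@dataclass
class GeneModel:
    """One gene's coding structure: strand plus ordered CDS segments (0-based half-open)."""

    name: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]  # genomic order, non-overlapping
    complete: bool = True

    def __post_init__(self):
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS segments in gene {self.name}")
        self.complete = self.cds_length % 3 == 0

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def transcript_coords(self) -> np.ndarray:
        """Genomic 0-based positions of the spliced CDS in transcription order."""
        coords = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return coords[::-1] if self.strand == "-" else coords

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.cds, self.cds[1:]) if s2 > e1]


class GenomeAnnotation:
    """Interval sets keyed by class plus gene models, with overlap queries."""

    def __init__(self):
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self.gene_models: dict[str, GeneModel] = {}

    def add_interval(self, cls: str, chrom: str, start: int, end: int, name=None) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end}) for class {cls}")
        tree = self._trees.setdefault(cls, {}).setdefault(chrom, IntervalTree())
        tree.addi(start, end, name)

    def add_gene_model(self, model: GeneModel) -> None:
        self.gene_models[model.name] = model
        s, e = model.span
        self.add_interval("gene", model.chrom, s, e, model.name)
        for cs, ce in model.cds:
            self.add_interval("CDS", model.chrom, cs, ce, model.name)
        for is_, ie in model.introns():
            self.add_interval("intron", model.chrom, is_, ie, model.name)

    def classes(self) -> list[str]:
        return sorted(self._trees)

    def intervals(self, cls: str, chrom: Optional[str] = None):
        """Yield (chrom, start, end, name) for one class (optionally one chromosome)."""
        for c, tree in sorted(self._trees.get(cls, {}).items()):
            if chrom is not None and c != chrom:
                continue
            for iv in sorted(tree):
                yield c, iv.begin, iv.end, iv.data

    def overlapping(self, cls: str, chrom: str, start: int, end: int):
        tree = self._trees.get(cls, {}).get(chrom)
        return sorted(tree.overlap(start, end)) if tree is not None else []

    def contains(self, cls: str, chrom: str, pos0: int) -> bool:
        return bool(self.overlapping(cls, chrom, pos0, pos0 + 1))

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        return sorted({iv.data for iv in self.overlapping("gene", chrom, start, end)})

    def models_with_cds_at(self, chrom: str, pos0: int) -> list[GeneModel]:
        names = {iv.data for iv in self.overlapping("CDS", chrom, pos0, pos0 + 1)}
        return [self.gene_models[n] for n in sorted(names) if n in self.gene_models]


def _read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def read_annotation(
    bed_paths: Optional[dict] = None,
    gff_path=None,
) -> GenomeAnnotation:
    """Load BED interval classes and GFF3 gene models into one annotation store.

    ``bed_paths`` maps an interval class name (``CpG``, ``regulatory``,
    ``repeat``, ``CNE``, ``gap``, ``lowMQ``) to a BED file.  Gene models whose
    total CDS length is not a multiple of 3 are flagged incomplete and excluded
    from consequence calling (a warning is logged).
    """
    ann = GenomeAnnotation()
    for cls, path in (bed_paths or {}).items():
        for row in _read_bed(path).itertuples(index=False):
            ann.add_interval(cls, row.chrom, int(row.start), int(row.end))
    if gff_path is not None:
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for gene in db.features_of_type("gene"):
            cds = [
                (c.start - 1, c.end)  # GFF3 1-based closed -> 0-based half-open
                for c in db.children(gene.id, featuretype="CDS")
            ]
            if not cds:
                continue
            name = gene.attributes.get("Name", [gene.id])[0]
            model = GeneModel(name, gene.seqid, gene.strand, cds)
            if not model.complete:
                logger.warning(
                    "gene model %s has CDS length %d (not divisible by 3); "
                    "flagged incomplete and excluded from consequence calls",
                    name, model.cds_length,
                )
            ann.add_gene_model(model)
    return ann
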