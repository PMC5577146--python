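"""Case/control variant segregation and consequence classification.

A site is *mutually exclusive* between two phenotype groups when the sets of
diploid genotype states observed in the two groups are disjoint (state-level,
not allele-level, disjointness: a shared reference allele is allowed, a shared
genotype state is not).  The no-tail (NT) pipeline keeps exclusive coding SNVs
and drops synonymous changes; the short-tail (ST) pipeline keeps exclusive
variants falling in CpG islands, regulatory regions or introns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import GenomeAnnotation
from .core import (
    GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, SampleGroups, VariantSite,
)
from .io import fetch_sequence

logger = logging.getLogger(__name__)

_STATE_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt"}

REGULATORY_CLASSES = ("CpG_island", "regulatory", "intron")


@dataclass
class ExclusiveSite:
    """An exclusive site with its per-group genotype-state multisets."""

    index: int  # row in the source GenotypeMatrix
    site: VariantSite
    case_states: tuple[int, ...]
    control_states: tuple[int, ...]

    @property
    def zygosity_label(self) -> str:
        states = set(self.case_states)
        if states == {HET}:
            return "heterogeneous"
        if states == {HOM_ALT} or states == {HOM_REF}:
            return "homogeneous"
        return "mixed"


def exclusive_variants(
    gm: GenotypeMatrix,
    groups: SampleGroups,
    case: str = "NT",
    control: str = "LT",
    min_call_rate: float = 1.0,
) -> list[ExclusiveSite]:
    """Sites whose genotype-state sets are disjoint between case and control.

    Both groups must reach ``min_call_rate`` (non-missing fraction, default
    complete data) for a site to be considered.
    """
    case_idx = gm.sample_indices(groups.members(case))
    control_idx = gm.sample_indices(groups.members(control))
    if len(case_idx) == 0 or len(control_idx) == 0:
        raise ValueError(f"empty group in contrast {case} vs {control}")
    out: list[ExclusiveSite] = []
    for i, site in enumerate(gm.sites):
        ca = gm.calls[i, case_idx]
        co = gm.calls[i, control_idx]
        ca_called = ca[ca != MISSING]
        co_called = co[co != MISSING]
        if len(ca_called) < min_call_rate * len(ca):
            continue
        if len(co_called) < min_call_rate * len(co):
            continue
        if len(ca_called) == 0 or len(co_called) == 0:
            continue
        if set(ca_called) & set(co_called):
            continue
        out.append(ExclusiveSite(i, site, tuple(int(x) for x in sorted(ca_called)),
                                 tuple(int(x) for x in sorted(co_called))))
    return out


def dominance_filter(
    sites: Sequence[ExclusiveSite], enabled: bool = True
) -> list[ExclusiveSite]:
    """Keep sites consistent with a single fully-penetrant dominant allele.

    Consistency: the variant allele is confined to exactly one group — every
    genotype there carries at least one copy (het or hom-alt) while the other
    group is uniformly homozygous reference.  The carrier group may be either
    cases or (mirrored) controls, since the ref/alt orientation of the causal
    allele is not known a priori.  A group mixing het with hom-ref is
    inconsistent: its hom-ref members would lack the dominant allele.  With
    ``enabled=False`` the input passes through unchanged, reproducing plain
    exclusivity counts.
    """
    if not enabled:
        return list(sites)
    kept = []
    for s in sites:
        ca, co = set(s.case_states), set(s.control_states)
        case_carries = ca <= {HET, HOM_ALT} and co == {HOM_REF}
        control_carries = co <= {HET, HOM_ALT} and ca == {HOM_REF}
        if case_carries or control_carries:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------


@dataclass
class Consequence:
    consequence: str
    gene: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None
    regions: list[str] = field(default_factory=list)


def _complement(base: str) -> str:
    return str(Seq(base).complement())


def _coding_call(site: VariantSite, model, reference) -> Consequence:
    """Classify an SNV inside the CDS of a complete gene model."""
    pos0 = site.pos - 1
    ref_base = fetch_sequence(reference, site.chrom, pos0, pos0 + 1)
    if ref_base not in "ACGT":
        raise ValueError(f"non-ACGT reference base {ref_base!r} at {site.chrom}:{site.pos}")
    if ref_base != site.ref:
        raise ValueError(
            f"VCF ref {site.ref!r} disagrees with reference {ref_base!r} "
            f"at {site.chrom}:{site.pos}"
        )
    coords = model.transcript_coords()
    i = int(np.nonzero(coords == pos0)[0][0])
    codon_i, offset = divmod(i, 3)
    codon_pos = coords[codon_i * 3 : codon_i * 3 + 3]
    bases = []
    for p in codon_pos:
        b = fetch_sequence(reference, site.chrom, int(p), int(p) + 1)
        bases.append(_complement(b) if model.strand == "-" else b)
    ref_codon = "".join(bases)
    alt_t = _complement(site.alt) if model.strand == "-" else site.alt
    alt_codon = ref_codon[:offset] + alt_t + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    kind = "coding_synonymous" if ref_aa == alt_aa else "coding_nonsynonymous"
    return Consequence(
        kind, gene=model.name,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{codon_i + 1}{alt_aa}",
    )


def classify_consequence(
    site: VariantSite, annotation: GenomeAnnotation, reference
) -> Consequence:
    """Classify a variant with precedence coding > CpG island > regulatory > intron > intergenic.

    All region memberships are retained in ``regions`` regardless of the
    winning class.  Coding SNVs are translated through the spliced CDS
    (reverse-complemented on minus-strand genes); indels keep their region
    class without frameshift annotation.  A variant inside the CDS of an
    incomplete model is reported ``coding_unresolved`` and excluded from
    candidate tables by the caller.
    """
    pos0 = site.pos - 1
    regions = [
        cls for cls in ("CDS", "CpG", "regulatory", "repeat", "CNE", "gap", "lowMQ")
        if annotation.contains(cls, site.chrom, pos0)
    ]
    gene_names = annotation.genes_overlapping(site.chrom, pos0, pos0 + 1)
    in_cds_of = annotation.models_with_cds_at(site.chrom, pos0)
    if in_cds_of:
        complete = [m for m in in_cds_of if m.complete]
        if not complete:
            logger.warning("variant %s:%d overlaps only incomplete gene models",
                           site.chrom, site.pos)
            return Consequence("coding_unresolved",
                               gene=in_cds_of[0].name, regions=regions)
        if site.vclass != "SNV":
            return Consequence("coding_indel", gene=complete[0].name, regions=regions)
        result = _coding_call(site, complete[0], reference)
        result.regions = regions
        return result
    if annotation.contains("CpG", site.chrom, pos0):
        return Consequence("CpG_island", gene=gene_names[0] if gene_names else None,
                           regions=regions)
    if annotation.contains("regulatory", site.chrom, pos0):
        return Consequence("regulatory", gene=gene_names[0] if gene_names else None,
                           regions=regions)
    if gene_names:  # inside a gene but not in any exon: intron
        return Consequence("intron", gene=gene_names[0], regions=regions + ["intron"])
    return Consequence("intergenic", regions=regions)


# ---------------------------------------------------------------------------
# candidate report
# ---------------------------------------------------------------------------


def _states_string(states: tuple[int, ...]) -> str:
    return ",".join(_STATE_NAMES[s] for s in states)


def _table_row(s: ExclusiveSite, contrast: str, cq: Consequence) -> dict:
    return {
        "chrom": s.site.chrom, "pos": s.site.pos, "ref": s.site.ref,
        "alt": s.site.alt, "vclass": s.site.vclass, "contrast": contrast,
        "case_states": _states_string(s.case_states),
        "control_states": _states_string(s.control_states),
        "zygosity_label": s.zygosity_label, "consequence": cq.consequence,
        "gene": cq.gene or "", "codon_change": cq.codon_change or "",
        "aa_change": cq.aa_change or "",
    }


_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass", "contrast", "case_states",
                  "control_states", "zygosity_label", "consequence", "gene",
                  "codon_change", "aa_change"]


@dataclass
class CandidateReport:
    nt_table: pd.DataFrame
    st_table: pd.DataFrame
    stage_counts: dict


def candidate_report(
    gm: GenotypeMatrix,
    groups: SampleGroups,
    annotation: GenomeAnnotation,
    reference,
    min_call_rate: float = 1.0,
    dominance: bool = False,
    st_control: str = "LT",
) -> CandidateReport:
    """Run both discovery pipelines and emit candidate tables with stage counts.

    NT pipeline: NT-vs-LT exclusivity → coding SNVs → non-synonymous.
    ST pipeline: ST-vs-control exclusivity → CpG island / regulatory / intron
    variants (SNVs and indels).
    """
    counts: dict = {"NT": {}, "ST": {}}

    nt_excl = exclusive_variants(gm, groups, "NT", "LT", min_call_rate)
    nt_excl = dominance_filter(nt_excl, enabled=dominance)
    counts["NT"]["exclusive_snv"] = sum(1 for s in nt_excl if s.site.vclass == "SNV")
    counts["NT"]["exclusive_indel"] = sum(1 for s in nt_excl if s.site.vclass != "SNV")
    nt_rows, n_coding, n_nonsyn = [], 0, 0
    for s in nt_excl:
        if s.site.vclass != "SNV":
            continue
        cq = classify_consequence(s.site, annotation, reference)
        if not cq.consequence.startswith("coding_") or cq.consequence == "coding_unresolved":
            continue
        n_coding += 1
        if cq.consequence == "coding_nonsynonymous":
            n_nonsyn += 1
            nt_rows.append(_table_row(s, "NT_vs_LT", cq))
    counts["NT"]["coding"] = n_coding
    counts["NT"]["nonsynonymous"] = n_nonsyn

    st_excl = exclusive_variants(gm, groups, "ST", st_control, min_call_rate)
    st_excl = dominance_filter(st_excl, enabled=dominance)
    counts["ST"]["exclusive_snv"] = sum(1 for s in st_excl if s.site.vclass == "SNV")
    counts["ST"]["exclusive_indel"] = sum(1 for s in st_excl if s.site.vclass != "SNV")
    st_rows = []
    for s in st_excl:
        cq = classify_consequence(s.site, annotation, reference)
        if cq.consequence in REGULATORY_CLASSES:
            st_rows.append(_table_row(s, f"ST_vs_{st_control}", cq))
    counts["ST"]["regulatory_class"] = len(st_rows)

    nt_table = pd.DataFrame(nt_rows, columns=_TABLE_COLUMNS).sort_values(
        ["chrom", "pos"], ignore_index=True)
    st_table = pd.DataFrame(st_rows, columns=_TABLE_COLUMNS).sort_values(
        ["chrom", "pos"], ignore_index=True)
    return CandidateReport(nt_table, st_table, counts)
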