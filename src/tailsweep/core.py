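"""Core domain types and site-level operations.

This module holds the in-memory containers every statistic operates on — variant
sites, the diploid genotype matrix, phenotype-group labels — together with the
two site-level operations that precede any analysis: the hard quality filters
used at variant-calling time, and ancestral/derived polarization against an
outgroup (gray wolf in the original cohort).

Genotype calls are encoded as small integers per (site, sample):

========  =====
code      state
========  =====
``0``     homozygous reference
``1``     heterozygous
``2``     homozygous alternate
``-1``    missing
========  =====
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GROUP_LABELS = ("NT", "ST", "LT", "OUTGROUP", "OTHER")

#: focal groups making up the DongGyeongi cohort itself
DG_GROUPS = ("NT", "ST", "LT")


def classify_alleles(ref: str, alt: str) -> str:
    """Return the variant class (``SNV``/``insertion``/``deletion``) for a REF/ALT pair."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    raise ValueError(f"unsupported same-length multi-base alleles {ref}>{alt}")


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic variant.

    ``pos`` is 1-based (VCF convention); interval containers elsewhere in the
    package are 0-based half-open, so membership tests use ``pos - 1``.
    ``qc`` optionally carries caller site metrics (MQ0, DP, QUAL, QD, FS).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str = ""
    qc: Optional[dict] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        expected = classify_alleles(self.ref, self.alt)
        if self.vclass == "":
            object.__setattr__(self, "vclass", expected)
        elif self.vclass != expected:
            raise ValueError(
                f"vclass {self.vclass!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )


@dataclass
class GenotypeMatrix:
    """Diploid calls for an ordered set of sites × samples.

    ``calls`` is an int8 array of shape ``(n_sites, n_samples)`` using the
    module-level genotype codes.
    """

    sites: list[VariantSite]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        valid = np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"invalid genotype code at site {bad[0]}, sample {bad[1]}")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos < last[s.chrom]:
                raise ValueError(f"sites not sorted within {s.chrom} at pos {s.pos}")
            last[s.chrom] = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        return np.array([index[n] for n in names], dtype=int)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([s.pos for s in self.sites if s.chrom == chrom], dtype=np.int64)

    def chroms(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if not seen or seen[-1] != s.chrom:
                if s.chrom in seen:
                    raise ValueError("sites of one chromosome are not contiguous")
                seen.append(s.chrom)
        return seen

    def site_index(self, chrom: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sites) if s.chrom == chrom], dtype=int
        )

    def subset_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], list(self.samples), self.calls[idx]
        )


@dataclass
class SampleGroups:
    """Sample name → phenotype-group label (NT/ST/LT/OUTGROUP/OTHER)."""

    mapping: dict[str, str]

    def __post_init__(self):
        for sample, label in self.mapping.items():
            if label not in GROUP_LABELS:
                raise ValueError(f"unknown group label {label!r} for sample {sample}")

    def members(self, *labels: str) -> list[str]:
        return [s for s, l in self.mapping.items() if l in labels]

    def label(self, sample: str) -> str:
        return self.mapping[sample]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        for s in gm.samples:
            if s not in self.mapping:
                raise KeyError(f"sample {s!r} present in VCF but absent from group table")


# ---------------------------------------------------------------------------
# hard site filters
# ---------------------------------------------------------------------------

#: criterion id → human-readable description
HARD_FILTER_CRITERIA = {
    1: "MQ0 >= 4 and MQ0/DP > 0.1",
    2: "QUAL < 30",
    3: "QD < 5.0",
    4: "FS > 200",
}


def hard_filter_reasons(qc: Optional[dict]) -> list[int]:
    """Evaluate the four site-quality criteria; return the ids of those triggered.

    A missing metric passes its sub-criterion.  DP == 0 with MQ0 > 0 is treated
    as an infinite MQ0/DP ratio.
    """
    qc = qc or {}
    reasons: list[int] = []
    mq0, dp = qc.get("MQ0"), qc.get("DP")
    if mq0 is not None and mq0 >= 4:
        if dp is None:
            pass  # ratio unknown: sub-criterion passes
        else:
            ratio = np.inf if dp == 0 and mq0 > 0 else (mq0 / dp if dp else 0.0)
            if ratio > 0.1:
                reasons.append(1)
    qual = qc.get("QUAL")
    if qual is not None and qual < 30:
        reasons.append(2)
    qd = qc.get("QD")
    if qd is not None and qd < 5.0:
        reasons.append(3)
    fs = qc.get("FS")
    if fs is not None and fs > 200:
        reasons.append(4)
    return reasons


def apply_hard_filters(
    sites: Sequence[VariantSite],
) -> tuple[list[VariantSite], list[tuple[VariantSite, list[int]]]]:
    """Partition sites into (pass, fail-with-reasons) under the four hard criteria."""
    passed: list[VariantSite] = []
    failed: list[tuple[VariantSite, list[int]]] = []
    n_missing_qc = 0
    for site in sites:
        if not site.qc:
            n_missing_qc += 1
        reasons = hard_filter_reasons(site.qc)
        if reasons:
            failed.append((site, reasons))
        else:
            passed.append(site)
    if n_missing_qc:
        logger.info("hard filters: %d sites without qc metrics passed by default", n_missing_qc)
    return passed, failed


# ---------------------------------------------------------------------------
# outgroup polarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolarizedSite:
    """A site with ancestral state resolved (or not) by the outgroup.

    ``n`` is the haploid number of non-missing focal genotypes (2 × diploids);
    ``b`` the derived-allele count among them, ``None`` when unpolarizable.
    """

    site: VariantSite
    n: int
    b: Optional[int]
    polarized: bool
    derived_is_alt: Optional[bool] = field(default=None, compare=False)


def polarize_by_outgroup(
    gm: GenotypeMatrix,
    groups: SampleGroups,
    focal: Sequence[str] = DG_GROUPS,
) -> list[PolarizedSite]:
    """Assign ancestral/derived states per site from outgroup homozygosity.

    The ancestral allele is the one carried homozygously by every non-missing
    outgroup sample.  Sites where the outgroup is heterozygous, polymorphic
    across outgroup samples, or entirely missing are flagged unpolarized and
    carry ``b=None``; they are excluded from unfolded-SFS computations.
    """
    out_names = groups.members("OUTGROUP")
    if not out_names:
        raise ValueError("polarization requires at least one OUTGROUP sample")
    focal_names = groups.members(*focal)
    if not focal_names:
        raise ValueError(f"no focal samples with labels {focal}")
    out_idx = gm.sample_indices(out_names)
    foc_idx = gm.sample_indices(focal_names)

    result: list[PolarizedSite] = []
    n_unpolarized = 0
    for i, site in enumerate(gm.sites):
        out_calls = gm.calls[i, out_idx]
        out_calls = out_calls[out_calls != MISSING]
        foc_calls = gm.calls[i, foc_idx]
        foc_calls = foc_calls[foc_calls != MISSING]
        n = 2 * len(foc_calls)
        if len(out_calls) == 0 or np.any(out_calls == HET) or len(set(out_calls)) > 1:
            n_unpolarized += 1
            result.append(PolarizedSite(site, n, None, False))
            continue
        ancestral_is_ref = out_calls[0] == HOM_REF
        alt_count = int(foc_calls.sum())  # code equals per-diploid alt dosage
        b = alt_count if ancestral_is_ref else n - alt_count
        result.append(PolarizedSite(site, n, b, True, derived_is_alt=ancestral_is_ref))
    if n_unpolarized:
        logger.info("polarization: %d of %d sites unresolvable via outgroup",
                    n_unpolarized, gm.n_sites)
    return result
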