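"""Model-matched synthetic cohorts.

Generates everything the analysis pipeline consumes, with the statistical
structure the statistics assume:

* neutral background variation from a clean two-population-split Kingman
  coalescent with infinite-sites mutation (DongGyeongi-style cohort vs. an
  outgroup), no intra-locus recombination, loci independent;
* sweep-distorted regions drawn from the same star-like escape/coalescence
  scheme the CLR scanner fits, so sweep-intensity recovery is well posed;
* a planted dominant causal allele per contrast (all case diploids
  heterozygous, all control diploids homozygous reference — the
  tail-loss inheritance hypothesis);
* a consistent reference FASTA, gene models (GFF3), interval annotations
  (BED) and group table, written as plain text and byte-identical across
  runs with the same seed.

Time is measured in coalescent units in which one pair of lineages coalesces
at rate 1; mutations fall on branches as Poisson((theta / 2) x total branch
length), which makes ``theta`` the expected pairwise diversity per locus.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .core import DG_GROUPS, SampleGroups
from .popgen import SiteFrequencySpectrum, project_sfs

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Cohort and coalescent parameters; defaults mirror the 22-dog study design."""

    seed: int = 0
    n_nt: int = 10
    n_st: int = 5
    n_lt: int = 7
    n_outgroup: int = 2
    theta: float = 1.8          # per locus; 0.0018/bp at the default locus length
    split_time: float = 1.0     # cohort/outgroup split, coalescent units
    n_loci: int = 300
    locus_len: int = 1_000
    # fixture layout
    chrom_name: str = "chr1"
    chrom_len: int = 400_000
    # (center fraction, alpha, span bp); span covers whole 50 kb scan bins so the
    # planted signal is not diluted across bin boundaries
    sweep_blocks: tuple = ((0.75, 2e-5, 100_000),)
    indel_fraction: float = 0.03
    missing_rate: float = 0.0
    n_lowqual_sites: int = 5    # planted hard-filter failures

    def __post_init__(self):
        if min(self.n_nt, self.n_st, self.n_lt, self.n_outgroup) < 1:
            raise ValueError("all group sizes must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    @property
    def n_dg(self) -> int:
        return self.n_nt + self.n_st + self.n_lt

    @property
    def n_diploids(self) -> int:
        return self.n_dg + self.n_outgroup

    @property
    def n_hap_dg(self) -> int:
        return 2 * self.n_dg

    def sample_names(self) -> list[str]:
        names = [f"NT{i:02d}" for i in range(1, self.n_nt + 1)]
        names += [f"ST{i:02d}" for i in range(1, self.n_st + 1)]
        names += [f"LT{i:02d}" for i in range(1, self.n_lt + 1)]
        names += [f"WOLF{i:02d}" for i in range(1, self.n_outgroup + 1)]
        return names

    def groups(self) -> SampleGroups:
        mapping = {}
        for name in self.sample_names():
            for label in DG_GROUPS:
                if name.startswith(label):
                    mapping[name] = label
                    break
            else:
                mapping[name] = "OUTGROUP"
        return SampleGroups(mapping)


@dataclass
class Locus:
    """One simulated locus: fractional positions in [0, 1) and a derived-state matrix."""

    positions: np.ndarray          # shape (S,), sorted
    derived: np.ndarray            # bool, shape (S, n_haplotypes)


def _genealogy_branches(rng: np.random.Generator, k1: int, k2: int, split_time: float):
    """Simulate one two-deme split genealogy; return [(branch length, leaf mask)].

    Before ``split_time`` lineages coalesce only within their deme, each pair
    at rate 1; at the split every lineage joins a single ancestral pool.
    """
    n = k1 + k2
    demes = [0] * k1 + [1] * k2
    births = [0.0] * n
    leaves = [np.eye(n, dtype=bool)[i] for i in range(n)]
    branches: list[tuple[float, np.ndarray]] = []
    t = 0.0
    merged = split_time <= 0.0
    if merged:
        demes = [0] * n
    while len(leaves) > 1:
        if not merged:
            k_a = demes.count(0)
            k_b = demes.count(1)
            rate = k_a * (k_a - 1) / 2 + k_b * (k_b - 1) / 2
            if rate == 0.0:
                t = split_time
                merged = True
                demes = [0] * len(leaves)
                continue
            dt = rng.exponential(1.0 / rate)
            if t + dt >= split_time:
                t = split_time
                merged = True
                demes = [0] * len(leaves)
                continue
            t += dt
            deme = 0 if rng.random() < (k_a * (k_a - 1) / 2) / rate else 1
            members = [i for i, d in enumerate(demes) if d == deme]
        else:
            k = len(leaves)
            t += rng.exponential(2.0 / (k * (k - 1)))
            members = list(range(k))
        i, j = rng.choice(len(members), size=2, replace=False)
        i, j = members[i], members[j]
        i, j = min(i, j), max(i, j)
        branches.append((t - births[i], leaves[i]))
        branches.append((t - births[j], leaves[j]))
        new_leafset = leaves[i] | leaves[j]
        for lst in (leaves, births, demes):
            del lst[j]
        leaves[i] = new_leafset
        births[i] = t
        demes[i] = demes[i]
    return branches


def simulate_neutral_loci(config: SimConfig, rng: Optional[np.random.Generator] = None
                          ) -> list[Locus]:
    """Independent neutral loci for the pooled cohort + outgroup sample.

    Haplotypes 0..2*n_dg-1 belong to the focal population (NT, ST, LT blocks
    in order), the rest to the outgroup; diploids pair consecutive
    haplotypes.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k1, k2 = config.n_hap_dg, 2 * config.n_outgroup
    n_hap = k1 + k2
    loci = []
    for _ in range(config.n_loci):
        branches = _genealogy_branches(rng, k1, k2, config.split_time)
        lengths = np.array([b[0] for b in branches])
        total = lengths.sum()
        n_mut = rng.poisson(config.theta / 2.0 * total)
        if n_mut == 0:
            loci.append(Locus(np.empty(0), np.zeros((0, n_hap), dtype=bool)))
            continue
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        positions = rng.random(n_mut)
        order = np.argsort(positions)
        derived = np.stack([branches[w][1] for w in which[order]])
        loci.append(Locus(positions[order], derived))
    return loci


def neutral_background_sfs(n: int) -> SiteFrequencySpectrum:
    """The analytic neutral (constant-size) SFS, q_j proportional to 1/j, j=1..n-1."""
    vals = np.zeros(n + 1)
    j = np.arange(1, n)
    vals[1:n] = 1.0 / j
    return SiteFrequencySpectrum(n, vals, includes_monomorphic=False).normalized()


def simulate_sweep_region(
    background: SiteFrequencySpectrum,
    alpha: float,
    center: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Derived-allele counts at given positions under the star-like sweep scheme.

    Generative twin of the analytic sweep site probability: each lineage
    escapes with probability ``1 - exp(-alpha d)``; conditional on ``e``
    escapees a configuration is drawn from the background projected to
    ``m = e + 1`` exchangeable ancestors, one of which represents the swept
    class of size ``n - e``.
    """
    n = background.n
    bg = background.polymorphic()
    positions = np.asarray(positions, dtype=float)
    d = np.abs(positions - center)
    pe = -np.expm1(-alpha * d)
    e = rng.binomial(n, pe)
    b = np.zeros(len(positions), dtype=np.int64)
    proj = {}
    for m in np.unique(e + 1):
        proj[int(m)] = (project_sfs(bg, int(m)).values if m <= n else bg.values)
    for i in range(len(positions)):
        ei = int(e[i])
        if ei == n:
            b[i] = rng.choice(n + 1, p=bg.values)
            continue
        m = ei + 1
        j = int(rng.choice(m + 1, p=proj[m]))
        if j >= 1 and rng.random() < j / m:
            b[i] = (n - ei) + (j - 1)
        else:
            b[i] = j
    return b


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------


@dataclass
class CausalSpec:
    """Where and how to plant one dominant causal allele."""

    contrast: str            # "NT" or "ST"
    position: int            # 1-based target position
    alt: str
    consequence: str         # expected class, recorded in the truth file


@dataclass
class FixtureBundle:
    """Paths to every generated file plus the ground-truth record."""

    outdir: Path
    vcf: Path
    groups: Path
    fasta: Path
    gff: Path
    beds: dict
    truth: dict


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=length)


def _cpg_rich(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-island-like sequence: GC-rich with frequent CG dinucleotides."""
    bases = rng.choice(np.array(list("ACGT")), size=length,
                       p=[0.15, 0.35, 0.35, 0.15])
    follow_g = rng.random(length) < 0.35
    for i in range(length - 1):
        if bases[i] == "C" and follow_g[i]:
            bases[i + 1] = "G"
    return bases


def _fixture_layout(L: int) -> dict:
    """Deterministic annotation layout as fractions of the chromosome length."""
    f = lambda x: int(x * L)
    genes = []
    for k, frac in enumerate((0.08, 0.19, 0.30, 0.41, 0.52, 0.63, 0.74, 0.85)):
        s = f(frac)
        strand = "+" if k % 2 == 0 else "-"
        genes.append({"name": f"gene{k + 1:02d}", "strand": strand,
                      "cds": [(s, s + 300), (s + 2000, s + 2300)]})
    return {
        "genes": genes,
        "CpG": [(f(0.125), f(0.125) + 1000), (f(0.375), f(0.375) + 1500),
                (f(0.775), f(0.775) + 1000)],
        "regulatory": [(f(0.175), f(0.175) + 500), (f(0.555), f(0.555) + 800)],
        "repeat": [(f(0.05), f(0.05) + 3000), (f(0.45), f(0.45) + 2000),
                   (f(0.88), f(0.88) + 2000)],
        "CNE": [(f(0.235), f(0.235) + 200), (f(0.65), f(0.65) + 300)],
        "gap": [(0, f(0.005))],
        "lowMQ": [(f(0.975), f(0.975) + 2000)],
    }


@dataclass
class _Record:
    pos: int                 # 1-based
    ref: str
    alt: str
    codes: np.ndarray        # per-diploid genotype codes, int8
    qc: dict


def plant_causal_variant(
    records: dict[int, "_Record"],
    reference: str,
    config: SimConfig,
    spec: CausalSpec,
) -> dict:
    """Plant a dominant case-exclusive variant; returns the truth record.

    All case diploids become heterozygous, every other sample homozygous
    reference.  An occupied target position is shifted to the nearest free
    one (preferring downstream on ties), logged.
    """
    pos = spec.position
    if pos in records:
        for delta in range(1, len(reference)):
            for cand in (pos + delta, pos - delta):
                if 1 <= cand <= len(reference) and cand not in records:
                    logger.warning("causal position %d occupied; shifted to %d", pos, cand)
                    pos = cand
                    break
            else:
                continue
            break
    ref = reference[pos - 1]
    codes = np.zeros(config.n_diploids, dtype=np.int8)
    offset = 0
    for label, count in (("NT", config.n_nt), ("ST", config.n_st), ("LT", config.n_lt)):
        if label == spec.contrast:
            codes[offset:offset + count] = 1
        offset += count
    records[pos] = _Record(pos, ref, spec.alt, codes,
                           {"QUAL": 100.0, "MQ0": 0, "DP": 350, "QD": 20.0, "FS": 5.0})
    return {"contrast": spec.contrast, "pos": pos, "ref": ref, "alt": spec.alt,
            "consequence": spec.consequence}


def _nonsyn_alt(reference: str, pos0: int, cds_start: int) -> Optional[str]:
    """An alternate base at pos0 changing the encoded amino acid (plus strand, frame 0)."""
    i = pos0 - cds_start
    codon_start = cds_start + (i // 3) * 3
    codon = reference[codon_start:codon_start + 3]
    off = i % 3
    ref_aa = str(Seq(codon).translate())
    for alt in "ACGT":
        if alt == codon[off]:
            continue
        alt_codon = codon[:off] + alt + codon[off + 1:]
        if str(Seq(alt_codon).translate()) != ref_aa:
            return alt
    return None


def write_fixture(config: SimConfig, outdir) -> FixtureBundle:
    """Generate the full cohort fixture (FASTA + VCF + BEDs + GFF3 + groups + truth).

    Neutral loci tile the chromosome contiguously; each sweep block replaces
    the background within its span by draws from the analytic sweep spectrum;
    two causal variants are planted (NT: non-synonymous coding SNV; ST: CpG
    island SNV).  Byte-identical across runs with the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    L = config.chrom_len
    layout = _fixture_layout(L)

    # reference sequence with CpG-island composition inside the islands
    seq = _random_sequence(rng, L)
    for s, e in layout["CpG"]:
        seq[s:e] = _cpg_rich(rng, e - s)
    reference = "".join(seq)

    # neutral background across contiguous loci
    n_loci = L // config.locus_len
    sim_cfg = SimConfig(**{**asdict(config), "n_loci": n_loci})
    loci = simulate_neutral_loci(sim_cfg, rng)
    base_qc = {"QUAL": 100.0, "MQ0": 0, "DP": 350, "QD": 20.0, "FS": 5.0}
    records: dict[int, _Record] = {}
    for li, locus in enumerate(loci):
        offset = li * config.locus_len
        for s_i in range(len(locus.positions)):
            pos = offset + int(locus.positions[s_i] * config.locus_len) + 1
            if pos in records or pos >= L:  # infinite-sites collision at bp scale
                continue
            ref = reference[pos - 1]
            hap = locus.derived[s_i]
            codes = (hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8))
            if rng.random() < config.indel_fraction and pos < L - 1:
                if rng.random() < 0.5:
                    alt = ref + str(rng.choice(list("ACGT")))
                else:
                    ref = reference[pos - 1 : pos + 1]
                    alt = ref[0]
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records[pos] = _Record(pos, ref, alt, codes, base_qc)

    # sweep blocks overwrite the background in their span (cohort only)
    bg = neutral_background_sfs(config.n_hap_dg)
    truth_sweeps = []
    for frac, alpha, span in config.sweep_blocks:
        center = int(frac * L)
        lo = max(0, center - span // 2)
        hi = min(L - 1, center + span // 2)
        for pos in [p for p in records if lo <= p - 1 < hi]:
            del records[pos]
        n_sites = rng.poisson(span * config.theta / config.locus_len
                              * np.log(config.n_hap_dg))
        positions = np.sort(rng.integers(lo, hi, size=n_sites)) + 1
        b = simulate_sweep_region(bg, alpha, center + 1, positions, rng)
        for pos, bi in zip(positions, b):
            pos = int(pos)
            if pos in records or bi == 0:
                continue
            carriers = rng.choice(config.n_hap_dg, size=int(bi), replace=False)
            hap = np.zeros(2 * config.n_diploids, dtype=bool)
            hap[carriers] = True
            codes = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
            ref = reference[pos - 1]
            alt = str(rng.choice([x for x in "ACGT" if x != ref]))
            records[pos] = _Record(pos, ref, alt, codes, base_qc)
        truth_sweeps.append({"center": center + 1, "alpha": alpha, "span": span})

    # planted causal variants
    nt_gene = layout["genes"][2]            # plus strand by construction
    cds_s, cds_e = nt_gene["cds"][0]
    nt_pos0 = None
    for cand in range(cds_s, cds_e):
        if cand + 1 in records:
            continue
        alt = _nonsyn_alt(reference, cand, cds_s)
        if alt is not None:
            nt_pos0, nt_alt = cand, alt
            break
    assert nt_pos0 is not None, "no free non-synonymous site in the causal exon"
    cpg_s, cpg_e = layout["CpG"][1]
    st_pos0 = next(p for p in range((cpg_s + cpg_e) // 2, cpg_e)
                   if p + 1 not in records)
    st_ref = reference[st_pos0]
    st_alt = str(rng.choice([x for x in "ACGT" if x != st_ref]))
    truth_causal = [
        plant_causal_variant(records, reference, config,
                             CausalSpec("NT", nt_pos0 + 1, nt_alt,
                                        "coding_nonsynonymous")),
        plant_causal_variant(records, reference, config,
                             CausalSpec("ST", st_pos0 + 1, st_alt, "CpG_island")),
    ]

    # a few planted low-quality sites exercising the hard filters
    lowq_positions = []
    for _ in range(config.n_lowqual_sites):
        while True:
            pos = int(rng.integers(1, L))
            if pos not in records:
                break
        ref = reference[pos - 1]
        alt = str(rng.choice([x for x in "ACGT" if x != ref]))
        codes = np.zeros(config.n_diploids, dtype=np.int8)
        codes[int(rng.integers(0, config.n_diploids))] = 1
        records[pos] = _Record(pos, ref, alt, codes,
                               {"QUAL": 10.0, "MQ0": 8, "DP": 20, "QD": 1.0, "FS": 250.0})
        lowq_positions.append(pos)

    # optional missingness
    if config.missing_rate > 0:
        for rec in records.values():
            mask = rng.random(config.n_diploids) < config.missing_rate
            rec.codes = np.where(mask, np.int8(-1), rec.codes)

    # consistency guard: every REF allele must match the reference sequence
    for rec in records.values():
        if reference[rec.pos - 1 : rec.pos - 1 + len(rec.ref)] != rec.ref:
            raise AssertionError(f"fixture inconsistency at position {rec.pos}")

    paths = _write_fixture_files(config, outdir, reference, layout, records)
    truth = {
        "seed": config.seed,
        "causal": truth_causal,
        "sweeps": truth_sweeps,
        "lowqual_positions": sorted(lowq_positions),
        "n_records": len(records),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return FixtureBundle(outdir, paths["vcf"], paths["groups"], paths["fasta"],
                         paths["gff"], paths["beds"], truth)


def _write_fixture_files(config, outdir, reference, layout, records):
    from .core import GenotypeMatrix, VariantSite
    from .io import write_fasta, write_groups, write_vcf

    chrom = config.chrom_name
    fasta = outdir / "reference.fa"
    write_fasta({chrom: reference}, fasta)

    sites, rows = [], []
    for pos in sorted(records):
        rec = records[pos]
        sites.append(VariantSite(chrom, rec.pos, rec.ref, rec.alt, qc=rec.qc))
        rows.append(rec.codes)
    gm = GenotypeMatrix(sites, config.sample_names(),
                        np.array(rows, dtype=np.int8))
    vcf = outdir / "cohort.vcf"
    write_vcf(gm, vcf, contigs={chrom: config.chrom_len})
    groups_path = outdir / "groups.tsv"
    write_groups(config.groups(), groups_path)

    beds = {}
    for cls in ("CpG", "regulatory", "repeat", "CNE", "gap", "lowMQ"):
        path = outdir / f"{cls.lower()}.bed"
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(layout[cls]):
                fh.write(f"{chrom}\t{s}\t{e}\t{cls.lower()}{i + 1}\n")
        beds[cls] = path

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in layout["genes"]:
            span_s = g["cds"][0][0] + 1
            span_e = g["cds"][-1][1]
            gid = g["name"]
            fh.write(f"{chrom}\ttailsweep\tgene\t{span_s}\t{span_e}\t.\t"
                     f"{g['strand']}\t.\tID={gid};Name={gid}\n")
            fh.write(f"{chrom}\ttailsweep\tmRNA\t{span_s}\t{span_e}\t.\t"
                     f"{g['strand']}\t.\tID={gid}.t1;Parent={gid}\n")
            segs = g["cds"] if g["strand"] == "+" else list(reversed(g["cds"]))
            phase = 0
            for s, e in segs:
                fh.write(f"{chrom}\ttailsweep\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g['strand']}\t{phase}\tID={gid}.cds;Parent={gid}.t1\n")
                phase = (3 - ((e - s) - phase) % 3) % 3
    return {"vcf": vcf, "groups": groups_path, "fasta": fasta, "gff": gff, "beds": beds}
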