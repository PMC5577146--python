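# Methods

This note documents the models and procedures implemented in `tailsweep`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open and a choice had to be made.

## Cohort model and segregation analysis

The package targets small case/control cohorts genotyped from whole-genome
sequencing: by default 10 no-tail (NT), 5 short-tail (ST) and 7 long-tail
(LT) diploids plus an outgroup (2 gray-wolf-like samples) used only for
polarization. Genotypes are diploid states {hom-ref, het, hom-alt, missing};
multi-allelic VCF records are split per alternate allele, and a genotype
carrying a third allele is recoded as missing for that split site, since all
downstream statistics are biallelic.

**Mutual exclusivity** is defined on genotype *states*, not alleles: a site
segregates exclusively between two groups when the sets of observed states
are disjoint. Allele-level disjointness would be too strict — it forbids the
case group being all-heterozygous while controls are homozygous reference,
which is precisely the signature of a dominant causal allele in a
case/control design. The default requires complete calls in both groups
(`min_call_rate = 1.0`; at a 22-dog scale complete data is realistic), and is
configurable.

**Dominance filter** (off by default, so plain exclusivity counts are
reproducible): a site is dominance-consistent when the variant allele is
confined to one group — every member there carries at least one copy (het or
hom-alt) and the opposite group is uniformly hom-ref. The carrier group may
be either cases or controls, because the ref/alt orientation of a causal
allele is unknown a priori. A group mixing het with hom-ref is inconsistent:
its hom-ref members would lack the putatively fully-penetrant allele.

**Consequence classification** uses precedence coding > CpG island >
regulatory > intron > intergenic; all raw region memberships are retained in
the output, so precedence only affects the single reported label. Coding
SNVs are translated through the spliced CDS (reverse-complemented on
minus-strand genes, frame anchored at the transcription-side CDS start);
indels inside CDS are labelled `coding_indel` without frameshift annotation.
Gene models whose total CDS length is not a multiple of 3 are flagged
incomplete; variants inside them are `coding_unresolved` and excluded from
candidate tables. Intron = gene span minus exons; splice sites and UTRs are
not modelled.

The NT discovery pipeline is: NT-vs-LT exclusivity → coding SNVs →
non-synonymous. The ST pipeline is: ST-vs-LT exclusivity → CpG island /
regulatory / intron variants (SNVs and indels). Stage counts are reported
per pipeline and are non-increasing by construction.

## Hard site filters

A site fails iff any of: (1) MQ0 ≥ 4 and MQ0/DP > 0.1; (2) QUAL < 30;
(3) QD < 5.0; (4) FS > 200. All four comparisons are strict in the direction
written, so QUAL = 30, QD = 5.0 and FS = 200 pass. A missing metric passes
its sub-criterion (synthetic data need not carry caller metrics). DP = 0
with MQ0 > 0 treats the ratio as +∞, so criterion (1) then triggers exactly
when MQ0 ≥ 4.

## Windowed statistics

* **π** uses every genotyped sample at a site (haploid n varies per site with
  missingness): per-site value 2j(n−j)/(n(n−1)), summed and divided by the
  window length in bp. Defaults for profiling: 100 kb windows, 500 b step,
  anchored at the region start; the region mean is the single window
  spanning it.
* **Tajima's D** requires one n per window. Sites with missing calls are
  down-projected to the window minimum n by hypergeometric expectation:
  per-site π is invariant under down-projection, and each site contributes
  its probability of remaining polymorphic to an expected (real-valued)
  segregating-site count. Windows with no segregating site report missing
  (NaN), never 0, so genome-wide quantiles are not diluted.
* **F<sub>ST</sub>** is the two-population Weir–Cockerham (1984) estimator;
  windowed values are the ratio of summed components Σa/Σ(a+b+c) (weighted
  estimator), not a mean of per-site ratios. Σ(a+b+c) = 0 reports missing.
  The pipeline's default contrast is cohort (NT+ST+LT) versus OUTGROUP and
  is configurable; which population pair the original analysis used is not
  derivable from the tooling it names.

## Sweep scan

The CLR test follows the star-like hitchhiking approximation (Nielsen-style,
as implemented by SweepFinder2): escape probability p_e = 1 − exp(−αd) per
lineage, instantaneous coalescence of non-escaped lineages, and a
configuration for the m = e + 1 pre-sweep lineages drawn from the genome-wide
background SFS projected to m. Distance d is physical (bp): no dog
recombination map is assumed, and α absorbs the scale.

Numerical and design choices:

* The background SFS is empirical over polymorphic classes 1..n−1, with
  sites at larger n down-projected hypergeometrically; empty classes get a
  0.5 pseudo-count before normalization so the scan never takes log 0.
* Only polymorphic sites enter the composite likelihood. The per-site sweep
  probabilities are therefore conditioned on polymorphism,
  P(b)/(1 − P(0) − P(n)); without conditioning the likelihood is
  misspecified near a real sweep (the model expects mostly monomorphic
  output there) and the α estimate collapses to the weakest grid value. The
  unconditioned spectrum — a proper distribution over b = 0..n — remains the
  generative model used by the simulator and the Monte-Carlo tests.
* α grid: 15 log-spaced values spanning p_e ∈ [0.001, 0.999] at half the
  scan radius; radius 100 kb; test grid every 10 kb. Adjacent grid points are
  within a factor ~1.9, so a grid argmax resolves α to well within a factor
  of 2. CLR is clipped at 0 (the background is the α → ∞ limit, so the
  models are nested). A site exactly at the test position with a polymorphic
  genotype has probability 0 under the sweep model (p_e = 0 forces
  monomorphism); the −∞ log-likelihood simply removes that α from the max.
* **Evidence combination**: per 50 kb bin, CLR = maximum over test positions
  in the bin; F<sub>ST</sub> and D are the bin's window values. Thresholds
  are order statistics over defined bins: the k-th most extreme value with
  k = max(1, ⌊qN⌋), q = 0.05; comparisons are ≥ (CLR, F<sub>ST</sub>) and ≤
  (D), so ties at the threshold are included. Candidates pass all three
  (union available by flag). Bins with any undefined statistic are excluded
  from both quantile estimation and candidacy. Note that with fewer than 20
  defined bins k is forced to 1 and the candidate fraction can exceed q
  (e.g. 1/8 on the toy fixture); with N ≥ 20 the intersection is bounded by
  q·N. A gene is reported for a bin on ≥ 1 bp overlap.

## Neutral-locus cascade

The mask is the union of assembly gaps, low-MQ tracts, repeats, CDS ± 10 kb,
conserved non-coding elements ± 100 b, regulatory regions and CpG islands,
flanks clipped at chromosome bounds. Locus sampling is deterministic (no
RNG): anchors every 50 kb, and each anchor accepts the first fully unmasked
1 kb window starting at or after it and ending by the next anchor. Exported
loci carry one consensus sequence per diploid sample with heterozygotes as
IUPAC ambiguity codes (phasing is not assumed) and missing calls as N; a
locus overlapping a non-reference indel call in any sample is dropped, since
the multi-locus format requires fixed lengths. Thinning keeps every k-th
locus starting from the first. The downstream coalescent-sampler MCMC itself
is out of scope — this module prepares and exports its input.

## Synthetic cohorts

`simulate` generates neutral background variation from a Kingman coalescent
with a clean two-population split: within each population any lineage pair
coalesces at rate 1, at `split_time` all lineages merge into one ancestral
pool. Time is measured in units in which a pair coalesces at rate 1;
mutations fall on branches as Poisson((θ/2) × total branch length) under the
infinite-sites model, which makes θ the expected pairwise diversity per
locus (the Hudson convention; verified against the closed form in the
tests). There is no intra-locus recombination and loci are independent —
matching the "neutrally evolving, independent loci" assumption of the
demographic-inference preparation and keeping the simulator exact. Diploids
pair consecutive haplotypes, so Hardy–Weinberg holds by construction.

Defaults: θ = 1.8 per 1 kb locus (0.0018/bp, the diversity scale reported
for dog cohorts of this kind), split_time = 1.0 to the outgroup (deep enough
that ~70% of sites polarize cleanly through two outgroup samples),
10/5/7 + 2 samples.

Sweep regions are drawn from the same analytic star-like spectrum the
scanner fits (the generative escape/coalescence scheme), which makes
α-recovery a well-posed test; this is a model-matched simulation, not an
ms-grade forward/backward simulation with linkage. The default fixture
plants one block at 0.75 of the chromosome with α = 2×10⁻⁵ spanning 100 kb —
two whole 50 kb scan bins, so the planted signal is not split across bin
boundaries. Planted causal variants follow the dominant model: all case
diploids het, everyone else hom-ref; the NT variant is placed at a free
coding position whose substitution is non-synonymous, the ST variant inside
a CpG island. Five low-quality sites (failing all four hard filters) are
planted to exercise the filter stage. The whole fixture — FASTA (CpG islands
generated CG-rich), VCF, GFF3, BEDs, group table, truth JSON — is
byte-identical across runs with the same seed.

What the generator does **not** emulate: linkage within loci, recombination
maps, sequencing error, genotype likelihoods or caller artefacts, incomplete
penetrance, and realistic gene density. Passing tests therefore demonstrate
correctness of the statistics and the discovery logic under the stated
models, not robustness to real-data artefacts.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run on 100 random windows (20–44 haplotypes); sweep-model
Monte-Carlo checks use 10⁵ draws; scan power uses n = 20 haplotypes and
2,000 sites per replicate with a 200-replicate null and 50 (tests) or 30
(acceptance script) sweep replicates; segregation recovery runs 20 fixture
seeds on 200 kb chromosomes; calibration uses 500 cohort loci, 300 loci per
split-time grid point and 2,000 two-haplotype loci. These sizes give stable
rates and sub-minute runtimes for each suite section.

## Known limitations

* The CLR uses physical distance; in regions of atypical recombination rate
  α estimates are not comparable across the genome.
* The three-way top-5% intersection is only meaningful with enough bins;
  desk-scale fixtures (8 bins) usually yield an empty intersection.
* Consequence calling handles single-codon substitutions only; frameshift,
  stop-gain bookkeeping, splice sites and UTRs are not modelled.
* F<sub>ST</sub> against a 2-sample outgroup is noisy per window; the
  simulator's calibration tests use 5 outgroup diploids for that reason.
* Exclusivity with `min_call_rate < 1` compares observed states only; a
  missing call can hide a shared state.
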