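"""Group-exclusive genotypes, dominance consistency, consequence calls, report."""
import itertools

import numpy as np
import pytest

from tailsweep.annotation import GeneModel, GenomeAnnotation
from tailsweep.core import HET, HOM_ALT, HOM_REF, MISSING
from tailsweep.segregation import (
    ExclusiveSite, candidate_report, classify_consequence, dominance_filter,
    exclusive_variants,
)

from conftest import make_gm, make_groups

CASE, CONTROL = ["c1", "c2", "c3"], ["k1", "k2", "k3", "k4", "k5", "k6", "k7"]
SAMPLES = CASE + CONTROL
LABELS = ["NT"] * 3 + ["LT"] * 7
GROUPS = make_groups(SAMPLES, LABELS)


def _excl(case_calls, control_calls, **kw):
    pad_case = case_calls + [case_calls[-1]] * (3 - len(case_calls))
    pad_ctrl = control_calls + [control_calls[-1]] * (7 - len(control_calls))
    gm = make_gm([pad_case + pad_ctrl], samples=SAMPLES)
    return exclusive_variants(gm, GROUPS, "NT", "LT", **kw)


class TestExclusiveVariants:
    def test_all_het_cases_vs_homref_controls(self):
        out = _excl([HET, HET, HET], [HOM_REF] * 7)
        assert len(out) == 1 and out[0].zygosity_label == "heterogeneous"

    def test_shared_het_state_not_exclusive(self):
        assert _excl([HET, HOM_ALT, HOM_ALT], [HET, HOM_REF, HOM_REF]) == []

    def test_mixed_and_homogeneous_labels(self):
        assert _excl([HET, HOM_ALT, HET], [HOM_REF] * 7)[0].zygosity_label == "mixed"
        assert _excl([HOM_ALT] * 3, [HOM_REF] * 7)[0].zygosity_label == "homogeneous"

    def test_call_rate_threshold(self):
        assert _excl([HET, HET, MISSING], [HOM_REF] * 7) == []
        out = _excl([HET, HET, MISSING], [HOM_REF] * 7, min_call_rate=0.6)
        assert len(out) == 1

    def test_empty_group_errors(self):
        gm = make_gm([[HET, HOM_REF]], samples=["a", "b"])
        groups = make_groups(["a", "b"], ["NT", "NT"])
        with pytest.raises(ValueError):
            exclusive_variants(gm, groups, "NT", "LT")

    def test_symmetric_in_case_control(self):
        rng = np.random.default_rng(30)
        gm = make_gm(rng.integers(0, 3, size=(80, 10)), samples=SAMPLES)
        fwd = {s.index for s in exclusive_variants(gm, GROUPS, "NT", "LT")}
        rev = {s.index for s in exclusive_variants(gm, GROUPS, "LT", "NT")}
        assert fwd == rev

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(31)
        codes = rng.integers(0, 3, size=(60, 10))
        gm = make_gm(codes, samples=SAMPLES)
        perm = rng.permutation(10)
        gm2 = make_gm(codes[:, perm], samples=[SAMPLES[i] for i in perm])
        a = {s.index for s in exclusive_variants(gm, GROUPS, "NT", "LT")}
        b = {s.index for s in exclusive_variants(gm2, GROUPS, "NT", "LT")}
        assert a == b

    def test_ref_alt_swap_flips_zygosity_not_exclusivity(self):
        rng = np.random.default_rng(32)
        codes = rng.integers(0, 3, size=(120, 10))
        gm = make_gm(codes, samples=SAMPLES)
        flip = {HOM_REF: HOM_ALT, HET: HET, HOM_ALT: HOM_REF}
        gm2 = make_gm(np.vectorize(flip.get)(codes), samples=SAMPLES)
        a = exclusive_variants(gm, GROUPS, "NT", "LT")
        b = exclusive_variants(gm2, GROUPS, "NT", "LT")
        assert [s.index for s in a] == [s.index for s in b]
        for s1, s2 in zip(a, b):
            # the label is invariant (hom-ref homog <-> hom-alt homog), the
            # underlying state multisets are mirrored
            assert s1.zygosity_label == s2.zygosity_label
            assert sorted(s1.case_states) == sorted(flip[c] for c in s2.case_states)


def _dominance_oracle(case_set, control_set):
    """By hand: the variant allele sits entirely in one group, which has no
    hom-ref member; the opposite group is uniformly hom-ref."""
    one_way = all(g in (HET, HOM_ALT) for g in case_set) \
        and list(control_set) == [HOM_REF]
    mirrored = all(g in (HET, HOM_ALT) for g in control_set) \
        and list(case_set) == [HOM_REF]
    return one_way or mirrored


class TestDominanceFilter:
    def _site(self, case_states, control_states):
        from tailsweep.core import VariantSite
        return ExclusiveSite(0, VariantSite("c", 1, "A", "G"),
                             tuple(sorted(case_states)), tuple(sorted(control_states)))

    def test_het_cases_kept_and_mirrored_assignment(self):
        assert dominance_filter([self._site({HET}, {HOM_REF})])
        assert dominance_filter([self._site({HOM_REF}, {HOM_ALT})])
        # exclusive but dominance-inconsistent: a hom-ref case carries no copy
        assert dominance_filter([self._site({HET, HOM_REF}, {HOM_ALT})]) == []

    def test_all_disjoint_state_set_pairs_enumerated(self):
        """Every disjoint (case, control) state-set pair classified as by hand."""
        states = [HOM_REF, HET, HOM_ALT]
        subsets = [set(c) for r in (1, 2, 3)
                   for c in itertools.combinations(states, r)]
        checked = 0
        for ca, co in itertools.product(subsets, subsets):
            if ca & co:
                continue
            site = self._site(ca, co)
            kept = dominance_filter([site]) == [site]
            assert kept == _dominance_oracle(ca, co), (ca, co)
            checked += 1
        assert checked > 10

    def test_disabled_passes_through(self):
        site = self._site({HET, HOM_REF}, {HOM_ALT})
        assert dominance_filter([site], enabled=False) == [site]


def _toy_annotation():
    ann = GenomeAnnotation()
    # plus-strand single-exon gene: CDS at 0-based [100, 130)
    ann.add_gene_model(GeneModel("plusg", "chr1", "+", [(100, 130)]))
    # minus-strand two-exon gene
    ann.add_gene_model(GeneModel("minusg", "chr1", "-", [(200, 212), (220, 229)]))
    ann.add_interval("CpG", "chr1", 300, 350)
    ann.add_interval("regulatory", "chr1", 340, 400)
    return ann


def _toy_reference(ann):
    seq = ["T"] * 500
    seq[100:130] = list("ATGCTTGGGAAACCCTTTACAGATGCAGGG")
    # minus-strand gene: genomic segments; transcript = revcomp(seg2) + revcomp(seg1)
    seq[200:212] = list("ATTACCGGTAGC")
    seq[220:229] = list("GGCCATTAC")
    return {"chr1": "".join(seq)}


class TestClassifyConsequence:
    ann = _toy_annotation()
    ref = _toy_reference(ann)

    def _site(self, pos1, ref, alt):
        from tailsweep.core import VariantSite
        return VariantSite("chr1", pos1, ref, alt)

    def test_met_to_ile_nonsynonymous(self):
        # codon ATG, third base G->A gives ATA (Met -> Ile)
        cq = classify_consequence(self._site(103, "G", "A"), self.ann, self.ref)
        assert cq.consequence == "coding_nonsynonymous"
        assert cq.codon_change == "ATG>ATA" and cq.aa_change == "M1I"

    def test_leu_to_leu_synonymous(self):
        # codon CTT, third base T->C gives CTC (Leu -> Leu)
        cq = classify_consequence(self._site(106, "T", "C"), self.ann, self.ref)
        assert cq.consequence == "coding_synonymous" and cq.aa_change == "L2L"

    def test_minus_strand_matches_manual_translation(self):
        """Hand-translated toy gene: transcript is revcomp of spliced genomic CDS."""
        from Bio.Seq import Seq
        spliced = self.ref["chr1"][200:212] + self.ref["chr1"][220:229]
        transcript = str(Seq(spliced).reverse_complement())
        # variant at genomic 0-based 210 (inside exon1): transcript index
        coords = list(range(228, 219, -1)) + list(range(211, 199, -1))
        t_idx = coords.index(210)
        alt_t = str(Seq("T").complement())
        alt_transcript = transcript[:t_idx] + alt_t + transcript[t_idx + 1 :]
        manual_ref_aa = str(Seq(transcript).translate())[t_idx // 3]
        manual_alt_aa = str(Seq(alt_transcript).translate())[t_idx // 3]
        expected = ("coding_synonymous" if manual_ref_aa == manual_alt_aa
                    else "coding_nonsynonymous")
        cq = classify_consequence(self._site(211, "G", "T"), self.ann, self.ref)
        assert cq.consequence == expected
        assert cq.aa_change == f"{manual_ref_aa}{t_idx // 3 + 1}{manual_alt_aa}"

    def test_precedence_cpg_over_regulatory(self):
        assert classify_consequence(self._site(345, "T", "C"), self.ann,
                                    self.ref).consequence == "CpG_island"
        assert classify_consequence(self._site(380, "T", "C"), self.ann,
                                    self.ref).consequence == "regulatory"

    def test_intron_and_intergenic(self):
        cq = classify_consequence(self._site(215, "T", "C"), self.ann, self.ref)
        assert cq.consequence == "intron" and cq.gene == "minusg"
        assert classify_consequence(self._site(450, "T", "C"), self.ann,
                                    self.ref).consequence == "intergenic"

    def test_coding_indel_keeps_region_class(self):
        cq = classify_consequence(self._site(105, "T", "TA"), self.ann, self.ref)
        assert cq.consequence == "coding_indel"

    def test_incomplete_model_unresolved(self):
        ann = GenomeAnnotation()
        ann.add_gene_model(GeneModel("frag", "chr1", "+", [(100, 120)]))
        cq = classify_consequence(self._site(105, "T", "C"), ann, self.ref)
        assert cq.consequence == "coding_unresolved"

    def test_vcf_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            classify_consequence(self._site(103, "C", "A"), self.ann, self.ref)


class TestCandidateReport:
    def test_recovers_planted_variants(self, cohort, annotation, reference,
                                       fixture_bundle):
        gm, groups = cohort
        report = candidate_report(gm, groups, annotation, reference)
        truth = {c["contrast"]: c for c in fixture_bundle.truth["causal"]}
        nt = report.nt_table
        assert truth["NT"]["pos"] in set(nt.pos)
        row = nt[nt.pos == truth["NT"]["pos"]].iloc[0]
        assert row.consequence == "coding_nonsynonymous"
        assert row.zygosity_label == "heterogeneous"
        st = report.st_table
        assert truth["ST"]["pos"] in set(st.pos)
        assert st[st.pos == truth["ST"]["pos"]].iloc[0].consequence == "CpG_island"

    def test_stage_counts_monotone(self, cohort, annotation, reference):
        gm, groups = cohort
        c = candidate_report(gm, groups, annotation, reference).stage_counts
        nt = c["NT"]
        assert nt["exclusive_snv"] >= nt["coding"] >= nt["nonsynonymous"]
        st = c["ST"]
        assert st["exclusive_snv"] + st["exclusive_indel"] >= st["regulatory_class"]

    def test_equals_composition_of_operations(self, cohort, annotation, reference):
        """The report applies exactly the documented filter chain, nothing more."""
        gm, groups = cohort
        report = candidate_report(gm, groups, annotation, reference)
        excl = exclusive_variants(gm, groups, "NT", "LT")
        expected = []
        for s in excl:
            if s.site.vclass != "SNV":
                continue
            cq = classify_consequence(s.site, annotation, reference)
            if cq.consequence == "coding_nonsynonymous":
                expected.append(s.site.pos)
        assert sorted(report.nt_table.pos) == sorted(expected)

    def test_no_exclusive_sites_gives_empty_tables(self, annotation, reference):
        samples = [f"n{i}" for i in range(4)] + [f"l{i}" for i in range(3)] + ["s0"]
        labels = ["NT"] * 4 + ["LT"] * 3 + ["ST"]
        codes = np.full((5, 8), HET)
        gm = make_gm(codes, samples=samples, start_pos=120_000)
        groups = make_groups(samples, labels)
        report = candidate_report(gm, groups, annotation, reference)
        assert report.nt_table.empty and report.st_table.empty
        assert report.stage_counts["NT"]["exclusive_snv"] == 0
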