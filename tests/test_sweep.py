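"""Star-like sweep spectrum, CLR scan, and top-5% evidence intersection."""
import numpy as np
import pandas as pd
import pytest

from tailsweep.core import PolarizedSite, VariantSite
from tailsweep.popgen import SiteFrequencySpectrum
from tailsweep.simulate import neutral_background_sfs, simulate_sweep_region
from tailsweep.sweep import (
    CandidateBin, SweepModel, SweepModelParams, background_sfs, clr_scan,
    combine_evidence, default_alpha_grid, genes_in_bins, sweep_site_probability,
)


def _psites(bs, n, positions=None):
    positions = positions if positions is not None else range(100, 100 + len(bs))
    return [PolarizedSite(VariantSite("chr1", int(p), "A", "T"), n, int(b), True)
            for p, b in zip(positions, bs)]


class TestBackgroundSfs:
    def test_tally_before_smoothing(self):
        sfs = background_sfs(_psites([1, 1, 1, 2], 4), smoothing=0.0)
        np.testing.assert_allclose(sfs.values, [0, 0.75, 0.25, 0, 0])

    def test_smoothing_fills_empty_classes(self):
        sfs = background_sfs(_psites([1, 1, 1, 2], 4))
        assert sfs.values[3] > 0 and sfs.values.sum() == pytest.approx(1.0)

    def test_no_polarizable_sites_errors(self):
        bad = [PolarizedSite(VariantSite("chr1", 5, "A", "T"), 4, None, False)]
        with pytest.raises(ValueError):
            background_sfs(bad)

    def test_neutral_simulation_recovers_one_over_j(self):
        """Coalescent-simulated counts follow the Watterson q_j ~ 1/j spectrum."""
        from scipy.stats import chisquare
        from tailsweep.simulate import SimConfig, simulate_neutral_loci
        cfg = SimConfig(seed=9, n_nt=4, n_st=3, n_lt=3, n_outgroup=1,
                        split_time=0.0, theta=2.0, n_loci=800)
        loci = simulate_neutral_loci(cfg)
        n = 20
        counts = np.zeros(n + 1)
        for l in loci:
            js = l.derived[:, :n].sum(axis=1)
            for j in js[(js > 0) & (js < n)]:
                counts[j] += 1
        expected = 1.0 / np.arange(1, n)
        expected = expected / expected.sum() * counts[1:n].sum()
        assert chisquare(counts[1:n], expected).pvalue > 0.01


class TestSweepSiteProbability:
    n = 10
    bg = neutral_background_sfs(10)

    def test_params_validation(self):
        assert SweepModelParams(1e-4, 0.0).p_escape == 0.0
        with pytest.raises(ValueError):
            SweepModelParams(0.0, 5.0)

    def test_normalizes_over_all_classes(self):
        model = SweepModel(self.bg)
        for alpha in (1e-6, 1e-4, 1e-2):
            for d in (0.0, 50.0, 5_000.0, 500_000.0):
                P = model.site_prob_matrix(alpha, np.array([d]))[0]
                assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_alpha_d_limit_is_background(self):
        P = SweepModel(self.bg).site_prob_matrix(1.0, np.array([1e9]))[0]
        np.testing.assert_allclose(P, self.bg.values, atol=1e-12)

    def test_zero_distance_is_complete_hitchhiking(self):
        P = SweepModel(self.bg).site_prob_matrix(1e-5, np.array([0.0]))[0]
        assert P[1:-1].sum() == pytest.approx(0.0, abs=1e-15)
        # all derived mass concentrates on the fixed class
        q1 = self.bg.polymorphic()
        derived_mass = sum(q1.values[j] * j / self.n for j in range(self.n + 1))
        assert P[self.n] == pytest.approx(derived_mass, abs=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sweep_site_probability(1, 8, 100.0, 1e-4, self.bg)

    def test_matches_generative_scheme(self):
        rng = np.random.default_rng(12)
        alpha, d, draws = 1e-5, 30_000, 20_000
        b = simulate_sweep_region(self.bg, alpha, 0.0, np.full(draws, d), rng)
        emp = np.bincount(b, minlength=self.n + 1) / draws
        ana = SweepModel(self.bg).site_prob_matrix(alpha, np.array([float(d)]))[0]
        se = np.sqrt(ana * (1 - ana) / draws)
        assert np.all(np.abs(emp - ana) <= 3 * np.maximum(se, 1e-9))

    def test_distortion_shrinks_with_alpha_and_distance(self):
        """Total variation from background is non-increasing in alpha and d."""
        model = SweepModel(self.bg)
        for alpha in (1e-6, 1e-5, 1e-4):
            tvs = [0.5 * np.abs(model.site_prob_matrix(alpha, np.array([d]))[0]
                                - self.bg.values).sum()
                   for d in (0, 1_000, 10_000, 100_000, 1_000_000)]
            assert all(a >= b - 1e-12 for a, b in zip(tvs, tvs[1:]))
        for d in (0, 1_000, 10_000):
            tvs = [0.5 * np.abs(model.site_prob_matrix(a, np.array([float(d)]))[0]
                                - self.bg.values).sum()
                   for a in (1e-7, 1e-6, 1e-5, 1e-4)]
            assert all(x >= y - 1e-12 for x, y in zip(tvs, tvs[1:]))


class TestClrScan:
    def test_clr_nonnegative_and_near_zero_under_null(self):
        rng = np.random.default_rng(13)
        n = 12
        bg = neutral_background_sfs(n)
        pos = np.sort(rng.integers(1, 200_000, 400))
        b = rng.choice(n + 1, size=400, p=bg.values)
        keep = (b > 0) & (b < n)
        track = clr_scan(_psites(b[keep], n, pos[keep]),
                         [50_000, 100_000, 150_000],
                         background=bg, n=n)
        assert (track.clr >= 0).all()
        assert track.clr.max() < 5.0

    def test_empty_radius_reports_missing(self):
        track = clr_scan(_psites([1, 2], 10, [100, 200]), [900_000],
                         radius=1000, n=10)
        assert np.isnan(track.clr[0]) and track.n_sites[0] == 0

    def test_sweep_signal_recovered_at_center(self):
        rng = np.random.default_rng(14)
        n, alpha, center = 20, 2e-5, 100_000
        bg = neutral_background_sfs(n)
        pos = np.sort(rng.integers(1, 2 * center, 1500))
        b = simulate_sweep_region(bg, alpha, center, pos.astype(float), rng)
        keep = (b > 0) & (b < n)
        track = clr_scan(_psites(b[keep], n, pos[keep]), [center, 10_000],
                         background=bg, n=n)
        at_center = track.set_index("position")
        assert at_center.loc[center, "clr"] > at_center.loc[10_000, "clr"]
        assert alpha / 2 <= at_center.loc[center, "alpha_hat"] <= alpha * 2


def _bin_table(rng, n_bins=20):
    tajd = pd.DataFrame({
        "chrom": "chr1", "start": 50_000 * np.arange(n_bins),
        "end": 50_000 * (np.arange(n_bins) + 1), "value": rng.normal(size=n_bins),
    })
    fst = tajd.copy()
    fst["value"] = rng.random(n_bins)
    clr = pd.DataFrame({
        "position": tajd.start + 25_000, "clr": rng.exponential(size=n_bins),
    })
    return clr, fst, tajd


def _bruteforce_intersection(clr, fst, tajd, q=0.05):
    n = len(tajd)
    k = max(1, int(np.floor(q * n)))
    clr_by_bin = clr.clr.to_numpy()
    top_clr = set(np.argsort(clr_by_bin)[-k:])
    top_fst = set(np.argsort(fst.value.to_numpy())[-k:])
    low_d = set(np.argsort(tajd.value.to_numpy())[:k])
    return top_clr & top_fst & low_d


class TestCombineEvidence:
    def test_single_triple_top_bin_returned(self):
        rng = np.random.default_rng(20)
        while True:  # find a table whose brute-force intersection is exactly one bin
            clr, fst, tajd = _bin_table(rng)
            expected = _bruteforce_intersection(clr, fst, tajd)
            if len(expected) == 1:
                break
        bins, _ = combine_evidence(clr, fst, tajd)
        assert {b.start // 50_000 for b in bins} == expected

    def test_disjoint_top_sets_empty(self):
        n = 20
        base = pd.DataFrame({"chrom": "chr1", "start": 50_000 * np.arange(n),
                             "end": 50_000 * (np.arange(n) + 1)})
        tajd = base.assign(value=np.arange(n, dtype=float))          # min at bin 0
        fst = base.assign(value=np.roll(np.arange(n, dtype=float), 5))  # max at bin 14
        clr = pd.DataFrame({"position": base.start + 10,
                            "clr": np.roll(np.arange(n, dtype=float), 10)})
        bins, _ = combine_evidence(clr, fst, tajd)
        assert bins == []

    def test_candidate_fraction_bounded_by_q(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n_bins = int(rng.integers(20, 120))
            clr, fst, tajd = _bin_table(rng, n_bins)
            bins, _ = combine_evidence(clr, fst, tajd)
            assert len(bins) <= 0.05 * n_bins

    def test_undefined_bins_excluded(self):
        rng = np.random.default_rng(22)
        clr, fst, tajd = _bin_table(rng)
        fst.loc[3, "value"] = np.nan
        bins, thresholds = combine_evidence(clr, fst, tajd)
        assert thresholds["n_defined"] == 19
        assert all(b.start != 3 * 50_000 for b in bins)

    def test_union_mode_supersets_intersection(self):
        rng = np.random.default_rng(23)
        clr, fst, tajd = _bin_table(rng, 60)
        inter, _ = combine_evidence(clr, fst, tajd, mode="intersection")
        union, _ = combine_evidence(clr, fst, tajd, mode="union")
        assert {b.start for b in inter} <= {b.start for b in union}

    def test_matches_bruteforce_on_fuzzed_tables(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            clr, fst, tajd = _bin_table(rng, int(rng.integers(20, 80)))
            bins, _ = combine_evidence(clr, fst, tajd)
            assert {b.start // 50_000 for b in bins} == \
                _bruteforce_intersection(clr, fst, tajd)


class TestGenesInBins:
    def _bin(self, start, end):
        return CandidateBin("chr5", start, end, 1, 1, -1, True, True, True, [])

    def test_overlapping_gene_reported(self):
        from tailsweep.annotation import GeneModel, GenomeAnnotation
        ann = GenomeAnnotation()
        ann.add_gene_model(
            GeneModel("ANKRD11-like", "chr5", "+", [(64_190_000, 64_260_000)]))
        # the 64.2-64.25 Mb candidate bin overlaps the gene
        bins, union = genes_in_bins([self._bin(64_200_000, 64_250_000)], ann)
        assert bins[0].genes == ["ANKRD11-like"] and union == ["ANKRD11-like"]

    def test_abutting_gene_not_reported(self):
        from tailsweep.annotation import GeneModel, GenomeAnnotation
        ann = GenomeAnnotation()
        ann.add_gene_model(GeneModel("g", "chr5", "+", [(50_000, 50_300)]))
        bins, union = genes_in_bins([self._bin(0, 50_000)], ann)
        assert bins[0].genes == [] and union == []

    def test_shared_gene_deduplicated_in_union(self):
        from tailsweep.annotation import GeneModel, GenomeAnnotation
        ann = GenomeAnnotation()
        ann.add_gene_model(GeneModel("g", "chr5", "+", [(0, 150_000)]))
        bins = [self._bin(s, s + 50_000) for s in (0, 50_000, 100_000)]
        _, union = genes_in_bins(bins, ann)
        assert union == ["g"]
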