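import numpy as np
import pytest
from scipy import stats

from lncse.intervals import AnnotationSet, Gene, GenomicInterval, Peak
from lncse.sigstats import (
    go_region_binomial,
    loess_smooth,
    meta_profile,
    overlap_enrichment,
    regulatory_domains,
    wilcoxon_rank_sum,
)
from lncse.tracks import SignalTrack


def mk_peaks(positions, width=100):
    return [
        Peak(GenomicInterval("chrS", p - width // 2, p + width // 2), f"p{i}")
        for i, p in enumerate(positions)
    ]


class TestOverlapEnrichment:
    def test_reference_covering_genome_gives_ratio_one_p_one(self):
        refs = [GenomicInterval("chrS", 0, 10_000)]
        ratio, p = overlap_enrichment(mk_peaks([500, 5000, 9000]), refs, 10_000)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_observed_gives_ratio_zero_p_one(self):
        refs = [GenomicInterval("chrS", 9000, 10_000)]
        ratio, p = overlap_enrichment(mk_peaks([500, 1000]), refs, 10_000)
        assert ratio == 0.0
        assert p == pytest.approx(1.0)

    def test_half_genome_all_hits_closed_form(self):
        # 10 midpoints all inside a half-genome reference: p = 0.5 ** 10
        refs = [GenomicInterval("chrS", 0, 5_000)]
        ratio, p = overlap_enrichment(mk_peaks([200 + 400 * i for i in range(10)]), refs, 10_000)
        assert ratio == pytest.approx(2.0)
        assert p == pytest.approx(0.5**10, rel=1e-12)

    def test_zero_reference_coverage_is_error(self):
        with pytest.raises(ValueError):
            overlap_enrichment(mk_peaks([100]), [], 10_000)

    def test_synthetic_atac_enrichment_direction(self, default_data):
        from lncse.simulate import sample_atac_peaks

        refs = [
            GenomicInterval("chrS", s, e) for s, e in default_data.truth.se_intervals
        ]
        peaks = sample_atac_peaks(default_data.cfg, default_data.atac)
        ratio, p = overlap_enrichment(peaks, refs, default_data.cfg.genome_length)
        assert ratio > 1.0
        assert p < 0.01

    def test_no_planted_fold_means_no_enrichment(self):
        from lncse.simulate import SimConfig, simulate_dataset, sample_atac_peaks

        data = simulate_dataset(SimConfig.compact(seed=5, atac_se_fold=1.0))
        refs = [GenomicInterval("chrS", s, e) for s, e in data.truth.se_intervals]
        peaks = sample_atac_peaks(data.cfg, data.atac)
        ratio, _ = overlap_enrichment(peaks, refs, data.cfg.genome_length)
        frac = sum(e - s for s, e in data.truth.se_intervals) / data.cfg.genome_length
        # sampling error on n*frac hits: ~3 sigma band around ratio 1
        sigma = np.sqrt(frac * (1 - frac) / (len(peaks) * frac**2))
        assert abs(ratio - 1.0) < 4 * sigma + 0.05


class TestMetaProfile:
    def test_constant_track_gives_flat_profile_smoothing_preserved(self):
        track = SignalTrack("chrS", 100, np.full(1000, 2.5))
        prof = meta_profile(track, [20_000, 50_000], halfwidth=2000)
        assert np.allclose(prof.mean, 2.5)
        assert np.allclose(prof.smoothed, 2.5)
        assert len(prof.smoothed) == len(prof.mean) == len(prof.offsets)

    def test_single_center_equals_track_slice(self):
        rng = np.random.default_rng(0)
        track = SignalTrack("chrS", 100, rng.gamma(2, 1, 1000))
        prof = meta_profile(track, [50_000], halfwidth=1000)
        cb = 50_000 // 100
        assert np.allclose(prof.mean, track.values[cb - 10 : cb + 11])

    def test_edge_centers_skipped_and_counted(self):
        track = SignalTrack("chrS", 100, np.ones(100))
        prof = meta_profile(track, [50, 5000], halfwidth=2000)
        assert prof.n_centers_used == 1
        assert prof.n_centers_skipped == 1

    def test_planted_se_centers_exceed_random_centers(self, default_data):
        truth = default_data.truth
        se_centers = [(s + e) // 2 for s, e in truth.se_intervals]
        rng = np.random.default_rng(1)
        random_centers = rng.integers(10_000, default_data.cfg.genome_length - 10_000, 50)
        se_prof = meta_profile(default_data.atac, se_centers)
        rand_prof = meta_profile(default_data.atac, list(map(int, random_centers)))
        assert se_prof.mean.mean() > rand_prof.mean.mean()


class TestLoess:
    def test_recovers_smooth_trend(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 200)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.05, 200)
        sm = loess_smooth(x, y, span=0.3)
        assert np.sqrt(np.mean((sm - np.sin(2 * np.pi * x)) ** 2)) < 0.1


from oracles import exact_rank_sum_p


class TestWilcoxon:
    def test_identical_multisets_give_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(a, list(a))
        assert p == pytest.approx(1.0)

    def test_textbook_separation_example_is_exact(self):
        # only one of C(6,3)=20 assignments gives rank sum 6: p = 2/20
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_samples_match_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        # integer data induces ties, exercising the midrank handling
        a = rng.integers(0, 8, n1).astype(float)
        b = rng.integers(0, 8, n2).astype(float) + rng.choice([0, 1])
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_normal_approximation_close_to_exact_on_continuous_data(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        _, p = wilcoxon_rank_sum(a, b, method="asymptotic")
        assert abs(p - exact_rank_sum_p(a, b)) <= 0.02

    def test_agrees_with_scipy_mannwhitneyu(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        _, p = wilcoxon_rank_sum(a, b)  # auto picks the asymptotic path here
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_all_identical_values_give_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0


class TestGoBinomial:
    def _annotation(self):
        genes = [
            Gene("g1", "g1", "protein_coding", GenomicInterval("chrS", 30_000, 31_000, "+")),
            Gene("g2", "g2", "protein_coding", GenomicInterval("chrS", 200_000, 201_000, "+")),
        ]
        return AnnotationSet(genes, {"T1": {"g1"}, "T2": {"g2"}, "TBOTH": {"g1", "g2"}})

    def test_domain_covering_genome_gives_p_one(self):
        gene = Gene("g", "g", "protein_coding", GenomicInterval("chrS", 30_000, 31_000, "+"))
        ann = AnnotationSet([gene], {"ALL": {"g"}})
        regions = [GenomicInterval("chrS", s, s + 100) for s in range(0, 60_000, 6000)]
        df = go_region_binomial(regions, ann.go_map, ann, genome_length=60_000,
                                basal=5000, extension=50_000)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_monotone_in_observed_count(self):
        ann = self._annotation()
        base = [GenomicInterval("chrS", 29_000, 29_100)]
        more = base + [GenomicInterval("chrS", 30_500, 30_600)]
        p1 = go_region_binomial(base, {"T1": {"g1"}}, ann, 1_000_000).loc[0, "p"]
        p2 = go_region_binomial(more, {"T1": {"g1"}}, ann, 1_000_000).loc[0, "p"]
        assert p2 < p1

    def test_domains_truncate_at_neighbours(self):
        genes = [
            Gene("a", "a", "protein_coding", GenomicInterval("chrS", 100_000, 101_000, "+")),
            Gene("b", "b", "protein_coding", GenomicInterval("chrS", 120_000, 121_000, "+")),
        ]
        ann = AnnotationSet(genes)
        dom = regulatory_domains(ann, basal=5000, extension=50_000)
        # a's extension toward b stops at b's basal start (115 000)
        assert dom["a"].end == 115_000
        assert dom["b"].start == 105_001

    def test_term_enriched_by_construction_has_smallest_q(self, default_data):
        # query regions sitting on the designated term's member promoters must
        # rank that term first
        from lncse.intervals import tss_of

        d = default_data
        term = d.truth.designated_go_term
        regions = []
        for gid in sorted(d.annotation.go_map[term]):
            t = tss_of(d.annotation[gid])
            regions.append(GenomicInterval("chrS", max(0, t - 100), t + 100))
        df = go_region_binomial(regions, d.annotation.go_map, d.annotation,
                                d.cfg.genome_length)
        assert df.loc[0, "term"] == term
        assert df.loc[0, "q"] == df["q"].min()
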