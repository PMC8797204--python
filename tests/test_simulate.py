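import json

import numpy as np
import pytest

from lncse.intervals import read_annotation, read_bed_peaks, read_go_map
from lncse.loops import read_contacts
from lncse.de import read_counts
from lncse.se import stitch_peaks
from lncse.simulate import (
    SimConfig,
    SimulationTruth,
    generate_annotation,
    simulate_contact_map,
    simulate_counts,
    simulate_dataset,
    simulate_peaks_and_signal,
)
from lncse.tracks import read_signal_track


class TestConfigValidation:
    def test_constraints_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(n_se=2, n_lncrna_se=3)
        with pytest.raises(ValueError):
            SimConfig(peaks_per_se=2)
        with pytest.raises(ValueError):
            SimConfig(decay_exponent=0.0)
        with pytest.raises(ValueError):
            SimConfig(genome_length=1_000_001, contact_binsize=5000)

    def test_genome_too_small_raises_explicitly(self):
        with pytest.raises(ValueError, match="too small"):
            generate_annotation(
                SimConfig(genome_length=1_000_000, contact_binsize=1000,
                          n_se=30, n_lncrna_se=5)
            )


class TestDeterminism:
    def test_same_seed_gives_identical_annotation(self):
        cfg = SimConfig.compact(seed=1)
        ann1, truth1 = generate_annotation(cfg)
        ann2, truth2 = generate_annotation(cfg)
        assert ann1.genes == ann2.genes
        assert truth1 == truth2

    def test_same_seed_gives_identical_counts(self):
        cfg = SimConfig.compact(seed=2)
        ann, truth = generate_annotation(cfg)
        c1, _ = simulate_counts(cfg, ann, truth)
        c2, _ = simulate_counts(cfg, ann, truth)
        assert c1.equals(c2)

    def test_full_dataset_byte_identical_on_disk(self, tmp_path):
        cfg = SimConfig.compact(seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg).write_all(d1)
        simulate_dataset(cfg).write_all(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name


class TestAnnotation:
    def test_requested_gene_counts(self):
        cfg = SimConfig.compact(seed=4, n_lncrna=50)
        ann, _ = generate_annotation(cfg)
        assert len(ann.lncrnas) == 50
        assert len(ann.coding_genes) == cfg.n_coding_genes

    def test_zero_coding_genes_is_valid(self):
        cfg = SimConfig.compact(
            seed=5, n_coding_genes=0, n_looped_de_lncrna_se=0, n_de_lncrna_se=0,
            n_looped_other_se=0,
        )
        ann, truth = generate_annotation(cfg)
        assert ann.coding_genes == []
        assert truth.loops == []

    def test_designated_term_contains_candidate_target(self):
        ann, truth = generate_annotation(SimConfig.compact(seed=6))
        assert truth.candidate_target in ann.go_map[truth.designated_go_term]
        # other looped DE targets are excluded so the funnel answer is unique
        for loop in truth.loops:
            if loop["target_gene"] != truth.candidate_target:
                assert loop["target_gene"] not in ann.go_map[truth.designated_go_term]

    def test_candidate_satisfies_all_four_conditions(self):
        ann, truth = generate_annotation(SimConfig.compact(seed=7))
        # (a) planted SE containing the candidate lncRNA TSS
        assert truth.candidate_se in truth.lncrna_se_map
        assert truth.lncrna_se_map[truth.candidate_se] == truth.candidate_lncrna
        # (b) anchored by a planted loop to a coding promoter
        assert any(l["se_id"] == truth.candidate_se for l in truth.loops)
        # (c) the lncRNA is planted DE
        assert truth.candidate_lncrna in truth.de_lncrnas
        # (d) the target carries the designated GO term
        assert truth.candidate_target in ann.go_map[truth.designated_go_term]

    def test_planted_loop_separations_bracketed(self):
        _, truth = generate_annotation(SimConfig(seed=8))
        bs = SimConfig().contact_binsize
        for loop in truth.loops:
            sep = abs(loop["se_bin"] - loop["promoter_bin"]) * bs
            assert 55_000 <= sep <= 405_000


class TestPeaksAndSignal:
    def test_planted_clusters_stitch_into_single_regions(self):
        cfg = SimConfig.compact(seed=9)
        ann, truth = generate_annotation(cfg)
        peaks, _, _, _ = simulate_peaks_and_signal(cfg, ann, truth)
        for se_id, (s, e) in enumerate(truth.se_intervals):
            members = [p for p in peaks if p.name.startswith(f"se{se_id}_")]
            regions = stitch_peaks(members, 12_500)
            assert len(regions) == 1
            assert (regions[0].interval.start, regions[0].interval.end) == (s, e)

    def test_every_planted_lncrna_se_contains_its_lncrna_tss(self):
        from lncse.intervals import tss_of

        cfg = SimConfig.compact(seed=10)
        ann, truth = generate_annotation(cfg)
        for se_id, gid in truth.lncrna_se_map.items():
            s, e = truth.se_intervals[se_id]
            assert s <= tss_of(ann[gid]) < e

    def test_atac_fold_one_means_flat_coverage(self):
        cfg = SimConfig.compact(seed=11, atac_se_fold=1.0)
        ann, truth = generate_annotation(cfg)
        _, _, _, atac = simulate_peaks_and_signal(cfg, ann, truth)
        bs = cfg.signal_binsize
        inside = np.concatenate(
            [atac.values[s // bs : e // bs] for s, e in truth.se_intervals]
        )
        outside_mean = atac.values.mean()
        assert inside.mean() == pytest.approx(outside_mean, rel=0.1)


class TestContactMap:
    def test_symmetric_by_construction_and_nonnegative(self):
        cfg = SimConfig.compact(seed=12)
        _, truth = generate_annotation(cfg)
        M = simulate_contact_map(cfg, truth)
        assert (M.bin1 <= M.bin2).all()
        assert (M.count >= 0).all()

    def test_decay_exponent_one_halves_mean_at_double_distance(self):
        cfg = SimConfig.compact(seed=13, decay_exponent=1.0)
        _, truth = generate_annotation(cfg)
        M = simulate_contact_map(cfg, truth)
        d = M.bin2 - M.bin1

        def mean_at(k):
            return M.count[d == k].sum() / (M.n_bins - k)

        for k in (10, 25, 60):
            assert mean_at(k) / mean_at(2 * k) == pytest.approx(2.0, rel=0.15)

    def test_null_map_has_no_planted_boost(self):
        cfg = SimConfig.compact(seed=14, loop_fold=1.0)
        _, truth = generate_annotation(cfg)
        M = simulate_contact_map(cfg, truth)
        d = M.bin2 - M.bin1
        for loop in truth.loops:
            i, j = sorted((loop["se_bin"], loop["promoter_bin"]))
            sel = (M.bin1 == i) & (M.bin2 == j)
            count = M.count[sel].sum()
            mu = cfg.contact_mu1 / (j - i)
            assert count < mu + 6 * np.sqrt(mu) + 1


class TestCounts:
    def test_nonpositive_dispersion_is_error(self):
        cfg = SimConfig.compact(seed=15)
        ann, truth = generate_annotation(cfg)
        cfg.nb_dispersion = 0.0
        with pytest.raises(ValueError):
            simulate_counts(cfg, ann, truth)

    def test_null_effect_size_keeps_groups_exchangeable(self):
        cfg = SimConfig.compact(seed=16, de_log2fc=0.0)
        ann, truth = generate_annotation(cfg)
        counts, groups = simulate_counts(cfg, ann, truth)
        from lncse.de import differential_expression

        res = differential_expression(counts, groups)
        assert (res["p"] < 0.05).mean() < 0.1
        assert (res["q"] < 0.05).sum() <= 2

    def test_planted_genes_floor_guarantees_expression(self):
        cfg = SimConfig.compact(seed=17)
        ann, truth = generate_annotation(cfg)
        counts, _ = simulate_counts(cfg, ann, truth)
        for gid in truth.de_lncrnas:
            assert counts.loc[gid].mean() > 5


class TestRoundTrips:
    def test_all_planted_objects_survive_writers_and_readers(self, tmp_path):
        cfg = SimConfig.compact(seed=18)
        data = simulate_dataset(cfg)
        data.write_all(tmp_path)

        assert read_bed_peaks(tmp_path / "h3k27ac_peaks.bed") == data.peaks
        ann = read_annotation(tmp_path / "annotation.tsv", tmp_path / "go.tsv")
        assert ann.genes == data.annotation.genes
        assert ann.go_map == data.annotation.go_map
        track = read_signal_track(tmp_path / "h3k27ac.tsv")
        assert np.array_equal(track.values, data.h3k27ac.values)
        assert track.binsize == data.h3k27ac.binsize
        M = read_contacts(tmp_path / "contacts.tsv")
        assert np.array_equal(M.count, data.contacts.count)
        assert np.array_equal(M.bin1, data.contacts.bin1)
        assert read_counts(tmp_path / "counts.tsv").equals(data.counts)
        truth = SimulationTruth.from_json(tmp_path / "truth.json")
        assert truth == data.truth

    def test_truth_json_is_valid_json(self, tmp_path):
        cfg = SimConfig.compact(seed=19)
        _, truth = generate_annotation(cfg)
        truth.to_json(tmp_path / "truth.json")
        with open(tmp_path / "truth.json") as fh:
            payload = json.load(fh)
        assert payload["candidate_lncrna"] == truth.candidate_lncrna
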