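"""Synthetic cohort generator: determinism, conservation and survival."""

import numpy as np
import pandas as pd
import pytest

from magphage.simulate import (
    SimulationConfig,
    TruthRecord,
    emit_region_calls,
    fragment_to_mag,
    gc_content,
    generate_host_genome,
    make_template_pool,
    mutate_sequence,
    plant_prophages,
    random_sequence,
    remap_truths_to_contigs,
    simulate_cohort,
)


class TestHostGenome:
    def test_minimal_length_yields_valid_nucleotide(self):
        assert generate_host_genome(1, 0.5, seed=1) in set("ACGT")

    def test_deterministic_under_fixed_seed(self):
        a = generate_host_genome(100_000, 0.5, seed=7)
        b = generate_host_genome(100_000, 0.5, seed=7)
        assert a == b
        assert set(a) <= set("ACGT") and len(a) == 100_000

    def test_empirical_gc_tracks_request(self):
        genome = generate_host_genome(100_000, 0.30, seed=7)
        assert 0.27 <= gc_content(genome) <= 0.33

    @pytest.mark.parametrize("length", [0, -5])
    def test_nonpositive_length_rejected(self, length):
        with pytest.raises(ValueError):
            generate_host_genome(length, 0.5, seed=1)


class TestPlantProphages:
    def test_zero_prophages_is_identity(self):
        genome = generate_host_genome(50_000, 0.45, seed=2)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 0))
        modified, truths, genes = plant_prophages(genome, cfg, seed=3)
        assert modified == genome
        assert truths == []
        assert (genes["category"] != "viral").all() or genes["category"].eq("viral").mean() < 0.2

    def test_modified_length_is_sum_of_insertions(self):
        genome = generate_host_genome(1_000_000, 0.45, seed=2)
        cfg = SimulationConfig(
            prophage_count_dist=("fixed", 2), prophage_length_dist=("fixed", 15_000)
        )
        modified, truths, _ = plant_prophages(genome, cfg, seed=5)
        assert len(modified) == 1_030_000
        assert sum(t.length for t in truths) == 30_000

    def test_prophages_never_overlap_and_match_insert(self):
        genome = generate_host_genome(200_000, 0.45, seed=9)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 3))
        modified, truths, _ = plant_prophages(genome, cfg, seed=5)
        intervals = sorted((t.genome_start, t.genome_end) for t in truths)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2
        # conservation: inserted bases account exactly for the length change
        assert len(modified) - len(genome) == sum(t.length for t in truths)

    def test_deterministic_truth_tables(self):
        genome = generate_host_genome(100_000, 0.45, seed=1)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 2))
        out1 = plant_prophages(genome, cfg, seed=42)
        out2 = plant_prophages(genome, cfg, seed=42)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
        pd.testing.assert_frame_equal(out1[2], out2[2])

    def test_total_prophage_length_exceeding_genome_rejected(self):
        genome = generate_host_genome(10_000, 0.45, seed=1)
        cfg = SimulationConfig(
            prophage_count_dist=("fixed", 2), prophage_length_dist=("fixed", 9_000)
        )
        with pytest.raises(ValueError, match="exceeds genome length"):
            plant_prophages(genome, cfg, seed=1)

    def test_gc_contrast_matches_composition_shift(self):
        genome = generate_host_genome(150_000, 0.45, seed=4)
        cfg = SimulationConfig(
            prophage_count_dist=("fixed", 2),
            prophage_length_dist=("fixed", 15_000),
            composition_shift=0.08,
        )
        modified, truths, _ = plant_prophages(genome, cfg, seed=6)
        host_gc = gc_content(genome)
        for t in truths:
            inside_gc = gc_content(modified[t.genome_start:t.genome_end])
            assert abs(inside_gc - host_gc - 0.08) <= 0.02

    def test_gene_labels_respect_prophage_boundaries(self):
        genome = generate_host_genome(100_000, 0.45, seed=4)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 2))
        modified, truths, genes = plant_prophages(genome, cfg, seed=6)
        intervals = [(t.genome_start, t.genome_end) for t in truths]
        inside = genes.apply(
            lambda g: any(s <= g["start"] and g["end"] <= e for s, e in intervals), axis=1
        )
        # metabolic genes only arise inside prophages; outside is mostly cellular
        assert set(genes.loc[~inside, "category"]) <= {"cellular", "viral", "transposon"}
        assert genes.loc[inside, "category"].eq("viral").mean() > 0.6


class TestFragmentToMag:
    def _planted(self, seed=8, length=300_000):
        genome = generate_host_genome(length, 0.45, seed=seed)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 2))
        return plant_prophages(genome, cfg, seed=seed)

    def test_full_completeness_keeps_everything(self):
        modified, truths, genes = self._planted()
        mag, out_truths, _ = fragment_to_mag(
            modified, truths, completeness=100, contamination=0, seed=3, genes=genes
        )
        assert mag.total_bp == len(modified)
        assert all(t.survived_fragmentation for t in out_truths)

    def test_half_completeness_retains_half_the_bases(self):
        modified, truths, _ = self._planted(length=1_000_000)
        mag, _, _ = fragment_to_mag(modified, truths, completeness=50,
                                    contamination=0, seed=3)
        assert 0.48 * len(modified) <= mag.total_bp <= 0.52 * len(modified)

    def test_contamination_adds_foreign_contigs(self):
        modified, truths, _ = self._planted()
        mag, _, _ = fragment_to_mag(modified, truths, completeness=90,
                                    contamination=4, seed=3)
        foreign = [cid for cid in mag.contigs if "_f" in cid]
        retained = sum(len(mag.contigs[c]) for c in mag.contigs if "_c" in c)
        foreign_bp = sum(len(mag.contigs[c]) for c in foreign)
        assert foreign and abs(foreign_bp - 0.04 * retained) <= 0.01 * retained

    @pytest.mark.parametrize("completeness", [0, -1, 101])
    def test_invalid_completeness_rejected(self, completeness):
        modified, truths, _ = self._planted()
        with pytest.raises(ValueError):
            fragment_to_mag(modified, truths, completeness=completeness, contamination=0)

    def test_split_prophage_does_not_survive(self):
        truth = TruthRecord("pp0", "T0", genome_start=10_000, genome_end=25_000)
        pieces = [("c0", 0, 17_500), ("c1", 17_500, 40_000)]
        (out,) = remap_truths_to_contigs([truth], pieces, "magA")
        assert not out.survived_fragmentation
        whole = [("c0", 0, 40_000)]
        (out,) = remap_truths_to_contigs([truth], whole, "magA")
        assert out.survived_fragmentation
        assert (out.true_start, out.true_end) == (10_000, 25_000)

    def test_survival_monotone_in_completeness(self):
        modified, truths, _ = self._planted(seed=13)
        counts = []
        for completeness in (70, 75, 80, 85, 90, 95, 100):
            _, out, _ = fragment_to_mag(modified, truths, completeness=completeness,
                                        contamination=0, seed=21)
            counts.append(sum(t.survived_fragmentation for t in out))
        assert counts == sorted(counts)

    def test_gene_coordinates_remapped_into_contigs(self):
        modified, truths, genes = self._planted()
        mag, _, out_genes = fragment_to_mag(
            modified, truths, completeness=80, contamination=0, seed=5, genes=genes
        )
        for row in out_genes.sample(min(50, len(out_genes)), random_state=0).itertuples():
            assert 0 <= row.start < row.end <= len(mag.contigs[row.contig_id])


class TestEmitRegionCalls:
    def _survivors(self, seed=15):
        modified, truths, _ = self._plant(seed)
        mag, out, _ = fragment_to_mag(modified, truths, completeness=95,
                                      contamination=0, seed=seed)
        return mag, out

    @staticmethod
    def _plant(seed):
        genome = generate_host_genome(300_000, 0.45, seed=seed)
        cfg = SimulationConfig(prophage_count_dist=("fixed", 3))
        return plant_prophages(genome, cfg, seed=seed)

    def test_noiseless_calls_equal_truth(self):
        mag, truths = self._survivors()
        calls = emit_region_calls(truths, mag.contig_lengths, jitter_sd=0,
                                  fnr=0, fpr_per_mag=0, seed=1)
        survived = [t for t in truths if t.survived_fragmentation]
        assert len(calls) == len(survived)
        call_keys = {(c.contig_id, c.start, c.end) for c in calls}
        truth_keys = {(t.contig_id, t.true_start, t.true_end) for t in survived}
        assert call_keys == truth_keys
        assert all(c.left_flank_present and c.right_flank_present for c in calls)

    def test_total_miss_rate_gives_empty_table(self):
        mag, truths = self._survivors()
        calls = emit_region_calls(truths, mag.contig_lengths, jitter_sd=0,
                                  fnr=1.0, fpr_per_mag=0, seed=1)
        assert calls == []

    def test_emission_count_matches_bernoulli_replay(self):
        mag, truths = self._survivors()
        fnr, seed = 0.2, 99
        calls = emit_region_calls(truths, mag.contig_lengths, jitter_sd=0,
                                  fnr=fnr, fpr_per_mag=0, seed=seed)
        replay = np.random.default_rng(seed)
        survived = [t for t in truths if t.survived_fragmentation]
        expected = sum(replay.random() >= fnr for _ in survived)
        assert len(calls) == expected

    def test_jittered_boundaries_stay_on_contig(self):
        mag, truths = self._survivors()
        calls = emit_region_calls(truths, mag.contig_lengths, jitter_sd=500,
                                  fnr=0, fpr_per_mag=0, seed=5)
        for c in calls:
            assert 0 <= c.start < c.end <= mag.contig_lengths[c.contig_id]


class TestSimulateCohort:
    def test_counts_and_files(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_individuals=1, n_mags_per_individual=2)
        cohort = simulate_cohort(cfg, out_dir=tmp_path)
        assert len(cohort.mags) == 2
        assert len(list((tmp_path / "mags").glob("*.fasta"))) == 2
        assert len(cohort.metadata) == 2

    def test_per_sample_cpm_totals(self, noisy_cohort):
        totals = noisy_cohort.abundance.groupby("sample_id")["cpm"].sum()
        assert np.allclose(totals, 1_000_000.0)

    def test_rerun_reproduces_manifest_and_truth(self):
        cfg = SimulationConfig(seed=5, n_individuals=1, n_mags_per_individual=2)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.manifest["config_hash"] == b.manifest["config_hash"]
        assert a.truths == b.truths
        pd.testing.assert_frame_equal(a.region_calls, b.region_calls)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"region_fnr": 1.5},
            {"composition_shift": 0.7},
            {"completeness_range": (0, 100)},
            {"contamination_range": (0, 9)},
            {"host_genome_length": -1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()

    def test_template_mutation_keeps_high_identity(self, rng):
        seq = random_sequence(10_000, 0.5, rng)
        mutated = mutate_sequence(seq, 0.02, rng)
        diffs = sum(a != b for a, b in zip(seq, mutated))
        assert 100 <= diffs <= 300  # binomial(10k, 0.02) bulk

    def test_template_pool_is_deterministic(self):
        cfg = SimulationConfig(seed=3)
        pool1 = make_template_pool(cfg, np.random.default_rng(3))
        pool2 = make_template_pool(cfg, np.random.default_rng(3))
        assert [t.sequence for t in pool1] == [t.sequence for t in pool2]
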