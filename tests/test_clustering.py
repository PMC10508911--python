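"""Fragment-mapping ANI, greedy vOTU clustering and gene-sharing genera."""

import math

import numpy as np
import pandas as pd
import pytest

from magphage.clustering import (
    build_gene_sharing_graph,
    cluster_genus_votus,
    cluster_proteins,
    cluster_species_votus,
    compare_to_catalog,
    dereplicate,
    greedy_order,
    host_range_summary,
    pairwise_ani,
)
from magphage.simulate import random_sequence


def mutate_exact(seq, fraction, rng):
    """Substitute an exact fraction of positions with a different base."""
    n = int(round(len(seq) * fraction))
    positions = rng.choice(len(seq), size=n, replace=False)
    buf = bytearray(seq, "ascii")
    for pos in positions:
        buf[pos] = next(b for b in b"ACGT" if b != buf[pos])
    return buf.decode("ascii")


class TestPairwiseANI:
    def test_identical_sequences(self, rng):
        seq = random_sequence(20_000, 0.45, rng)
        res = pairwise_ani(seq, seq)
        assert res.ani == 1.0 and res.coverage_shorter == 1.0

    def test_unrelated_sequences_have_zero_coverage(self, rng):
        a = random_sequence(5_000, 0.45, rng)
        b = random_sequence(8_000, 0.45, rng)
        res = pairwise_ani(a, b)
        assert res.coverage_shorter == 0.0 and res.ani == 0.0

    def test_two_percent_substitutions(self, rng):
        seq = random_sequence(20_000, 0.45, rng)
        mutated = mutate_exact(seq, 0.02, rng)
        res = pairwise_ani(seq, mutated)
        assert 0.975 <= res.ani <= 0.985
        assert res.coverage_shorter > 0.95

    def test_swap_invariance(self, rng):
        a = random_sequence(12_000, 0.45, rng)
        b = mutate_exact(a, 0.03, rng)[:9_000]
        r1 = pairwise_ani(a, b)
        r2 = pairwise_ani(b, a)
        assert r1.ani == r2.ani and r1.coverage_shorter == r2.coverage_shorter

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_ani("", "ACGT")


def brute_force_greedy(sequences, ani_threshold, cov_threshold):
    """Independent oracle: materialize the full ANI matrix, then assign
    each sequence (length-descending, id-ascending) to the first existing
    representative passing both gates."""
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    matrix = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            res = pairwise_ani(sequences[a], sequences[b])
            matrix[(a, b)] = matrix[(b, a)] = (res.ani, res.coverage_shorter)
    reps, assignment = [], {}
    for sid in order:
        for rep in reps:
            ani, cov = matrix[(sid, rep)]
            if ani >= ani_threshold and cov >= cov_threshold:
                assignment[sid] = rep
                break
        else:
            reps.append(sid)
            assignment[sid] = sid
    return assignment


def random_instance(rng, n_max=14):
    """A small set of sequences with planted duplicate structure."""
    n_bases = int(rng.integers(2, 5))
    bases = [random_sequence(int(rng.integers(1_000, 2_500)), 0.45, rng)
             for _ in range(n_bases)]
    seqs = {}
    for i in range(int(rng.integers(4, n_max))):
        if rng.random() < 0.7:
            base = bases[rng.integers(0, n_bases)]
            seq = mutate_exact(base, float(rng.uniform(0, 0.08)), rng)
            if rng.random() < 0.3:  # partial copy exercises the coverage gate
                seq = seq[: int(len(seq) * rng.uniform(0.5, 0.95))]
        else:
            seq = random_sequence(int(rng.integers(1_000, 2_500)), 0.45, rng)
        seqs[f"s{i:02d}"] = seq
    return seqs


class TestGreedyClustering:
    def test_distinct_sequences_all_representatives(self, rng):
        seqs = {f"s{i}": random_sequence(2_000, 0.45, rng) for i in range(5)}
        reps, assignment = dereplicate(seqs)
        assert sorted(reps) == sorted(seqs)
        assert all(assignment[s] == s for s in seqs)

    def test_exact_duplicate_pair_collapses(self, rng):
        seq = random_sequence(3_000, 0.45, rng)
        reps, assignment = dereplicate({"a": seq, "b": seq})
        assert reps == ["a"]  # tie broken by id
        assert assignment == {"a": "a", "b": "a"}

    def test_idempotent_on_representatives(self, rng):
        seqs = random_instance(rng)
        reps, _ = dereplicate(seqs)
        reps2, assignment2 = dereplicate({r: seqs[r] for r in reps})
        assert sorted(reps2) == sorted(reps)
        assert all(assignment2[r] == r for r in reps)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            seqs = random_instance(rng)
            assignment = dict(zip(
                cluster_species_votus(seqs)["sequence_id"],
                cluster_species_votus(seqs)["species_votu_id"],
            ))
            oracle = brute_force_greedy(seqs, 0.95, 0.75)
            # same partition: members grouped identically
            by_votu, by_rep = {}, {}
            for sid, votu in assignment.items():
                by_votu.setdefault(votu, set()).add(sid)
            for sid, rep in oracle.items():
                by_rep.setdefault(rep, set()).add(sid)
            assert sorted(map(sorted, by_votu.values())) == \
                sorted(map(sorted, by_rep.values()))

    def test_coverage_gate_binds(self, rng):
        base = random_sequence(20_000, 0.45, rng)
        high_cov = mutate_exact(base[:13_000], 0.03, rng) + random_sequence(3_250, 0.45, rng)
        low_cov = mutate_exact(base[:11_500], 0.03, rng) + random_sequence(4_750, 0.45, rng)
        res_high = pairwise_ani(base, high_cov)
        res_low = pairwise_ani(base, low_cov)
        assert res_high.ani >= 0.95 and res_high.coverage_shorter >= 0.75
        assert res_low.ani >= 0.95 and res_low.coverage_shorter < 0.75
        table_high = cluster_species_votus({"a": base, "b": high_cov})
        table_low = cluster_species_votus({"a": base, "c": low_cov})
        assert table_high["species_votu_id"].nunique() == 1
        assert table_low["species_votu_id"].nunique() == 2

    def test_partition_property(self, rng):
        seqs = random_instance(rng)
        table = cluster_species_votus(seqs)
        assert len(table) == len(seqs)
        assert set(table["sequence_id"]) == set(seqs)
        sizes = table.groupby("species_votu_id").size()
        assert sizes.sum() == len(seqs)
        singletons = table[table["is_singleton"]]
        assert set(singletons.groupby("species_votu_id").size()) <= {1}
        # each vOTU has exactly one representative
        reps = table.groupby("species_votu_id")["is_representative"].sum()
        assert (reps == 1).all()

    def test_input_order_invariance(self, rng):
        seqs = random_instance(rng)
        shuffled = {k: seqs[k] for k in reversed(list(seqs))}
        t1 = cluster_species_votus(seqs).sort_values("sequence_id").reset_index(drop=True)
        t2 = cluster_species_votus(shuffled).sort_values("sequence_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_dereplication_nests_within_species_votus(self, rng):
        seqs = random_instance(rng)
        _, derep_map = dereplicate(seqs)
        species = cluster_species_votus(
            {r: seqs[r] for r in set(derep_map.values())}
        )
        votu_of_rep = dict(zip(species["sequence_id"], species["species_votu_id"]))
        votu_of_member = {sid: votu_of_rep[derep_map[sid]] for sid in seqs}
        for rep in set(derep_map.values()):
            members = [s for s, r in derep_map.items() if r == rep]
            assert len({votu_of_member[m] for m in members}) == 1


class TestProteinFamilies:
    def test_identical_proteins_one_family(self, rng):
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        families = cluster_proteins({"a": prot, "b": prot})
        assert families == {"a": "a", "b": "a"}

    def test_unrelated_proteins_stay_singletons(self, rng):
        prots = {f"p{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=180))
                 for i in range(4)}
        families = cluster_proteins(prots)
        assert all(families[p] == p for p in prots)

    def test_sixty_percent_identity_joins_seed(self, rng):
        seed_prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        variant = bytearray(seed_prot, "ascii")
        for pos in rng.choice(200, size=80, replace=False):  # 60% identity left
            variant[pos] = ord("A") if variant[pos] != ord("A") else ord("G")
        families = cluster_proteins({"seed00": seed_prot, "var00": variant.decode()})
        assert families["var00"] == "seed00"


class TestGeneSharingGraph:
    def test_full_overlap_strongest_edge(self):
        profiles = {
            "a": {"f1", "f2", "f3"}, "b": {"f1", "f2", "f3"},
            "c": {"f1", "f9", "f8"},
        }
        edges = build_gene_sharing_graph(profiles, min_weight=0.0, universe_size=20)
        weights = {(a, b): w for a, b, w in edges}
        assert weights[("a", "b")] == max(weights.values())

    def test_zero_shared_families_drops_edge(self):
        edges = build_gene_sharing_graph({"a": {"f1"}, "b": {"f2"}}, min_weight=0.0)
        assert edges == []

    def test_exact_hypergeometric_tail(self):
        # two genomes of 3 families sharing 2, universe of 10:
        # P(X >= 2) = (C(3,2) C(7,1) + C(3,3) C(7,0)) / C(10,3) = 22/120
        profiles = {"a": {"f1", "f2", "f3"}, "b": {"f1", "f2", "f4"}}
        (edge,) = build_gene_sharing_graph(profiles, min_weight=0.0, universe_size=10)
        assert edge[2] == pytest.approx(-math.log10(22 / 120), abs=1e-9)
        # below the default significance cut, the edge is dropped
        assert build_gene_sharing_graph(profiles, universe_size=10) == []

    def test_empty_profile_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no proteins"):
            edges = build_gene_sharing_graph({"a": {"f1"}, "b": set()}, min_weight=0.0)
        assert edges == []


class TestGenusClustering:
    def test_empty_edges_all_singletons(self):
        genera = cluster_genus_votus([], nodes=["a", "b", "c"])
        assert len(set(genera.values())) == 3

    def test_triangle_forms_one_genus(self):
        edges = [("a", "b", 2.0), ("b", "c", 2.0), ("a", "c", 2.0)]
        genera = cluster_genus_votus(edges, nodes=["a", "b", "c"])
        assert len(set(genera.values())) == 1

    def test_two_cliques_two_genera(self):
        edges = [("a", "b", 2.0), ("b", "c", 2.0),
                 ("x", "y", 2.0), ("y", "z", 2.0)]
        genera = cluster_genus_votus(edges, nodes=list("abcxyz"))
        assert len(set(genera.values())) == 2
        assert genera["a"] == genera["c"] != genera["x"] == genera["z"]


class TestCatalogComparison:
    def test_empty_reference_all_novel(self, rng):
        reps = {"a": random_sequence(2_000, 0.45, rng)}
        assert compare_to_catalog(reps, {}) == {"a": True}

    def test_reference_copies_nothing_novel(self, rng):
        reps = {f"r{i}": random_sequence(2_000, 0.45, rng) for i in range(3)}
        refs = {f"ref{i}": seq for i, seq in enumerate(reps.values())}
        novelty = compare_to_catalog(reps, refs)
        assert not any(novelty.values())

    def test_planted_overlap_fraction(self, rng):
        reps = {f"r{i}": random_sequence(3_000, 0.45, rng) for i in range(10)}
        # catalog holds slightly diverged copies of 4 of the 10
        refs = {f"ref{i}": mutate_exact(reps[f"r{i}"], 0.02, rng) for i in range(4)}
        novelty = compare_to_catalog(reps, refs)
        assert sum(novelty.values()) == 6


class TestHostRange:
    def test_all_singletons_zero_counts(self):
        table = pd.DataFrame({
            "species_votu_id": ["v1", "v2", "v3"],
            "host_species": ["s1", "s2", "s3"],
            "host_family": ["f1", "f2", "f3"],
        })
        assert host_range_summary(table) == (0, 0)

    def test_species_span_without_family_span(self):
        table = pd.DataFrame({
            "species_votu_id": ["v1", "v1"],
            "host_species": ["s1", "s2"],
            "host_family": ["f1", "f1"],
        })
        assert host_range_summary(table) == (1, 0)

    def test_random_table_matches_direct_tally(self, rng):
        n = 200
        table = pd.DataFrame({
            "species_votu_id": rng.choice([f"v{i}" for i in range(40)], size=n),
            "host_species": rng.choice([f"s{i}" for i in range(10)], size=n),
            "host_family": rng.choice([f"f{i}" for i in range(4)], size=n),
        })
        multi_species = multi_family = 0
        for _, g in table.groupby("species_votu_id"):
            if len(g) >= 2:
                multi_species += g["host_species"].nunique() > 1
                multi_family += g["host_family"].nunique() > 1
        assert host_range_summary(table) == (multi_species, multi_family)


def test_greedy_order_is_length_then_id():
    seqs = {"b": "AAAA", "a": "AAAA", "c": "AAAAAA"}
    assert greedy_order(seqs) == ["c", "a", "b"]
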