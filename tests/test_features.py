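"""Feature encodings (symmetry contracts) and dataset construction."""

import itertools

import numpy as np
import pytest

from gipredict.features import (GeneAnnotation, GIRecord, PAIR_COMBOS,
                                PairEncoder, SchemaError, SingleEncoder,
                                TRIPLET_COMBOS, TripletEncoder,
                                build_hybrid_gi_dataset, canonical_pair,
                                derive_mo_lethal, fitness_combo_index,
                                negative_sample_neutral_pairs, regroup_labels)


class TestFitnessCombos:
    def test_order_insensitive(self):
        assert fitness_combo_index(("L", "N")) == fitness_combo_index(("N", "L"))
        for perm in itertools.permutations(("L", "R", "N")):
            assert fitness_combo_index(perm) == fitness_combo_index(("L", "R", "N"))

    def test_six_pair_categories(self):
        idx = {fitness_combo_index(p)
               for p in itertools.product("LRN", repeat=2)}
        assert idx == set(range(6)) and len(PAIR_COMBOS) == 6

    def test_ten_triplet_categories_from_27_ordered(self):
        idx = {fitness_combo_index(t)
               for t in itertools.product("LRN", repeat=3)}
        assert idx == set(range(10)) and len(TRIPLET_COMBOS) == 10

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            fitness_combo_index(("L", "X"))


class TestSingleEncoder:
    def test_isolated_unannotated_gene_is_zero_vector(self, toy_net, toy_table):
        toy_table.add(GeneAnnotation("z", np.zeros(5), 0.0, "N"))
        enc = SingleEncoder(toy_table, toy_net)
        assert np.array_equal(enc.encode("z"), np.zeros(7))

    def test_layout_composition(self, toy_net, toy_table):
        enc = SingleEncoder(toy_table, toy_net)
        v = enc.encode("e")  # triangle vertex, pident 0, no terms
        assert v[0] == 1.0 and v[1] == 0.0 and not v[2:].any()
        assert len(v) == 2 + 5

    def test_encode_many_matches_encode(self, toy_net, toy_table):
        enc = SingleEncoder(toy_table, toy_net)
        genes = ["a", "b", "f", "z"]
        X = enc.encode_many(genes)
        for i, g in enumerate(genes):
            assert np.array_equal(X[i], enc.encode(g))


class TestPairEncoder:
    def test_symmetry_bitwise(self, toy_net, toy_table):
        enc = PairEncoder(toy_table, toy_net)
        for a, b in itertools.combinations("abcdef", 2):
            assert np.array_equal(enc.encode(a, b), enc.encode(b, a))

    def test_structure(self, toy_net, toy_table):
        enc = PairEncoder(toy_table, toy_net)
        v = enc.encode("a", "b")
        combo = v[1:7]
        assert combo.sum() == 1.0  # one-hot
        assert combo[PAIR_COMBOS.index("LR")] == 1.0
        assert v[7] == 1.0 and v[8] == 0.0  # adjacent, reachable
        shared = v[9:]
        assert set(shared.tolist()) <= {0.0, 1.0, 2.0}
        assert shared[0] == 2.0  # both a and b carry term T0

    def test_unreachable_pair_flagged(self, toy_net, toy_table):
        v = PairEncoder(toy_table, toy_net).encode("a", "z")
        assert v[7] == 0.0 and v[8] == 1.0

    def test_identical_genes_rejected(self, toy_net, toy_table):
        with pytest.raises(ValueError):
            PairEncoder(toy_table, toy_net).encode("a", "a")

    def test_encode_many_matches_encode(self, toy_net, toy_table):
        enc = PairEncoder(toy_table, toy_net)
        pairs = list(itertools.combinations("abcdefz", 2))
        X = enc.encode_many(pairs)
        for i, (a, b) in enumerate(pairs):
            assert np.array_equal(X[i], enc.encode(a, b))

    def test_missing_fitness_is_schema_error(self, toy_net, toy_table):
        from gipredict.features import GeneAnnotation
        toy_table.add(GeneAnnotation("q", np.zeros(5), 0.0, None))
        with pytest.raises(SchemaError):
            PairEncoder(toy_table, toy_net).encode("a", "q")

    def test_gene_blocks_are_slot_symmetric(self, toy_net, toy_table):
        enc = PairEncoder(toy_table, toy_net)
        G, P = enc.encode_gene_blocks([("a", "b"), ("b", "a")])
        assert np.array_equal(G[0, 0], G[1, 1])
        assert np.array_equal(G[0, 1], G[1, 0])
        assert np.array_equal(P[0], P[1])
        assert G.shape == (2, 2, 4 + 5) and P.shape == (2, 2)


class TestTripletEncoder:
    def test_all_six_orders_identical(self, toy_net, toy_table):
        enc = TripletEncoder(toy_table, toy_net)
        base = enc.encode("b", "c", "d")
        for p in itertools.permutations(("b", "c", "d")):
            assert np.array_equal(enc.encode(*p), base)

    def test_structure(self, toy_net, toy_table):
        enc = TripletEncoder(toy_table, toy_net)
        v = enc.encode("d", "e", "f")  # triangle: SCL 3
        assert v[1:11].sum() == 1.0
        assert v[11] == 3.0 and v[12] == 0.0
        assert set(v[13:].tolist()) <= {0.0, 1.0, 2.0, 3.0}

    def test_sharing_count_reaches_three(self, toy_net, toy_table):
        v = TripletEncoder(toy_table, toy_net).encode("a", "b", "f")
        assert v[13] == 3.0  # T0 carried by a, b and f

    def test_duplicates_rejected(self, toy_net, toy_table):
        with pytest.raises(ValueError):
            TripletEncoder(toy_table, toy_net).encode("a", "a", "b")

    def test_encode_many_matches_encode(self, toy_net, toy_table):
        enc = TripletEncoder(toy_table, toy_net)
        trips = list(itertools.combinations("abcdef", 3))
        X = enc.encode_many(trips)
        for i, t in enumerate(trips):
            assert np.array_equal(X[i], enc.encode(*t))


class TestHybridDataset:
    def test_publication_filter(self):
        gi = [GIRecord(("g1", f"h{i}"), "negative", n_publications=i)
              for i in (1, 2, 3, 4)]
        kept = build_hybrid_gi_dataset([], gi, min_pubs=3)
        assert len(kept) == 2

    def test_min_pubs_zero_keeps_all(self):
        gi = [GIRecord(("g1", f"h{i}"), "positive", n_publications=i)
              for i in (0, 1)]
        assert len(build_hybrid_gi_dataset([], gi, min_pubs=0)) == 2

    def test_conflict_resolves_to_non_neutral(self):
        neutral = [GIRecord(("a", "b"), "neutral")]
        gi = [GIRecord(("b", "a"), "negative", n_publications=3)]
        merged = build_hybrid_gi_dataset(neutral, gi)
        assert len(merged) == 1 and merged[0].label == "negative"

    def test_size_identity_on_toy_data(self):
        neutral = [GIRecord((f"n{i}", f"m{i}"), "neutral") for i in range(5)]
        gi = ([GIRecord(("n0", "m0"), "negative", n_publications=5)]
              + [GIRecord((f"x{i}", f"y{i}"), "suppression",
                          n_publications=4) for i in range(3)])
        merged = build_hybrid_gi_dataset(neutral, gi)
        assert len(merged) == 5 + 4 - 1


class TestNegativeSampling:
    def test_exclusion_and_reproducibility(self):
        genes = [f"g{i}" for i in range(30)]
        gi = {("g0", "g1"), ("g2", "g3")}
        s1 = negative_sample_neutral_pairs(genes, gi, 50, seed=3)
        s2 = negative_sample_neutral_pairs(genes, gi, 50, seed=3)
        s3 = negative_sample_neutral_pairs(genes, gi, 50, seed=4)
        assert s1 == s2 and s1 != s3
        assert len(set(s1)) == 50
        assert not set(s1) & {canonical_pair(*p) for p in gi}

    def test_small_universe_exact(self):
        genes = list("wxyz")
        got = negative_sample_neutral_pairs(genes, {("w", "x")}, 5, seed=0)
        assert len(got) == 5
        assert ("w", "x") not in got

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            negative_sample_neutral_pairs(list("wxyz"), {("w", "x")}, 6,
                                          seed=0)


class TestLabelRegrouping:
    def test_lethal_vs_viable_conserves_counts(self):
        labels = ["L"] * 5 + ["R"] * 3 + ["N"] * 12
        out = regroup_labels(labels, "lethal_vs_viable")
        assert out.count("lethal") == 5 and out.count("viable") == 15

    def test_gi_grouping(self):
        labels = (["negative"] * 2 + ["neutral"] * 10 + ["positive"]
                  + ["suppression"])
        out = regroup_labels(labels, "interacting_vs_neutral")
        assert out.count("GI") == 4 and out.count("neutral") == 10

    def test_ca_mo_viable_partition(self):
        genes = [f"g{i}" for i in range(10)]
        ca = {"g0", "g1"}
        mo = derive_mo_lethal({"g0", "g1", "g2", "g3"}, ca)
        assert mo == {"g2", "g3"} and not mo & ca
        out = regroup_labels(None, "ca_mo_viable", genes=genes,
                             ca_lethal=ca, mo_lethal=mo)
        assert out.count("CA") == 2 and out.count("MO") == 2
        assert out.count("viable") == 6

    def test_unknown_label_rejected(self):
        with pytest.raises(SchemaError):
            regroup_labels(["L", "weird"], "lethal_vs_viable")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(SchemaError):
            regroup_labels(["L"], "no_such_scheme")
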