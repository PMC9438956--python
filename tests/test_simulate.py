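"""Synthetic-data generators: reproducibility and statistical structure."""

import collections

import numpy as np
import pytest
from scipy import stats

from gipredict import simulate as sim
from gipredict.complexes import gi_enrichment_test, within_across_distribution
from gipredict.mn import MNModel


class TestNetwork:
    def test_edge_count_and_no_self_loops(self):
        net = sim.generate_network(100, 2, seed=1)
        assert len(net) == 100
        assert net.n_edges == (100 - 2) * 2
        assert all(a != b for a, b in net.graph.edges)

    def test_reproducible(self):
        e1 = set(sim.generate_network(80, 3, seed=5).graph.edges)
        e2 = set(sim.generate_network(80, 3, seed=5).graph.edges)
        e3 = set(sim.generate_network(80, 3, seed=6).graph.edges)
        assert e1 == e2 and e1 != e3

    def test_erdos_renyi_variant(self):
        net = sim.generate_network(100, 3, seed=2, model="erdos_renyi")
        assert len(net) == 100

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_network(3, 3, seed=0)


class TestAnnotations:
    def test_term_frequency_binomial(self):
        table = sim.generate_annotations(sim.gene_ids(5000), n_terms=20,
                                         term_prob=0.3, seed=3)
        bits = np.array([table[g].sgo for g in table.genes])
        freq = bits.mean()
        se = np.sqrt(0.3 * 0.7 / bits.size)
        assert abs(freq - 0.3) < 3 * se

    def test_zero_term_prob_all_zero(self):
        table = sim.generate_annotations(sim.gene_ids(50), n_terms=10,
                                         term_prob=0.0, seed=4)
        assert not any(table[g].sgo.any() for g in table.genes)

    def test_pident_range_and_zero_mass(self):
        table = sim.generate_annotations(sim.gene_ids(2000),
                                         pident_zero_prob=0.4, seed=5)
        pid = np.array([table[g].pident for g in table.genes])
        assert ((0 <= pid) & (pid <= 100)).all()
        zero_frac = (pid == 0).mean()
        assert abs(zero_frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 2000)


class TestSingleLabels:
    def test_zero_coefficients_give_uniform_classes(self, small_study):
        table, net = small_study["table"], small_study["net"]
        layout_names = small_study["truth"].s_mn.feature_names
        null = MNModel(("L", "R", "N"), "N",
                       np.zeros((2, 1 + len(layout_names))), layout_names)
        genes = [table.genes[i] for i in
                 np.random.default_rng(0).integers(0, len(table), 9000)]
        ds = sim.generate_single_labels(table, net, null, seed=6,
                                        genes=genes, assign_fitness=False)
        freq = collections.Counter(ds.y.tolist())
        se = np.sqrt((1 / 3) * (2 / 3) / 9000)
        for c in "LRN":
            assert abs(freq[c] / 9000 - 1 / 3) < 3 * se

    def test_saturating_intercept(self, small_study):
        table, net = small_study["table"], small_study["net"]
        names = small_study["truth"].s_mn.feature_names
        coef = np.zeros((2, 1 + len(names)))
        coef[0, 0] = 25.0  # lethal log-odds dominates everything
        truth = MNModel(("L", "R", "N"), "N", coef, names)
        ds = sim.generate_single_labels(table, net, truth, seed=7,
                                        assign_fitness=False)
        assert (ds.y == "L").mean() > 0.999

    def test_reproducible_and_fitness_assignment(self, small_study):
        study = small_study
        ds1 = sim.generate_single_labels(study["table"], study["net"],
                                         study["truth"].s_mn, seed=8,
                                         assign_fitness=False)
        ds2 = sim.generate_single_labels(study["table"], study["net"],
                                         study["truth"].s_mn, seed=8,
                                         assign_fitness=False)
        assert np.array_equal(ds1.y, ds2.y)
        assert all(study["table"][g].fitness is not None
                   for g in study["table"].genes)


class TestPairSampling:
    def test_distinct_canonical_pairs(self):
        genes = sim.gene_ids(40)
        pairs = sim.sample_gene_pairs(genes, 300, seed=9)
        assert len(pairs) == 300 and len(set(pairs)) == 300
        assert all(a < b for a, b in pairs)

    def test_capacity_guard(self):
        with pytest.raises(ValueError):
            sim.sample_gene_pairs(sim.gene_ids(5), 11, seed=0)

    def test_triplets(self):
        trips = sim.sample_gene_triplets(sim.gene_ids(30), 100, seed=10)
        assert len(set(trips)) == 100
        assert all(a < b < c for a, b, c in trips)


class TestGILabels:
    def test_reproducible(self, small_study):
        study = small_study
        pairs = sim.sample_gene_pairs(study["table"].genes, 500, seed=11)
        ds1 = sim.generate_gi_labels(pairs, study["table"], study["net"],
                                     study["truth"].d_mn, seed=12)
        ds2 = sim.generate_gi_labels(pairs, study["table"], study["net"],
                                     study["truth"].d_mn, seed=12)
        assert np.array_equal(ds1.y, ds2.y)

    def test_null_truth_labels_independent_of_features(self, small_study):
        """Zero non-intercept coefficients: labels carry no feature
        signal (chi-squared association with a informative feature)."""
        study = small_study
        names = study["truth"].d_mn.feature_names
        coef = np.zeros((3, 1 + len(names)))
        null = MNModel(("negative", "neutral", "positive", "suppression"),
                       "neutral", coef, names)
        pairs = sim.sample_gene_pairs(study["table"].genes, 3000, seed=13)
        ds = sim.generate_gi_labels(pairs, study["table"], study["net"],
                                    null, seed=14)
        # association between label and the high/low lid_sum split
        lid_hi = ds.X[:, 0] > np.median(ds.X[:, 0])
        table = [[(lid_hi & (ds.y == c)).sum() for c in null.classes],
                 [(~lid_hi & (ds.y == c)).sum() for c in null.classes]]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_imbalance_calibration_small_scale(self, small_study):
        study = small_study
        pairs = sim.sample_gene_pairs(study["table"].genes, 10000, seed=15)
        ds = sim.generate_gi_labels(pairs, study["table"], study["net"],
                                    study["truth"].d_mn, seed=16,
                                    imbalance_target=0.05)
        realized = (ds.y != "neutral").mean()
        assert realized == pytest.approx(0.05, rel=0.2)

    def test_calibration_failure_reported(self, small_study):
        study = small_study
        names = study["truth"].d_mn.feature_names
        # a coefficient so extreme that no common intercept shift can
        # push the marginal below the target accuracy window
        coef = np.zeros((3, 1 + len(names)))
        coef[:, 0] = 50.0
        degenerate = MNModel(study["truth"].d_mn.classes, "neutral", coef,
                             names)
        pairs = sim.sample_gene_pairs(study["table"].genes, 100, seed=17)
        with pytest.raises(sim.CalibrationError):
            sim.calibrate_intercepts(degenerate,
                                     np.zeros((100, len(names))), 1e-9)


class TestComplexes:
    def test_unit_sizes(self):
        membership, _ = sim.generate_complexes(sim.gene_ids(100), 15, seed=18)
        assert len(membership) == 15
        assert all(len(m) >= 2 for m in membership.units.values())

    def test_within_effect_recoverable(self, small_study):
        study = small_study
        membership, _ = sim.generate_complexes(study["table"].genes, 12,
                                               seed=19, size_range=(6, 12))
        pairs = sim.sample_gene_pairs(study["table"].genes, 8000, seed=20)
        ds = sim.generate_gi_labels(pairs, study["table"], study["net"],
                                    study["truth"].d_mn, seed=21,
                                    imbalance_target=0.10,
                                    membership=membership, within_effect=2.0)
        res = within_across_distribution(pairs, ds.y, membership,
                                         classes=ds.classes)
        gi = ("negative", "positive", "suppression")
        assert res.fraction("within", gi) > res.fraction("across", gi)


def test_bundle_writes_complete_fixture(tmp_path):
    truth = sim.default_ground_truth(n_genes=60, attachment_m=2,
                                     gi_imbalance=0.2)
    sim.simulate_bundle(tmp_path, seed=22, truth=truth, n_pairs=300,
                        n_triplets=100, n_units=5)
    expected = ["ppi_edges.tsv", "annotations.tsv", "single_fitness.tsv",
                "pair_gi.tsv", "triplet_gi.tsv", "complex_membership.tsv",
                "ground_truth.json"]
    for name in expected:
        assert (tmp_path / name).exists()
    back = sim.GroundTruth.from_json(tmp_path / "ground_truth.json")
    assert back.n_genes == 60
    assert np.array_equal(back.d_mn.coefficients, truth.d_mn.coefficients)
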