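"""Synthetic study generator.

Produces fully synthetic inputs with the statistical structure the
viability models assume, so the whole pipeline — feature encoding,
model fitting, evaluation, feature selection, complex-context analysis
— is exercisable end to end without any external download:

* a connected scale-free PPI network (preferential attachment; real PPI
  degree distributions are heavy-tailed), optionally Erdős–Rényi for
  null checks;
* per-gene annotations: independent Bernoulli slim-GO memberships over
  a 45-term vocabulary, and percent identity drawn from a mixture of a
  point mass at zero (genes without an in-genome homolog) and a uniform
  component;
* single-mutant fitness labels sampled from a ground-truth single-gene
  multinomial model, then pair/triplet genetic-interaction labels
  sampled from ground-truth pair/triplet models, with intercepts
  calibrated by bisection so the marginal non-neutral fraction matches
  a target imbalance (default 0.8%, the empirical rarity of negative
  interactions among double knockouts);
* complex membership with an optional within-unit log-odds bonus on the
  non-neutral classes, so within/across enrichment is recoverable.

All generators are bit-reproducible under fixed seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .complexes import MembershipTable, shares_unit
from .features import (AnnotationTable, GeneAnnotation, PairEncoder,
                       SingleEncoder, TripletEncoder,
                       pair_layout, single_layout, triplet_layout)
from .graph import PPINetwork
from .mn import MNModel

logger = logging.getLogger(__name__)

SINGLE_CLASSES = ("L", "R", "N")
PAIR_CLASSES = ("negative", "neutral", "positive", "suppression")
TRIPLET_CLASSES = ("negative", "neutral")


class CalibrationError(RuntimeError):
    """Intercept bisection failed to reach the imbalance target."""


@dataclass
class GroundTruth:
    """Generating models and distributional parameters of a synthetic study.

    ``within_effect`` is a log-odds bonus added to every non-reference
    class score of pair/triplet tuples whose genes share a complex.
    """

    s_mn: MNModel
    d_mn: MNModel
    t_mn: MNModel
    n_genes: int = 1000
    attachment_m: int = 3
    n_sgo_terms: int = 45
    term_prob: float = 0.3
    pident_zero_prob: float = 0.4
    gi_imbalance: float = 0.008
    within_effect: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "n_genes": self.n_genes, "attachment_m": self.attachment_m,
            "n_sgo_terms": self.n_sgo_terms, "term_prob": self.term_prob,
            "pident_zero_prob": self.pident_zero_prob,
            "gi_imbalance": self.gi_imbalance,
            "within_effect": self.within_effect,
        }
        for name in ("s_mn", "d_mn", "t_mn"):
            m: MNModel = getattr(self, name)
            payload[name] = {"classes": list(m.classes),
                             "reference_class": m.reference_class,
                             "feature_names": list(m.feature_names),
                             "coefficients": m.coefficients.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        models = {}
        for name in ("s_mn", "d_mn", "t_mn"):
            md = d.pop(name)
            models[name] = MNModel(tuple(md["classes"]),
                                   md["reference_class"],
                                   np.array(md["coefficients"]),
                                   tuple(md["feature_names"]))
        return cls(**models, **d)


def default_vocabulary(n_terms: int = 45) -> list[str]:
    return [f"sGO{i:02d}" for i in range(n_terms)]


def _sparse_coeffs(layout, entries: dict[str, float]) -> np.ndarray:
    """Row [intercept, features...] from a name → value mapping."""
    row = np.zeros(1 + len(layout.names))
    names = {"intercept": 0, **{n: j + 1 for j, n in enumerate(layout.names)}}
    for name, value in entries.items():
        row[names[name]] = value
    return row


def default_ground_truth(n_terms: int = 45, **overrides) -> GroundTruth:
    """The canonical synthetic study conditions.

    Coefficient magnitudes are moderate (|coef| ≤ 2 on the encoder
    scale) with a handful of informative slim-GO terms per class; the
    fitness-combination coefficients are in the gauge where the
    all-normal combination (NN / NNN) is zero, and unreachable-flag
    coefficients are zero (the column is identically zero on a
    connected network).  Percent-identity coefficients are per
    percentage point, hence small.
    """
    if n_terms < 10:
        raise ValueError("the canonical ground truth places informative "
                         "coefficients on the first 10 sGO terms")
    vocab = default_vocabulary(n_terms)
    s_lay, p_lay, t_lay = (single_layout(vocab), pair_layout(vocab),
                           triplet_layout(vocab))
    term = lambda i: f"sgo:{vocab[i]}"

    s_coef = np.vstack([
        _sparse_coeffs(s_lay, {
            "intercept": -1.1, "lid": 2.0, "pident": -0.015,
            term(0): 1.2, term(1): 0.9, term(2): 0.7, term(3): 0.5,
            term(4): -0.6, term(5): -0.8, term(6): 0.4, term(7): -0.4}),
        _sparse_coeffs(s_lay, {
            "intercept": -0.7, "lid": 1.0, "pident": -0.008,
            term(0): 0.5, term(1): 0.3, term(4): -0.3, term(6): 0.6,
            term(8): -0.5, term(9): 0.4}),
    ])
    s_mn = MNModel(SINGLE_CLASSES, "N", s_coef, s_lay.names)

    d_coef = np.vstack([
        _sparse_coeffs(p_lay, {
            "intercept": -1.0, "lid_sum": 1.5, "spl": -0.25,
            "combo:LL": 0.6, "combo:LR": 0.8, "combo:LN": 0.3,
            "combo:RR": 1.0, "combo:RN": 0.5,
            term(0): 0.5, term(1): 0.4, term(2): -0.3, term(3): 0.3,
            term(5): 0.25, term(7): -0.25}),
        _sparse_coeffs(p_lay, {
            "intercept": -1.3, "lid_sum": 0.8, "spl": -0.15,
            "combo:LR": 0.5, "combo:RR": 0.9, "combo:RN": 0.4,
            term(0): 0.3, term(4): 0.35, term(6): -0.3}),
        _sparse_coeffs(p_lay, {
            "intercept": -1.6, "lid_sum": 0.5, "spl": -0.3,
            "combo:RR": 0.6, "combo:RN": 0.35, "combo:LR": 0.3,
            term(1): 0.3, term(8): 0.4}),
    ])
    # row order = non-reference classes in PAIR_CLASSES order
    d_mn = MNModel(PAIR_CLASSES, "neutral", d_coef, p_lay.names)

    t_coef = _sparse_coeffs(t_lay, {
        "intercept": -1.0, "lid_sum": 1.2, "scl": -0.12,
        "combo:LLL": 0.8, "combo:LLR": 0.7, "combo:LLN": 0.4,
        "combo:LRR": 0.6, "combo:LRN": 0.3, "combo:RRN": 0.5,
        "combo:RNN": 0.2, "combo:RRR": 0.9, "combo:NNL": 0.2,
        term(0): 0.4, term(2): 0.3, term(5): -0.3, term(9): 0.35,
    })[None, :]
    t_mn = MNModel(TRIPLET_CLASSES, "neutral", t_coef, t_lay.names)

    return GroundTruth(s_mn, d_mn, t_mn, n_sgo_terms=n_terms, **overrides)


def recovery_ground_truth(n_terms: int = 45, **overrides) -> GroundTruth:
    """Ground truth for parameter-recovery studies.

    Identical slopes to :func:`default_ground_truth` but with intercepts
    set so the output classes are roughly balanced (each ≈ 1/K) under
    the default network/annotation distributions with uniform
    single-mutant fitness.  Balanced classes maximise the Fisher
    information per example, which is what a recovery experiment is
    designed to measure; the rare-GI imbalance regime is exercised
    separately by the calibration study.
    """
    truth = default_ground_truth(n_terms, **overrides)
    truth.s_mn.coefficients[:, 0] = [-0.8, -0.3]
    truth.d_mn.coefficients[:, 0] = [-1.3, -0.55, 0.05]
    return truth


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def generate_network(n_genes: int, attachment_m: int, seed: int,
                     model: str = "preferential",
                     triad_prob: float = 0.6) -> PPINetwork:
    """Connected scale-free-style network over synthetic gene IDs.

    ``model="preferential"`` (default) is preferential attachment with
    triad closure (Holme–Kim), giving both the heavy-tailed degree
    distribution and the high clustering of real PPI networks — without
    clustering the neighbourhood-density (LID) feature would be nearly
    degenerate at zero.  (n_genes - attachment_m) * attachment_m edges.
    ``triad_prob=0`` reduces to plain Barabási–Albert;
    ``"erdos_renyi"`` draws a G(n, p) graph with matched expected
    degree for null comparisons.
    """
    if not n_genes > attachment_m >= 1:
        raise ValueError("need n_genes > attachment_m >= 1")
    if model == "preferential":
        g = nx.powerlaw_cluster_graph(n_genes, attachment_m, triad_prob,
                                      seed=seed)
    elif model == "erdos_renyi":
        p = 2.0 * attachment_m / (n_genes - 1)
        g = nx.gnp_random_graph(n_genes, p, seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    mapping = dict(zip(sorted(g.nodes), gene_ids(n_genes)))
    return PPINetwork(nx.relabel_nodes(g, mapping))


def generate_annotations(genes, n_terms: int = 45, term_prob: float = 0.3,
                         pident_zero_prob: float = 0.4,
                         seed: int = 0) -> AnnotationTable:
    """Independent Bernoulli sGO bits and mixture-distributed pident.

    pident is 0 with probability ``pident_zero_prob`` (no in-genome
    homolog) and Uniform(10, 100) otherwise.
    """
    if not (0.0 <= term_prob <= 1.0 and 0.0 <= pident_zero_prob <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab = default_vocabulary(n_terms)
    table = AnnotationTable(vocab)
    genes = list(genes)
    bits = (rng.random((len(genes), n_terms)) < term_prob).astype(float)
    has_hom = rng.random(len(genes)) >= pident_zero_prob
    pident = np.where(has_hom, rng.uniform(10.0, 100.0, len(genes)), 0.0)
    for i, g in enumerate(genes):
        table.add(GeneAnnotation(g, bits[i], float(pident[i])))
    return table


def _sample_labels(rng, probs: np.ndarray, classes) -> np.ndarray:
    u = rng.random(probs.shape[0])
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(classes)[idx]


@dataclass
class LabeledDataset:
    """Gene tuples, encoded features and sampled labels."""

    tuples: list
    X: np.ndarray
    y: np.ndarray
    layout: object
    classes: tuple[str, ...]


def generate_single_labels(table: AnnotationTable, net: PPINetwork,
                           truth: MNModel, seed: int,
                           genes=None, assign_fitness: bool = True
                           ) -> LabeledDataset:
    """Sample a fitness class per gene from the ground-truth single-gene
    model's softmax probabilities on its encoded features.

    With ``assign_fitness`` the sampled class is written back into the
    annotation table (each gene's first draw), so that pair/triplet
    encoders can use single-mutant fitness as an input feature.
    """
    enc = SingleEncoder(table, net)
    if tuple(truth.feature_names) != tuple(enc.layout.names):
        raise ValueError("ground-truth layout does not match the encoder")
    genes = list(genes) if genes is not None else sorted(table.genes)
    X = enc.encode_many(genes)
    probs = truth.predict_proba(X)
    rng = np.random.default_rng(seed)
    y = _sample_labels(rng, probs, truth.classes)
    if assign_fitness:
        for g, lab in zip(genes, y):
            if table[g].fitness is None:
                table.set_fitness(g, str(lab))
    return LabeledDataset(genes, X, y, enc.layout, truth.classes)


def sample_gene_pairs(genes, n: int, seed: int) -> list[tuple[str, str]]:
    """n distinct unordered gene pairs, uniformly without replacement."""
    genes = sorted(genes)
    n_genes = len(genes)
    universe = n_genes * (n_genes - 1) // 2
    if n > universe:
        raise ValueError(f"requested {n} pairs from a universe of {universe}")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n:
        k = int(1.5 * (n - len(chosen))) + 8
        ia = rng.integers(0, n_genes, size=k)
        ib = rng.integers(0, n_genes, size=k)
        for a, b in zip(ia, ib):
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            chosen.add(key)
            if len(chosen) == n:
                break
    return [(genes[a], genes[b]) for a, b in sorted(chosen)]


def sample_gene_triplets(genes, n: int, seed: int) -> list[tuple[str, str, str]]:
    genes = sorted(genes)
    n_genes = len(genes)
    universe = n_genes * (n_genes - 1) * (n_genes - 2) // 6
    if n > universe:
        raise ValueError(f"requested {n} triplets from a universe of "
                         f"{universe}")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int, int]] = set()
    while len(chosen) < n:
        k = int(1.5 * (n - len(chosen))) + 8
        picks = rng.integers(0, n_genes, size=(k, 3))
        for row in picks:
            if len(set(row.tolist())) != 3:
                continue
            chosen.add(tuple(sorted(row.tolist())))
            if len(chosen) == n:
                break
    return [tuple(genes[i] for i in t) for t in sorted(chosen)]


def _within_bonus(tuples, membership: MembershipTable | None,
                  within_effect: float, rule: str = "all") -> np.ndarray:
    if membership is None or within_effect == 0.0:
        return np.zeros(len(tuples))
    mask = np.array([shares_unit(t, membership, rule=rule) for t in tuples])
    return within_effect * mask.astype(float)


def calibrate_intercepts(truth: MNModel, X: np.ndarray,
                         target: float, bonus: np.ndarray | None = None,
                         rel_tol: float = 0.02, max_iter: int = 60) -> MNModel:
    """Shift all non-reference intercepts by a common offset (bisection)
    so the mean non-reference probability over ``X`` equals ``target``.

    The marginal non-reference fraction is monotone increasing in the
    offset, so bisection on [-30, 30] converges; failure to bracket or
    to reach ``rel_tol`` relative accuracy raises CalibrationError.
    """
    bonus = np.zeros(X.shape[0]) if bonus is None else bonus
    ref_idx = truth.classes.index(truth.reference_class)

    def marginal(delta: float) -> float:
        m = truth.coefficients.copy()
        m[:, 0] += delta
        shifted = MNModel(truth.classes, truth.reference_class, m,
                          truth.feature_names)
        s = shifted.scores(X)
        s[:, [i for i in range(len(truth.classes)) if i != ref_idx]] += \
            bonus[:, None]
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        p = e / e.sum(axis=1, keepdims=True)
        return float(1.0 - p[:, ref_idx].mean())

    lo, hi = -30.0, 30.0
    if not (marginal(lo) < target < marginal(hi)):
        raise CalibrationError(
            f"target {target} not bracketed: marginal({lo})="
            f"{marginal(lo):.3g}, marginal({hi})={marginal(hi):.3g}")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if marginal(mid) < target:
            lo = mid
        else:
            hi = mid
    delta = (lo + hi) / 2.0
    achieved = marginal(delta)
    if abs(achieved - target) > rel_tol * target:
        raise CalibrationError(
            f"bisection stalled: achieved {achieved:.4g} vs target {target}")
    coef = truth.coefficients.copy()
    coef[:, 0] += delta
    return MNModel(truth.classes, truth.reference_class, coef,
                   truth.feature_names,
                   {"calibration_offset": delta,
                    "calibration_target": target})


def generate_gi_labels(tuples, table: AnnotationTable, net: PPINetwork,
                       truth: MNModel, seed: int,
                       imbalance_target: float | None = None,
                       membership: MembershipTable | None = None,
                       within_effect: float = 0.0,
                       rule: str = "all") -> LabeledDataset:
    """Sample GI labels for pairs or triplets from a ground-truth model.

    With ``imbalance_target`` the intercepts are first calibrated by
    bisection so the expected non-reference (non-neutral) fraction over
    these tuples hits the target; ``within_effect`` adds a log-odds
    bonus to non-neutral scores of tuples sharing a membership unit.
    """
    arity = len(tuples[0])
    enc_cls = PairEncoder if arity == 2 else TripletEncoder
    enc = enc_cls(table, net)
    if tuple(truth.feature_names) != tuple(enc.layout.names):
        raise ValueError("ground-truth layout does not match the encoder")
    X = enc.encode_many(tuples)
    bonus = _within_bonus(tuples, membership, within_effect, rule=rule)
    model = truth
    if imbalance_target is not None:
        model = calibrate_intercepts(truth, X, imbalance_target, bonus=bonus)
    s = model.scores(X)
    ref_idx = model.classes.index(model.reference_class)
    nonref = [i for i in range(len(model.classes)) if i != ref_idx]
    s[:, nonref] += bonus[:, None]
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    probs = e / e.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    y = _sample_labels(rng, probs, model.classes)
    return LabeledDataset(list(tuples), X, y, enc.layout, model.classes)


def generate_complexes(genes, n_units: int, seed: int,
                       size_range: tuple[int, int] = (3, 8),
                       within_effect: float = 0.0,
                       truth: GroundTruth | None = None):
    """Random complex membership units (possibly overlapping).

    Returns ``(membership, adjusted_truth)`` where the adjusted truth
    carries ``within_effect`` so label generation applies the
    within-unit bonus.  Unit sizes are uniform over ``size_range``
    (every unit has at least two members).
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("unit sizes must be at least 2")
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    units: dict[str, set] = {}
    for u in range(n_units):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        units[f"cplx{u:03d}"] = {genes[i] for i in members}
    membership = MembershipTable(units)
    adjusted = None
    if truth is not None:
        adjusted = replace(truth, within_effect=within_effect)
    return membership, adjusted


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

def simulate_bundle(outdir, seed: int, truth: GroundTruth | None = None,
                    n_pairs: int = 5000, n_triplets: int = 2000,
                    n_units: int = 40) -> GroundTruth:
    """Emit a complete synthetic study into ``outdir``.

    Writes the PPI edge list, annotation table, single/pair/triplet
    label tables, complex membership and the ground truth JSON.  Seeds
    for the constituent generators are derived from ``seed``.
    """
    import os
    import pandas as pd

    truth = truth or default_ground_truth()
    os.makedirs(outdir, exist_ok=True)
    net = generate_network(truth.n_genes, truth.attachment_m, seed)
    table = generate_annotations(gene_ids(truth.n_genes), truth.n_sgo_terms,
                                 truth.term_prob, truth.pident_zero_prob,
                                 seed + 1)
    singles = generate_single_labels(table, net, truth.s_mn, seed + 2)
    membership, adj = generate_complexes(
        table.genes, n_units, seed + 3,
        within_effect=truth.within_effect, truth=truth)
    pairs = sample_gene_pairs(table.genes, n_pairs, seed + 4)
    pair_ds = generate_gi_labels(
        pairs, table, net, truth.d_mn, seed + 5,
        imbalance_target=truth.gi_imbalance, membership=membership,
        within_effect=truth.within_effect)
    triplets = sample_gene_triplets(table.genes, n_triplets, seed + 6)
    trip_ds = generate_gi_labels(
        triplets, table, net, truth.t_mn, seed + 7,
        imbalance_target=truth.gi_imbalance, membership=membership,
        within_effect=truth.within_effect)

    edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
    with open(os.path.join(outdir, "ppi_edges.tsv"), "w") as fh:
        fh.write("# synthetic PPI edge list\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
    table.to_tsv(os.path.join(outdir, "annotations.tsv"))
    pd.DataFrame({"gene": singles.tuples, "fitness": singles.y}) \
        .to_csv(os.path.join(outdir, "single_fitness.tsv"),
                sep="\t", index=False)
    pd.DataFrame([(a, b, lab) for (a, b), lab
                  in zip(pair_ds.tuples, pair_ds.y)],
                 columns=["gene_a", "gene_b", "label"]) \
        .to_csv(os.path.join(outdir, "pair_gi.tsv"), sep="\t", index=False)
    pd.DataFrame([(a, b, c, lab) for (a, b, c), lab
                  in zip(trip_ds.tuples, trip_ds.y)],
                 columns=["gene_a", "gene_b", "gene_c", "label"]) \
        .to_csv(os.path.join(outdir, "triplet_gi.tsv"), sep="\t", index=False)
    membership.to_tsv(os.path.join(outdir, "complex_membership.tsv"))
    truth.to_json(os.path.join(outdir, "ground_truth.json"))
    return truth
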