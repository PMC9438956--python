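"""Model-ready feature vectors for single genes, gene pairs and triplets.

Feature layouts mirror the right-hand sides of the three multinomial
viability models:

* single gene:  ``[LID, Pident, sGO_1 .. sGO_m]``
* gene pair:    ``[LID_A+LID_B, 6-way fitness-combo one-hot, SPL,
  SPL-unreachable flag, (sGO_iA+sGO_iB) per term]``
* gene triplet: ``[ΣLID, 10-way fitness-combo one-hot, SCL, flag,
  (sGO_iA+sGO_iB+sGO_iC) per term]``

Pair and triplet encodings are exactly permutation-invariant: every
constituent is a symmetric function of the genes, so ``(A, B)`` and
``(B, A)`` produce bitwise-identical vectors.

Also houses dataset construction: hybrid GI sets (systematic neutral
screen merged with literature GIs above a publication threshold),
negative sampling of neutral pairs, cell-autonomous vs multicellular-
organismal lethal partitions, and binary label regroupings.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graph import UNREACHABLE, DistanceIndex, PPINetwork, lid, \
    shortest_circuit_length, shortest_path_length

logger = logging.getLogger(__name__)

#: Single-mutant fitness classes: lethal, reduced growth, normal.
FITNESS_CLASSES = ("L", "R", "N")

#: Unordered pair fitness combinations, canonical order.
PAIR_COMBOS = ("LL", "LR", "LN", "RR", "RN", "NN")

#: Unordered triplet fitness combinations, canonical order.
TRIPLET_COMBOS = ("LLL", "LLR", "LLN", "LRR", "LRN",
                  "RRN", "RNN", "RRR", "NNN", "NNL")

_COMBO_BY_COUNTS = {
    2: {tuple(Counter(c)[f] for f in FITNESS_CLASSES): i
        for i, c in enumerate(PAIR_COMBOS)},
    3: {tuple(Counter(c)[f] for f in FITNESS_CLASSES): i
        for i, c in enumerate(TRIPLET_COMBOS)},
}


class SchemaError(ValueError):
    """Layout / vocabulary / label-scheme mismatch."""


def fitness_combo_index(classes, arity: int | None = None) -> int:
    """Index of an unordered fitness combination in the canonical list.

    ``classes`` is a multiset drawn from {L, R, N} of size 2 or 3;
    the index is order-insensitive ((L,N) and (N,L) both map to LN).
    """
    classes = tuple(classes)
    if arity is None:
        arity = len(classes)
    if len(classes) != arity or arity not in (2, 3):
        raise ValueError(f"expected a multiset of size 2 or 3, got {classes!r}")
    for c in classes:
        if c not in FITNESS_CLASSES:
            raise ValueError(f"unknown fitness class {c!r}")
    counts = tuple(Counter(classes)[f] for f in FITNESS_CLASSES)
    return _COMBO_BY_COUNTS[arity][counts]


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene annotation: sGO membership bits, percent identity, fitness.

    ``pident`` is the percent amino-acid identity of the closest
    within-genome homolog (0 when no homolog was found) and ``fitness``
    the single-mutant fitness class (may be ``None`` before labels are
    assigned, e.g. for freshly simulated genes).
    """

    gene: str
    sgo: np.ndarray
    pident: float
    fitness: str | None = None

    def __post_init__(self):
        self.sgo = np.asarray(self.sgo, dtype=float)
        if not np.isin(self.sgo, (0.0, 1.0)).all():
            raise SchemaError(f"{self.gene}: sGO entries must be 0/1")
        if not 0.0 <= self.pident <= 100.0:
            raise SchemaError(f"{self.gene}: pident must lie in [0, 100]")
        if self.fitness is not None and self.fitness not in FITNESS_CLASSES:
            raise SchemaError(f"{self.gene}: unknown fitness {self.fitness!r}")


class AnnotationTable:
    """Gene → annotation mapping together with the sGO vocabulary."""

    def __init__(self, vocabulary: list[str],
                 annotations: dict[str, GeneAnnotation] | None = None):
        self.vocabulary = list(vocabulary)
        self._ann: dict[str, GeneAnnotation] = {}
        for ann in (annotations or {}).values():
            self.add(ann)

    def add(self, ann: GeneAnnotation) -> None:
        if len(ann.sgo) != len(self.vocabulary):
            raise SchemaError(
                f"{ann.gene}: sGO vector length {len(ann.sgo)} != "
                f"vocabulary size {len(self.vocabulary)}")
        self._ann[ann.gene] = ann

    def __getitem__(self, gene: str) -> GeneAnnotation:
        return self._ann[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._ann

    def __len__(self) -> int:
        return len(self._ann)

    @property
    def genes(self) -> list[str]:
        return list(self._ann)

    def set_fitness(self, gene: str, fitness: str) -> None:
        self._ann[gene] = replace(self._ann[gene], fitness=fitness)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = []
        for g, a in self._ann.items():
            terms = ";".join(t for t, bit in zip(self.vocabulary, a.sgo) if bit)
            rows.append((g, a.fitness or "", a.pident, terms))
        pd.DataFrame(rows, columns=["gene", "fitness", "pident", "sgo_terms"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, vocabulary: list[str]) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        idx = {t: i for i, t in enumerate(vocabulary)}
        table = cls(vocabulary)
        for row in df.itertuples(index=False):
            bits = np.zeros(len(vocabulary))
            terms = str(row.sgo_terms)
            for t in filter(None, terms.split(";")):
                if t not in idx:
                    raise SchemaError(f"unknown sGO term {t!r} in {path}")
                bits[idx[t]] = 1.0
            fitness = row.fitness or None
            table.add(GeneAnnotation(row.gene, bits, float(row.pident), fitness))
        return table


def load_vocabulary(path) -> list[str]:
    """Read an sGO vocabulary file: one term per line, '#' comments."""
    with open(path) as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# Feature layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureLayout:
    """Named feature columns plus the category → column-index grouping
    used by feature-set selection and the Siamese per-gene/pairwise split."""

    names: tuple[str, ...]
    blocks: dict[str, tuple[int, ...]]

    def __len__(self) -> int:
        return len(self.names)

    def columns(self, categories) -> list[int]:
        cols: list[int] = []
        for cat in categories:
            if cat not in self.blocks:
                raise SchemaError(f"unknown feature category {cat!r}")
            cols.extend(self.blocks[cat])
        return sorted(cols)


def single_layout(vocabulary: list[str]) -> FeatureLayout:
    names = ("lid", "pident") + tuple(f"sgo:{t}" for t in vocabulary)
    blocks = {"lid": (0,), "pident": (1,),
              "sgo": tuple(range(2, 2 + len(vocabulary)))}
    return FeatureLayout(names, blocks)


def pair_layout(vocabulary: list[str]) -> FeatureLayout:
    names = (("lid_sum",) + tuple(f"combo:{c}" for c in PAIR_COMBOS)
             + ("spl", "spl_unreachable")
             + tuple(f"sgo:{t}" for t in vocabulary))
    m = len(vocabulary)
    blocks = {"lid": (0,), "fitness_combo": tuple(range(1, 7)),
              "spl": (7, 8), "sgo": tuple(range(9, 9 + m))}
    return FeatureLayout(names, blocks)


def triplet_layout(vocabulary: list[str]) -> FeatureLayout:
    names = (("lid_sum",) + tuple(f"combo:{c}" for c in TRIPLET_COMBOS)
             + ("scl", "scl_unreachable")
             + tuple(f"sgo:{t}" for t in vocabulary))
    m = len(vocabulary)
    blocks = {"lid": (0,), "fitness_combo": tuple(range(1, 11)),
              "scl": (11, 12), "sgo": tuple(range(13, 13 + m))}
    return FeatureLayout(names, blocks)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def _distance_features(d: float, *, binned: bool = False,
                       bin_threshold: float = 8.0) -> tuple[float, float]:
    """(value, unreachable_flag) encoding of an SPL/SCL distance.

    With ``binned=True`` the value becomes a <threshold indicator
    (the alternative coarse encoding; threshold 8 for circuits)."""
    if d == UNREACHABLE:
        return 0.0, 1.0
    if binned:
        return (1.0 if d < bin_threshold else 0.0), 0.0
    return float(d), 0.0


class SingleEncoder:
    """Encode single genes as ``[LID, Pident, sGO bits]``."""

    def __init__(self, table: AnnotationTable, net: PPINetwork):
        self.table = table
        self.net = net
        self.layout = single_layout(table.vocabulary)

    def encode(self, gene: str) -> np.ndarray:
        ann = self.table[gene]
        return np.concatenate(([lid(self.net, gene), ann.pident], ann.sgo))

    def encode_many(self, genes) -> np.ndarray:
        lid_cache = {g: lid(self.net, g) for g in set(genes)}
        X = np.empty((len(genes), len(self.layout)))
        for i, g in enumerate(genes):
            ann = self.table[g]
            X[i, 0] = lid_cache[g]
            X[i, 1] = ann.pident
            X[i, 2:] = ann.sgo
        return X


class _TupleEncoder:
    """Shared machinery for pair/triplet encoders.

    Precomputes per-gene LID, fitness codes and the sGO matrix plus the
    all-pairs SPL table, so ``encode_many`` is vectorised; ``encode``
    composes the identical vector from per-query graph calls (the two
    paths are tested for bitwise equality).
    """

    arity: int

    def __init__(self, table: AnnotationTable, net: PPINetwork,
                 *, binned_distance: bool = False):
        self.table = table
        self.net = net
        self.binned_distance = binned_distance
        self._dist: DistanceIndex | None = None

    def _require_fitness(self, gene: str) -> str:
        fit = self.table[gene].fitness
        if fit is None:
            raise SchemaError(f"gene {gene!r} has no fitness class assigned")
        return fit

    def _distance_cache(self) -> DistanceIndex:
        if self._dist is None:
            genes = sorted(set(self.table.genes) | self.net.nodes)
            self._dist = DistanceIndex(self.net, genes=genes)
        return self._dist

    def _gene_arrays(self):
        dist = self._distance_cache()
        genes = dist.genes
        pos = dist.index
        m = len(self.table.vocabulary)
        lid_vec = dist.lid
        fit_code = np.full(len(genes), -1, dtype=int)
        sgo = np.zeros((len(genes), m))
        for g in genes:
            if g in self.table:
                ann = self.table[g]
                if ann.fitness is not None:
                    fit_code[pos[g]] = FITNESS_CLASSES.index(ann.fitness)
                sgo[pos[g]] = ann.sgo
        return pos, lid_vec, fit_code, sgo, dist.spl


class PairEncoder(_TupleEncoder):
    """Encode unordered gene pairs (symmetric by construction)."""

    arity = 2

    def __init__(self, table, net, **kw):
        super().__init__(table, net, **kw)
        self.layout = pair_layout(table.vocabulary)

    def encode(self, gene_a: str, gene_b: str) -> np.ndarray:
        if gene_a == gene_b:
            raise ValueError("pair must consist of two distinct genes")
        # canonical gene order makes the vector bitwise order-invariant
        gene_a, gene_b = sorted((gene_a, gene_b))
        fits = (self._require_fitness(gene_a), self._require_fitness(gene_b))
        combo = np.zeros(len(PAIR_COMBOS))
        combo[fitness_combo_index(fits)] = 1.0
        spl = shortest_path_length(self.net, gene_a, gene_b)
        val, flag = _distance_features(spl, binned=self.binned_distance)
        ann_a, ann_b = self.table[gene_a], self.table[gene_b]
        lid_sum = lid(self.net, gene_a) + lid(self.net, gene_b)
        return np.concatenate(([lid_sum], combo, [val, flag],
                               ann_a.sgo + ann_b.sgo))

    def encode_many(self, pairs) -> np.ndarray:
        pos, lid_vec, fit_code, sgo, spl = self._gene_arrays()
        pairs = [tuple(sorted(p)) for p in pairs]
        ia = np.array([pos[a] for a, b in pairs])
        ib = np.array([pos[b] for a, b in pairs])
        if np.any(ia == ib):
            raise ValueError("pair must consist of two distinct genes")
        if np.any(fit_code[ia] < 0) or np.any(fit_code[ib] < 0):
            raise SchemaError("all pair genes need an assigned fitness class")
        n, m = len(pairs), sgo.shape[1]
        X = np.zeros((n, 9 + m))
        X[:, 0] = lid_vec[ia] + lid_vec[ib]
        counts = np.zeros((n, 3), dtype=int)
        for code in (fit_code[ia], fit_code[ib]):
            counts[np.arange(n), code] += 1
        combo_idx = np.array([_COMBO_BY_COUNTS[2][tuple(c)] for c in counts])
        X[np.arange(n), 1 + combo_idx] = 1.0
        d = spl[ia, ib]
        unreach = ~np.isfinite(d)
        if self.binned_distance:
            X[:, 7] = np.where(unreach, 0.0, (d < 8.0).astype(float))
        else:
            X[:, 7] = np.where(unreach, 0.0, d)
        X[:, 8] = unreach.astype(float)
        X[:, 9:] = sgo[ia] + sgo[ib]
        return X

    def encode_gene_blocks(self, pairs):
        """Per-gene and pairwise feature blocks for the Siamese models.

        Returns ``(G, P)`` where ``G`` has shape (n, 2, d_gene) holding
        each gene's ``[LID, fitness one-hot(3), sGO bits]`` block and
        ``P`` has shape (n, 2) holding ``[SPL value, unreachable flag]``.
        """
        pos, lid_vec, fit_code, sgo, spl = self._gene_arrays()
        n, m = len(pairs), sgo.shape[1]
        G = np.zeros((n, 2, 4 + m))
        P = np.zeros((n, 2))
        for j in range(2):
            gi = np.array([pos[p[j]] for p in pairs])
            G[:, j, 0] = lid_vec[gi]
            G[np.arange(n), j, 1 + fit_code[gi]] = 1.0
            G[:, j, 4:] = sgo[gi]
        ia = np.array([pos[a] for a, b in pairs])
        ib = np.array([pos[b] for a, b in pairs])
        d = spl[ia, ib]
        unreach = ~np.isfinite(d)
        P[:, 0] = np.where(unreach, 0.0, d)
        P[:, 1] = unreach.astype(float)
        return G, P


class TripletEncoder(_TupleEncoder):
    """Encode unordered gene triplets (symmetric by construction)."""

    arity = 3

    def __init__(self, table, net, **kw):
        super().__init__(table, net, **kw)
        self.layout = triplet_layout(table.vocabulary)

    def encode(self, gene_a: str, gene_b: str, gene_c: str) -> np.ndarray:
        if len({gene_a, gene_b, gene_c}) != 3:
            raise ValueError("triplet must consist of three distinct genes")
        genes = tuple(sorted((gene_a, gene_b, gene_c)))
        fits = tuple(self._require_fitness(g) for g in genes)
        combo = np.zeros(len(TRIPLET_COMBOS))
        combo[fitness_combo_index(fits)] = 1.0
        scl = shortest_circuit_length(self.net, *genes)
        val, flag = _distance_features(scl, binned=self.binned_distance)
        sgo_sum = sum(self.table[g].sgo for g in genes)
        lid_sum = sum(lid(self.net, g) for g in genes)
        return np.concatenate(([lid_sum], combo, [val, flag], sgo_sum))

    def encode_many(self, triplets) -> np.ndarray:
        pos, lid_vec, fit_code, sgo, spl = self._gene_arrays()
        if any(len(set(t)) != 3 for t in triplets):
            raise ValueError("triplet must consist of three distinct genes")
        triplets = [tuple(sorted(t)) for t in triplets]
        n, m = len(triplets), sgo.shape[1]
        gi = np.array([[pos[g] for g in t] for t in triplets])
        if np.any(fit_code[gi] < 0):
            raise SchemaError("all triplet genes need an assigned fitness class")
        X = np.zeros((n, 13 + m))
        X[:, 0] = lid_vec[gi].sum(axis=1)
        counts = np.zeros((n, 3), dtype=int)
        for j in range(3):
            counts[np.arange(n), fit_code[gi[:, j]]] += 1
        combo_idx = np.array([_COMBO_BY_COUNTS[3][tuple(c)] for c in counts])
        X[np.arange(n), 1 + combo_idx] = 1.0
        d = (spl[gi[:, 0], gi[:, 1]] + spl[gi[:, 1], gi[:, 2]]
             + spl[gi[:, 0], gi[:, 2]])
        unreach = ~np.isfinite(d)
        if self.binned_distance:
            X[:, 11] = np.where(unreach, 0.0, (d < 8.0).astype(float))
        else:
            X[:, 11] = np.where(unreach, 0.0, d)
        X[:, 12] = unreach.astype(float)
        X[:, 13:] = sgo[gi[:, 0]] + sgo[gi[:, 1]] + sgo[gi[:, 2]]
        return X

    def encode_gene_blocks(self, triplets):
        """Per-gene blocks (n, 3, d_gene) and pairwise block [SCL, flag]."""
        pos, lid_vec, fit_code, sgo, spl = self._gene_arrays()
        n, m = len(triplets), sgo.shape[1]
        G = np.zeros((n, 3, 4 + m))
        for j in range(3):
            gi = np.array([pos[t[j]] for t in triplets])
            G[:, j, 0] = lid_vec[gi]
            G[np.arange(n), j, 1 + fit_code[gi]] = 1.0
            G[:, j, 4:] = sgo[gi]
        gi = np.array([[pos[g] for g in t] for t in triplets])
        d = (spl[gi[:, 0], gi[:, 1]] + spl[gi[:, 1], gi[:, 2]]
             + spl[gi[:, 0], gi[:, 2]])
        unreach = ~np.isfinite(d)
        P = np.stack([np.where(unreach, 0.0, d), unreach.astype(float)], axis=1)
        return G, P


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GIRecord:
    """A labelled genetic-interaction observation for a gene pair."""

    genes: tuple[str, str]
    label: str
    n_publications: int = 0
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", canonical_pair(*self.genes))
        if self.n_publications < 0:
            raise ValueError("n_publications must be non-negative")


def build_hybrid_gi_dataset(neutral_records, gi_records,
                            min_pubs: int = 3) -> list[GIRecord]:
    """Merge systematic-screen neutrals with literature-curated GIs.

    Keeps every neutral record and every non-neutral record supported by
    at least ``min_pubs`` publications; a pair present in both sources
    resolves to the non-neutral label (a literature-supported GI trumps
    a screen-level neutral call, logged).
    """
    merged: dict[tuple[str, str], GIRecord] = {}
    for rec in neutral_records:
        merged[rec.genes] = rec
    n_conflicts = 0
    for rec in gi_records:
        if rec.label != "neutral" and rec.n_publications < min_pubs:
            continue
        prev = merged.get(rec.genes)
        if prev is not None and prev.label != rec.label:
            n_conflicts += 1
        if prev is None or rec.label != "neutral":
            merged[rec.genes] = rec
    if n_conflicts:
        logger.info("hybrid GI dataset: %d neutral/GI conflicts resolved "
                    "to the non-neutral label", n_conflicts)
    return list(merged.values())


def negative_sample_neutral_pairs(genes, gi_pairs, n: int,
                                  seed: int) -> list[tuple[str, str]]:
    """Sample ``n`` distinct unordered pairs never observed as GIs.

    Reproducible under ``seed``; raises if the pair universe minus the
    GI pairs cannot supply ``n`` pairs.
    """
    genes = sorted(set(genes))
    geneset = set(genes)
    gi = {canonical_pair(*p) for p in gi_pairs}
    universe = len(genes) * (len(genes) - 1) // 2
    capacity = universe - sum(1 for p in gi
                              if p[0] in geneset and p[1] in geneset)
    if n > capacity:
        raise ValueError(
            f"requested {n} neutral pairs but only {capacity} are available")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    if universe <= 4 * n:  # small universe: enumerate and choose exactly
        pool = [p for p in itertools.combinations(genes, 2) if p not in gi]
        picks = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(picks)]
    while len(chosen) < n:  # rejection sampling in a large universe
        k = 2 * (n - len(chosen))
        ia = rng.integers(0, len(genes), size=k)
        ib = rng.integers(0, len(genes), size=k)
        for a, b in zip(ia, ib):
            if a == b:
                continue
            p = canonical_pair(genes[a], genes[b])
            if p not in gi and p not in chosen:
                chosen.add(p)
                if len(chosen) == n:
                    break
    return sorted(chosen)


def derive_mo_lethal(organismal_lethal: set, ca_lethal: set) -> set:
    """Multicellular-organismal lethal genes: organismal minus
    cell-autonomous lethals (genes lethal to single cells are removed so
    the remainder is essential only at the whole-organism level)."""
    return set(organismal_lethal) - set(ca_lethal)


_REGROUP_MAPS = {
    "lethal_vs_viable": {"L": "lethal", "R": "viable", "N": "viable"},
    "interacting_vs_neutral": {"negative": "GI", "positive": "GI",
                               "suppression": "GI", "neutral": "neutral"},
}


def regroup_labels(labels, scheme: str, *, genes=None,
                   ca_lethal: set | None = None,
                   mo_lethal: set | None = None) -> list[str]:
    """Deterministically merge label classes under a named scheme.

    ``lethal_vs_viable`` folds reduced growth and normal into viable;
    ``interacting_vs_neutral`` folds negative/positive/suppression into
    a single GI class; ``ca_mo_viable`` relabels genes (passed via
    ``genes``) as cell-autonomous lethal, multicellular-organismal
    lethal, or viable from the two lethal gene sets.
    """
    if scheme == "ca_mo_viable":
        if genes is None or ca_lethal is None or mo_lethal is None:
            raise SchemaError("ca_mo_viable needs genes, ca_lethal, mo_lethal")
        out = []
        for g in genes:
            if g in ca_lethal:
                out.append("CA")
            elif g in mo_lethal:
                out.append("MO")
            else:
                out.append("viable")
        return out
    if scheme not in _REGROUP_MAPS:
        raise SchemaError(f"unknown regrouping scheme {scheme!r}")
    mapping = _REGROUP_MAPS[scheme]
    out = []
    for lab in labels:
        if lab not in mapping:
            raise SchemaError(f"label {lab!r} not valid under scheme {scheme!r}")
        out.append(mapping[lab])
    return out


def dataset_to_tsv(path, tuples, X: np.ndarray, y, layout: FeatureLayout):
    """Write an encoded dataset as TSV with a JSON sidecar for the layout."""
    import json
    arity = len(tuples[0])
    gene_cols = [f"gene_{chr(97 + i)}" for i in range(arity)]
    df = pd.DataFrame(tuples, columns=gene_cols)
    for j, name in enumerate(layout.names):
        df[name] = X[:, j]
    df["label"] = list(y)
    df.to_csv(path, sep="\t", index=False)
    sidecar = str(path) + ".layout.json"
    with open(sidecar, "w") as fh:
        json.dump({"names": list(layout.names),
                   "blocks": {k: list(v) for k, v in layout.blocks.items()}},
                  fh, indent=2)
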