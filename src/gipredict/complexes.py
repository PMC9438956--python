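"""Within- vs across-complex (or pathway) genetic-interaction structure.

Genetic interactions concentrate among genes whose proteins belong to
the same molecular complex or pathway.  This module computes, for a set
of labelled gene pairs or triplets and a unit-membership table, the
class distribution of tuples whose genes all share a unit ("within")
versus those that do not ("across"), plus a one-sided proportion test
for GI enrichment in the within group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)


class MembershipTable:
    """unit ID → member gene set (complexes or pathways).

    Genes may belong to several units; every unit must be non-empty.
    """

    def __init__(self, units: dict[str, set] | None = None):
        self._units: dict[str, frozenset] = {}
        for uid, members in (units or {}).items():
            self.add(uid, members)
        self._gene_units: dict[str, set] | None = None

    def add(self, unit_id: str, members) -> None:
        members = frozenset(members)
        if not members:
            raise ValueError(f"unit {unit_id!r} has no members")
        self._units[unit_id] = members
        self._gene_units = None

    def __getitem__(self, unit_id: str) -> frozenset:
        return self._units[unit_id]

    def __len__(self) -> int:
        return len(self._units)

    @property
    def units(self) -> dict[str, frozenset]:
        return dict(self._units)

    def units_of(self, gene: str) -> set:
        if self._gene_units is None:
            gu: dict[str, set] = {}
            for uid, members in self._units.items():
                for g in members:
                    gu.setdefault(g, set()).add(uid)
            self._gene_units = gu
        return self._gene_units.get(gene, set())

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = [(uid, g) for uid, members in self._units.items()
                for g in sorted(members)]
        pd.DataFrame(rows, columns=["unit_id", "gene"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MembershipTable":
        df = pd.read_csv(path, sep="\t")
        units: dict[str, set] = {}
        for row in df.itertuples(index=False):
            units.setdefault(str(row.unit_id), set()).add(row.gene)
        return cls(units)


def shares_unit(genes, membership: MembershipTable,
                rule: str = "all") -> bool:
    """Whether a gene tuple counts as within-unit.

    ``"all"``: every gene shares at least one common unit (intersection
    non-empty); ``"majority"``: some unit contains at least two of three
    genes (the relaxed reading for triplets).
    """
    unit_sets = [membership.units_of(g) for g in genes]
    if rule == "all":
        common = set.intersection(*unit_sets) if unit_sets else set()
        return bool(common)
    if rule == "majority":
        if len(genes) == 2:
            return bool(unit_sets[0] & unit_sets[1])
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if unit_sets[i] & unit_sets[j]:
                    return True
        return False
    raise ValueError(f"unknown within-unit rule {rule!r}")


@dataclass
class WithinAcrossResult:
    """Class counts and distributions for within- vs across-unit tuples."""

    classes: tuple[str, ...]
    within_counts: np.ndarray
    across_counts: np.ndarray

    def _dist(self, counts) -> np.ndarray | None:
        total = counts.sum()
        return counts / total if total else None

    @property
    def within_distribution(self) -> np.ndarray | None:
        return self._dist(self.within_counts)

    @property
    def across_distribution(self) -> np.ndarray | None:
        return self._dist(self.across_counts)

    @property
    def n_within(self) -> int:
        return int(self.within_counts.sum())

    @property
    def n_across(self) -> int:
        return int(self.across_counts.sum())

    def fraction(self, group: str, labels) -> float | None:
        """Fraction of tuples in ``group`` ("within"/"across") whose
        class is in ``labels`` (e.g. the non-neutral GI classes)."""
        counts = self.within_counts if group == "within" else self.across_counts
        total = counts.sum()
        if total == 0:
            return None
        sel = [i for i, c in enumerate(self.classes) if c in set(labels)]
        return float(counts[sel].sum() / total)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"class": self.classes,
                           "within_count": self.within_counts,
                           "across_count": self.across_counts})
        for grp in ("within", "across"):
            dist = getattr(self, f"{grp}_distribution")
            df[f"{grp}_fraction"] = dist if dist is not None else np.nan
        df.to_csv(path, sep="\t", index=False)


def within_across_distribution(tuples, labels, membership: MembershipTable,
                               classes=None,
                               rule: str = "all") -> WithinAcrossResult:
    """Split labelled tuples into within/across-unit groups and count
    outcome classes in each.  Genes in no unit count as across."""
    labels = list(labels)
    if classes is None:
        classes = tuple(sorted(set(labels)))
    classes = tuple(classes)
    cindex = {c: i for i, c in enumerate(classes)}
    within = np.zeros(len(classes), dtype=int)
    across = np.zeros(len(classes), dtype=int)
    for tup, lab in zip(tuples, labels):
        target = within if shares_unit(tup, membership, rule=rule) else across
        target[cindex[lab]] += 1
    if within.sum() == 0:
        logger.warning("no within-unit tuples; within distribution missing")
    if across.sum() == 0:
        logger.warning("no across-unit tuples; across distribution missing")
    return WithinAcrossResult(classes, within, across)


def gi_enrichment_test(result: WithinAcrossResult, gi_classes):
    """One-sided two-sample proportion z-test that the within-unit GI
    fraction exceeds the across-unit one.  Returns (z, p)."""
    gi_classes = set(gi_classes)
    sel = [i for i, c in enumerate(result.classes) if c in gi_classes]
    counts = np.array([result.within_counts[sel].sum(),
                       result.across_counts[sel].sum()])
    nobs = np.array([result.n_within, result.n_across])
    if (nobs == 0).any():
        raise ValueError("both groups need at least one tuple")
    z, p = proportions_ztest(counts, nobs, alternative="larger")
    return float(z), float(p)
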