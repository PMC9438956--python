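"""Exhaustive feature-set selection.

All non-empty subsets of the named feature categories are enumerated
(2^m - 1 of them; seven categories give the classic 127 candidate
models), each is scored by repeated cross-validated balanced accuracy,
and the refined model is the smallest subset whose mean BA is within a
tolerance of the best — mirroring the principle of keeping the fewest
input features that achieve the highest prediction performance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import CVPlan, repeated_cv
from .features import FeatureLayout

#: Enumerating beyond this many categories is almost certainly a mistake.
MAX_CATEGORIES = 16


def enumerate_feature_subsets(categories) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``categories``, ordered by size then
    lexicographically.  m categories yield 2^m - 1 subsets."""
    cats = list(categories)
    if len(cats) == 0:
        raise ValueError("need at least one feature category")
    if len(cats) > MAX_CATEGORIES:
        raise ValueError(
            f"{len(cats)} categories would enumerate {2 ** len(cats) - 1} "
            f"subsets; the guard is {MAX_CATEGORIES}")
    subsets = []
    for size in range(1, len(cats) + 1):
        for combo in itertools.combinations(sorted(cats), size):
            subsets.append(combo)
    return subsets


@dataclass
class SelectionResult:
    """Outcome of refined-model selection."""

    table: pd.DataFrame            # subset, size, mean_ba, sd_ba
    chosen: tuple[str, ...]
    tolerance: float

    @property
    def chosen_row(self) -> pd.Series:
        mask = self.table["subset"].apply(lambda s: tuple(s) == self.chosen)
        return self.table[mask].iloc[0]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["subset"] = df["subset"].apply(lambda s: "+".join(s))
        df["chosen"] = df["subset"] == "+".join(self.chosen)
        df.to_csv(path, sep="\t", index=False)


def evaluate_subsets(X, y, layout: FeatureLayout, fit_fn,
                     plan: CVPlan | None = None,
                     categories=None) -> pd.DataFrame:
    """Cross-validate one model per feature-category subset.

    ``fit_fn(X_sub, y, seed)`` fits a classifier on the selected
    columns.  Returns a DataFrame with columns subset / size / mean_ba /
    sd_ba in enumeration order.
    """
    cats = list(categories) if categories is not None else list(layout.blocks)
    rows = []
    for subset in enumerate_feature_subsets(cats):
        cols = layout.columns(subset)
        res = repeated_cv(np.asarray(X)[:, cols], y, fit_fn, plan)
        rows.append({"subset": subset, "size": len(subset),
                     "mean_ba": res.mean_ba, "sd_ba": res.sd_ba})
    return pd.DataFrame(rows)


def select_refined(results: pd.DataFrame,
                   tolerance: float | None = None) -> SelectionResult:
    """Pick the smallest subset within ``tolerance`` of the best mean BA.

    ``tolerance=None`` uses one standard deviation of the best subset's
    cross-validated BA (the default operational reading of "achieves the
    highest performance"); ties in size break lexicographically.
    """
    if len(results) == 0:
        raise ValueError("no selection results supplied")
    best_idx = results["mean_ba"].idxmax()
    best_ba = float(results.loc[best_idx, "mean_ba"])
    if tolerance is None:
        tolerance = float(results.loc[best_idx, "sd_ba"])
    ok = results[results["mean_ba"] >= best_ba - tolerance].copy()
    ok = ok.sort_values(
        by=["size", "subset"],
        key=lambda col: col.apply(tuple) if col.name == "subset" else col)
    chosen = tuple(ok.iloc[0]["subset"])
    return SelectionResult(results, chosen, float(tolerance))
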