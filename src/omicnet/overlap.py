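"""Cross-tabulation of two module partitions and overlap significance.

Given the partitions of two networks (e.g. two brain regions) over a shared
feature universe, every (module A, module B) cell of the contingency table
holds the number of features assigned to both, and its one-sided
hypergeometric upper-tail p — identical to a one-sided Fisher exact test on
the collapsed 2x2 table — asks whether that overlap is larger than chance.
p-values are computed in log space so magnitudes far below the float
underflow limit (the interesting overlaps can reach 1e-40 and beyond) are
represented exactly as -log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .network import GREY, ModulePartition

__all__ = [
    "ContingencyTable",
    "cross_tabulate",
    "overlap_p",
    "overlap_log10_p",
    "shared_members",
]


@dataclass
class ContingencyTable:
    """Counts and per-cell overlap significance for two partitions."""

    counts: pd.DataFrame        # rows = modules of A (incl grey), cols = modules of B
    p: pd.DataFrame             # one-sided hypergeometric upper-tail p per cell
    neg_log10_p: pd.DataFrame   # exact -log10 p (log-space computation)
    universe: list              # shared features the table is computed over

    @property
    def universe_size(self) -> int:
        return len(self.universe)


def _ordered_labels(part: ModulePartition, universe) -> list:
    sub = part.assignments.reindex(universe)
    sizes = sub.value_counts()
    labels = [c for c in sizes.index if c != GREY]
    labels.sort(key=lambda c: (-sizes[c], c))
    if GREY in sizes.index:
        labels.append(GREY)
    return labels


def overlap_log10_p(cell: int, row_total: int, col_total: int, universe: int) -> float:
    """Exact log10 of P(X >= cell), X ~ Hypergeometric(universe, row_total, col_total).

    Computed by log-sum-exp over hypergeometric log-pmf terms, so values
    like 1e-46 are represented without underflow.
    """
    _check_margins(cell, row_total, col_total, universe)
    hi = min(row_total, col_total)
    if cell <= 0:
        return 0.0
    k = np.arange(cell, hi + 1)
    lp = stats.hypergeom.logpmf(k, universe, row_total, col_total)
    return float(logsumexp(lp) / np.log(10.0))


def overlap_p(cell: int, row_total: int, col_total: int, universe: int) -> float:
    """One-sided overlap p: hypergeometric upper tail P(X >= cell).

    Equals the one-sided Fisher exact p of the collapsed 2x2 table.  May
    underflow to 0.0 for extreme overlaps; use :func:`overlap_log10_p` when
    the magnitude matters.
    """
    return float(10.0 ** overlap_log10_p(cell, row_total, col_total, universe))


def _check_margins(cell: int, row_total: int, col_total: int, universe: int) -> None:
    if not (0 <= row_total <= universe and 0 <= col_total <= universe):
        raise ValueError("margins exceed universe")
    if not 0 <= cell <= min(row_total, col_total):
        raise ValueError(
            f"cell {cell} inconsistent with margins ({row_total}, {col_total})"
        )
    if cell < row_total + col_total - universe:
        raise ValueError("cell below the hypergeometric support minimum")


def cross_tabulate(partA: ModulePartition, partB: ModulePartition) -> ContingencyTable:
    """Contingency table of two partitions over their shared feature universe.

    The universe is the intersection of features present in both partitions
    (only those can overlap); grey rows/columns are included.  Every cell
    gets a one-sided hypergeometric p.
    """
    universe = sorted(set(partA.assignments.index) & set(partB.assignments.index))
    if not universe:
        raise ValueError("empty universe: partitions share no features")
    a = partA.assignments.reindex(universe)
    b = partB.assignments.reindex(universe)
    rows = _ordered_labels(partA, universe)
    cols = _ordered_labels(partB, universe)
    counts = (
        pd.crosstab(a, b)
        .reindex(index=rows, columns=cols, fill_value=0)
        .astype(int)
    )
    counts.index.name = "moduleA"
    counts.columns.name = "moduleB"
    N = len(universe)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    log10p = pd.DataFrame(
        0.0,
        index=pd.Index(rows, name="moduleA"),
        columns=pd.Index(cols, name="moduleB"),
    )
    for ra in rows:
        for cb in cols:
            log10p.loc[ra, cb] = overlap_log10_p(
                int(counts.loc[ra, cb]), int(row_tot[ra]), int(col_tot[cb]), N
            )
    p = (10.0 ** log10p).clip(upper=1.0)
    return ContingencyTable(counts=counts, p=p, neg_log10_p=-log10p, universe=universe)


def shared_members(
    partA: ModulePartition, partB: ModulePartition, moduleA: str, moduleB: str
) -> list:
    """Sorted universe features assigned to ``moduleA`` in A and ``moduleB`` in B."""
    for part, name in ((partA, moduleA), (partB, moduleB)):
        if name not in set(part.assignments.unique()):
            raise KeyError(f"unknown module {name!r}")
    universe = set(partA.assignments.index) & set(partB.assignments.index)
    return sorted(
        f
        for f in universe
        if partA.assignments[f] == moduleA and partB.assignments[f] == moduleB
    )
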