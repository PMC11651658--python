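"""Hallmark combination counting.

Given per-hallmark driver-gene counts for a cancer type, the number of
distinct one-gene-per-hallmark mutation combinations is the exact integer
product of the counts; the reciprocal of each count bounds the prevalence of
any single gene within its hallmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from pathlib import Path

import pandas as pd


@dataclass
class CombinationResult:
    product: int
    min_prevalence: dict[str, float | None]


def load_hallmark_table(path: str | Path, column: str | None = None) -> dict[str, int]:
    """Load a hallmark -> gene-count map from a TSV.

    With two columns the second is the count; with more, ``column`` selects
    the count column.
    """
    df = pd.read_csv(path, sep="\t")
    if column is None:
        if len(df.columns) != 2:
            raise ValueError("ambiguous hallmark table: pass column=")
        column = df.columns[1]
    counts = {str(r[df.columns[0]]): int(r[column]) for _, r in df.iterrows()}
    if any(c < 0 for c in counts.values()):
        raise ValueError("hallmark counts must be non-negative")
    return counts


def combination_count(table: dict[str, int]) -> CombinationResult:
    """Exact product of per-hallmark gene counts and per-hallmark 1/count bounds.

    An empty table yields product 1; any zero count makes the product 0 and
    its prevalence bound undefined (None).
    """
    if any(c < 0 for c in table.values()):
        raise ValueError("hallmark counts must be non-negative")
    product = prod(table.values())
    bounds = {h: (1 / c if c else None) for h, c in table.items()}
    return CombinationResult(product, bounds)


def leave_k_out_products(table: dict[str, int], k: int = 1) -> dict[tuple[str, ...], int]:
    """Products with k hallmarks left out (unvalidated exploratory variant)."""
    from itertools import combinations

    names = sorted(table)
    out = {}
    for drop in combinations(names, k):
        kept = [table[h] for h in names if h not in drop]
        out[drop] = prod(kept)
    return out
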