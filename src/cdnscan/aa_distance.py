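"""Elementary amino-acid pairs and physicochemical-distance (dU) profiling.

Of the 190 unordered amino-acid pairs, exactly 75 are "elementary" under the
standard genetic code: reachable by changing a single nucleotide of a codon.
Each elementary pair carries a physicochemical distance dU in [0, 1]
summarizing dozens of property scales (hydrophobicity, size, charge, ...);
the most similar pair (Ser, Thr) anchors 0 and the most dissimilar
(Asp, Tyr) anchors 1.  Canonical per-pair values come from the published
reference scale and are loaded from a user-supplied TSV; a deterministic
placeholder table (uniform grid respecting the two anchors) is provided for
self-contained runs and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import seq1

from .caller import CDN

Pair = frozenset


def enumerate_elementary_pairs(code: dict[str, str] | None = None) -> set[Pair]:
    """Unordered amino-acid pairs reachable by a 1-bp sense-codon change.

    Synonymous and stop-involving codon pairs are discarded.  75 pairs for
    the standard code.
    """
    from .coding import standard_code

    code = code or standard_code()
    pairs: set[Pair] = set()
    for codon, aa in code.items():
        if aa == "*":
            continue
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                other = code[codon[:pos] + alt + codon[pos + 1 :]]
                if other == "*" or other == aa:
                    continue
                pairs.add(frozenset((aa, other)))
    return pairs


@dataclass
class DeltaUTable:
    """Symmetric map from elementary amino-acid pair to dU in [0, 1]."""

    values: dict[Pair, float]
    provenance: str = "canonical"  # "canonical" | "placeholder"
    _elementary: set[Pair] = field(default_factory=enumerate_elementary_pairs, repr=False)

    def validate(self) -> None:
        if set(self.values) != self._elementary:
            missing = self._elementary - set(self.values)
            extra = set(self.values) - self._elementary
            raise ValueError(
                f"dU table domain mismatch: {len(missing)} missing, {len(extra)} non-elementary"
            )
        if any(not 0 <= v <= 1 for v in self.values.values()):
            raise ValueError("dU values must lie in [0, 1]")
        if self.values[frozenset(("S", "T"))] != 0:
            raise ValueError("anchor violated: (Ser, Thr) must be 0")
        if max(self.values.values()) != 1:
            raise ValueError("anchor violated: maximum dU must be 1")


def delta_u(pair: tuple[str, str] | Pair, table: DeltaUTable) -> float:
    """Symmetric dU lookup; raises on a non-elementary pair."""
    key = frozenset(pair)
    try:
        return table.values[key]
    except KeyError:
        a, b = sorted(pair)
        raise ValueError(f"({a}, {b}) is not an elementary amino-acid pair") from None


def placeholder_delta_u(code: dict[str, str] | None = None) -> DeltaUTable:
    """Deterministic non-canonical dU table for self-contained runs.

    Anchors (Ser, Thr) = 0 and (Asp, Tyr) = 1; the remaining pairs receive an
    evenly spaced grid over (0, 1) in lexicographic pair order.  Structurally
    valid but NOT the published distance scale; outputs derived from it carry
    the ``placeholder`` provenance flag.
    """
    pairs = enumerate_elementary_pairs(code)
    anchors = {frozenset(("S", "T")): 0.0, frozenset(("D", "Y")): 1.0}
    rest = sorted(tuple(sorted(p)) for p in pairs if frozenset(p) not in anchors)
    values = dict(anchors)
    for j, p in enumerate(rest, start=1):
        values[frozenset(p)] = j / (len(rest) + 1)
    table = DeltaUTable(values, provenance="placeholder")
    table.validate()
    return table


def load_delta_u(path: str | Path) -> DeltaUTable:
    """Load a dU table from a TSV with columns aa1, aa2, delta_u.

    Amino acids may be one- or three-letter codes.  The table is validated
    against the elementary pair set and the printed anchors.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("aa1", "aa2", "delta_u"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    values = {}
    for r in df.itertuples(index=False):
        a = seq1(r.aa1) if len(str(r.aa1)) == 3 else str(r.aa1).upper()
        b = seq1(r.aa2) if len(str(r.aa2)) == 3 else str(r.aa2).upper()
        values[frozenset((a, b))] = float(r.delta_u)
    table = DeltaUTable(values, provenance="canonical")
    table.validate()
    return table


@dataclass
class RecurrenceGroupProfile:
    i_min: int
    i_max: int
    count: int
    prop_gt_08: float
    prop_lt_04: float


def deltau_recurrence_profile(
    cdns: list[CDN],
    table: DeltaUTable,
    min_group: int = 10,
) -> list[RecurrenceGroupProfile]:
    """Bin CDNs by recurrence and profile dU per group.

    Whole recurrence classes accumulate in descending order of i until a
    group holds at least ``min_group`` CDNs; a trailing group short of
    ``min_group`` merges into the previous one.  Per group, reports the
    proportions of CDNs with dU strictly above 0.8 and strictly below 0.4.
    """
    if not cdns:
        return []
    by_i: dict[int, list[float]] = {}
    for c in cdns:
        by_i.setdefault(c.i, []).append(delta_u((c.aa_ref, c.aa_alt), table))
    groups: list[tuple[int, int, list[float]]] = []
    current: list[float] = []
    hi: int | None = None
    for i in sorted(by_i, reverse=True):
        if hi is None:
            hi = i
        current.extend(by_i[i])
        lo = i
        if len(current) >= min_group:
            groups.append((lo, hi, current))
            current, hi = [], None
    if current:
        if groups:
            lo_prev, hi_prev, vals = groups.pop()
            groups.append((lo, hi_prev, vals + current))
        else:
            groups.append((lo, hi if hi is not None else lo, current))
    return [
        RecurrenceGroupProfile(
            i_min=lo,
            i_max=hi,
            count=len(vals),
            prop_gt_08=sum(v > 0.8 for v in vals) / len(vals),
            prop_lt_04=sum(v < 0.4 for v in vals) / len(vals),
        )
        for lo, hi, vals in groups
    ]
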