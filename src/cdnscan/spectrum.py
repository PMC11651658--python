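"""Per-site recurrence tallies: the A_i / S_i spectrum and its summaries.

A_i (S_i) is the number of missense (synonymous) site-alleles mutated in
exactly i distinct patients; A_0 and S_0 are defined by subtraction from the
total missense/synonymous site counts L_A and L_S, so that
sum_i A_i + A_0 = L_A holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .coding import MISSENSE, SYNONYMOUS, SiteCounts


@dataclass
class RecurrenceSpectrum:
    """Recurrence spectrum of one cohort (one cancer type).

    ``A`` and ``S`` map exact recurrence i (>= 1) to site-allele counts.
    Published summaries may carry additional binned classes in ``A_binned``,
    keyed by (lo, hi) inclusive ranges with ``hi=None`` meaning open-ended;
    :meth:`a_tail` uses them transparently.
    """

    cancer_type: str
    n: int
    A: dict[int, int]
    S: dict[int, int]
    L_A: float
    L_S: float
    A_binned: dict[tuple[int, int | None], int] = field(default_factory=dict)
    site_index: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.A = {int(i): int(c) for i, c in self.A.items() if c}
        self.S = {int(i): int(c) for i, c in self.S.items() if c}
        if self.A_0 < 0 or self.S_0 < 0:
            raise ValueError("mutated site-alleles exceed site counts (model/table mismatch)")

    @property
    def A_0(self) -> float:
        return self.L_A - sum(self.A.values()) - sum(self.A_binned.values())

    @property
    def S_0(self) -> float:
        return self.L_S - sum(self.S.values())

    @property
    def total_missense_mutations(self) -> float:
        """Sum of i * A_i; exact only when no binned classes are present."""
        if self.A_binned:
            raise ValueError("total is not exactly recoverable from binned classes")
        return sum(i * c for i, c in self.A.items())

    def a_tail(self, k: int) -> int:
        """A_{i>=k}: number of missense site-alleles with recurrence >= k."""
        total = sum(c for i, c in self.A.items() if i >= k)
        for (lo, hi), c in self.A_binned.items():
            if lo >= k:
                total += c
            elif hi is None or hi >= k:
                raise ValueError(f"threshold {k} falls inside binned class [{lo}, {hi}]")
        return total

    def s_tail(self, k: int) -> int:
        return sum(c for i, c in self.S.items() if i >= k)


def tally_spectrum(
    annotated: pd.DataFrame,
    counts: SiteCounts,
    n: int,
    cancer_type: str = "",
) -> RecurrenceSpectrum:
    """Tally the recurrence spectrum from a consolidated, annotated table.

    Recurrence of a site-allele is the number of *distinct patients* carrying
    it (duplicate patient records guard against upstream consolidation bugs).
    Nonsense and other records are excluded from both A and S.
    """
    n_distinct = annotated["patient_id"].nunique() if len(annotated) else 0
    if n < n_distinct:
        raise ValueError(f"n={n} smaller than {n_distinct} distinct patients in table")

    coding = annotated[annotated["consequence"].isin([MISSENSE, SYNONYMOUS])]
    if len(coding):
        grouped = (
            coding.groupby("site_key")
            .agg(
                gene=("gene", "first"),
                consequence=("consequence", "first"),
                aa_ref=("aa_ref", "first"),
                aa_alt=("aa_alt", "first"),
                patients=("patient_id", lambda s: tuple(sorted(set(s)))),
            )
            .reset_index()
        )
        grouped["i"] = grouped["patients"].map(len)
    else:
        grouped = pd.DataFrame(
            columns=["site_key", "gene", "consequence", "aa_ref", "aa_alt", "patients", "i"]
        )

    A: dict[int, int] = {}
    S: dict[int, int] = {}
    for cons, target in ((MISSENSE, A), (SYNONYMOUS, S)):
        sub = grouped[grouped["consequence"] == cons]
        for i, c in sub["i"].value_counts().items():
            target[int(i)] = int(c)
    if sum(A.values()) > counts.L_A or sum(S.values()) > counts.L_S:
        raise ValueError("mutated site-alleles exceed site counts (model/table mismatch)")
    return RecurrenceSpectrum(
        cancer_type=cancer_type,
        n=n,
        A=A,
        S=S,
        L_A=counts.L_A,
        L_S=counts.L_S,
        site_index=grouped,
    )


def spectrum_ratios(spec: RecurrenceSpectrum) -> pd.DataFrame:
    """Per-i A/S ratio table (i=0 uses A_0/S_0); NaN where S_i = 0."""
    rows = []
    imax = max([0, *spec.A.keys(), *spec.S.keys()])
    for i in range(imax + 1):
        a = spec.A_0 if i == 0 else spec.A.get(i, 0)
        s = spec.S_0 if i == 0 else spec.S.get(i, 0)
        rows.append({"i": i, "A": a, "S": s, "ratio": a / s if s else math.nan})
    return pd.DataFrame(rows)


@dataclass
class CrossCancerSummary:
    k: int
    per_type_tail: dict[str, int]
    mean_tail: float
    mean_A: dict[int, float]
    mean_S: dict[int, float]
    ratio_of_means: dict[int, float]


def aggregate_spectra(specs: list[RecurrenceSpectrum], k: int = 3) -> CrossCancerSummary:
    """Cross-cancer summaries: per-type A_{i>=k}, means, and ratio-of-means A/S.

    The per-i A/S ratio of means divides the cross-cancer mean A_i by the
    mean S_i (i = 0 uses A_0 and S_0).
    """
    if not specs:
        raise ValueError("need at least one spectrum")
    per_type_tail = {s.cancer_type: s.a_tail(k) for s in specs}
    mean_tail = sum(per_type_tail.values()) / len(specs)
    imax = max(max([0, *s.A.keys()]) for s in specs)
    imax = max(imax, max(max([0, *s.S.keys()]) for s in specs))
    mean_A: dict[int, float] = {}
    mean_S: dict[int, float] = {}
    ratio: dict[int, float] = {}
    for i in range(imax + 1):
        if i == 0:
            ma = sum(s.A_0 for s in specs) / len(specs)
            ms = sum(s.S_0 for s in specs) / len(specs)
        else:
            ma = sum(s.A.get(i, 0) for s in specs) / len(specs)
            ms = sum(s.S.get(i, 0) for s in specs) / len(specs)
        mean_A[i], mean_S[i] = ma, ms
        ratio[i] = ma / ms if ms else math.nan
    return CrossCancerSummary(k, per_type_tail, mean_tail, mean_A, mean_S, ratio)


def spectrum_to_frame(spec: RecurrenceSpectrum) -> pd.DataFrame:
    """Tidy (i, A_i, S_i) export including the i=0 row."""
    imax = max([0, *spec.A.keys(), *spec.S.keys()])
    rows = [{"i": 0, "A": spec.A_0, "S": spec.S_0}]
    rows += [
        {"i": i, "A": spec.A.get(i, 0), "S": spec.S.get(i, 0)} for i in range(1, imax + 1)
    ]
    return pd.DataFrame(rows)
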