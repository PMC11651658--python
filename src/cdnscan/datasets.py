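"""Packaged reference datasets.

Two small public summary tables ship with the package: the per-cancer-type
recurrence summary of the 12 TCGA cohorts with n > 300 (patient counts,
missense site numbers, exact A_1..A_5 and binned higher classes, synonymous
S_0..S_3), and the COSMIC per-hallmark driver-gene counts for all records
plus the breast and colon columns.  These let the desk-scale arithmetic of
the analysis be recomputed without any controlled-access data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .spectrum import RecurrenceSpectrum

_BINS = {"A6_9": (6, 9), "A10_19": (10, 19), "A20_plus": (20, None)}


def _read(name: str) -> pd.DataFrame:
    with resources.files("cdnscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_tcga_summary() -> pd.DataFrame:
    """Raw 12-cohort recurrence summary as a DataFrame."""
    return _read("tcga_recurrence_summary.tsv")


def load_tcga_spectra() -> list[RecurrenceSpectrum]:
    """The 12 TCGA cohort spectra as RecurrenceSpectrum objects.

    Exact A_i for i <= 5 plus binned classes; L_S is S_0 + S_1 + S_2 + S_3.
    Site-level indexes are not available for published summaries.
    """
    df = load_tcga_summary()
    specs = []
    for r in df.itertuples(index=False):
        A = {i: getattr(r, f"A{i}") for i in range(1, 6)}
        S = {1: r.S1, 2: r.S2, 3: r.S3}
        L_S = r.S0 + r.S1 + r.S2 + r.S3
        specs.append(
            RecurrenceSpectrum(
                cancer_type=r.cancer_type,
                n=int(r.n_patients),
                A={i: int(c) for i, c in A.items() if c},
                S={i: int(c) for i, c in S.items() if c},
                L_A=float(r.missense_sites),
                L_S=float(L_S),
                A_binned={_BINS[k]: int(getattr(r, k)) for k in _BINS if getattr(r, k)},
            )
        )
    return specs


def load_hallmark_counts(column: str = "breast") -> dict[str, int]:
    """COSMIC hallmark gene counts; column in {all_records, breast, colon}."""
    df = _read("cosmic_hallmark_counts.tsv")
    if column not in df.columns:
        raise ValueError(f"unknown column {column!r}")
    return {str(r.hallmark): int(getattr(r, column)) for r in df.itertuples(index=False)}
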