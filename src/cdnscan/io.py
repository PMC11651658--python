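"""Reading, validation, QC filtering and consolidation of cohort mutation tables.

A cohort is held as a :class:`pandas.DataFrame` with one row per mutation per
patient (columns in :data:`COLUMNS`).  Two dialects are read: ``simple_tsv``
(columns named as in :data:`COLUMNS`) and ``maf`` (standard MAF column names).
Coordinates are 1-based and fully closed, matching MAF; all alleles are on the
+ genomic strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

#: canonical column order of a mutation table
COLUMNS = [
    "patient_id",
    "cancer_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "pop_freq",
    "pipeline_count",
    "sample_id",
    "donor_age",
]

REQUIRED = ["patient_id", "chrom", "pos", "ref", "alt"]

_MAF_MAP = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Tumor_Sample_Barcode": "sample_id",
    "patient_id": "patient_id",
    "cancer_type": "cancer_type",
    "gnomAD_AF": "pop_freq",
    "pop_freq": "pop_freq",
    "pipeline_count": "pipeline_count",
    "donor_age": "donor_age",
}

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input table does not conform to its declared dialect."""


@dataclass
class QCConfig:
    """Thresholds for cohort quality control.

    max_pop_freq
        Population allele-frequency ceiling; records with a known frequency
        strictly above it are removed as likely germline (default 1 per mille).
    min_pipelines
        Minimum number of concordant calling pipelines; records with a known
        count below it are removed.  Missing counts pass.
    max_coding_mutations
        Patients with strictly more coding point mutations are removed
        entirely as hypermutators.
    max_donor_age
        Donors strictly older are removed, applied only when ages are present.
    """

    max_pop_freq: float = 0.001
    min_pipelines: int = 2
    max_coding_mutations: int = 3000
    max_donor_age: float = 80.0

    def __post_init__(self) -> None:
        for name in ("max_pop_freq", "min_pipelines", "max_coding_mutations", "max_donor_age"):
            if getattr(self, name) < 0:
                raise ValueError(f"QCConfig.{name} must be non-negative")


@dataclass
class FilterReport:
    records_in: int = 0
    records_out: int = 0
    records_removed_per_rule: dict = field(default_factory=dict)
    patients_removed: list = field(default_factory=list)

    def validate(self) -> None:
        removed = sum(self.records_removed_per_rule.values())
        if self.records_in != self.records_out + removed:
            raise AssertionError("filter report does not reconcile")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})


def _normalise(df: pd.DataFrame, path: str) -> tuple[pd.DataFrame, int]:
    """Coerce dtypes, validate rows, drop non-SNV rows. Returns (table, n_dropped)."""
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    try:
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype("int64")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable coordinate in column 'pos': {exc}") from exc
    for col in ("pop_freq", "donor_age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pipeline_count"] = pd.to_numeric(df["pipeline_count"], errors="coerce").astype("Int64")
    if (df["pos"] < 1).any():
        bad = int(df.index[df["pos"] < 1][0]) + 2
        raise FormatError(f"{path}: non-positive coordinate at line {bad}")
    snv = (
        df["ref"].isin(_BASES)
        & df["alt"].isin(_BASES)
        & (df["ref"] != df["alt"])
    )
    dropped = int((~snv).sum())
    return df[snv].reset_index(drop=True), dropped


def read_mutation_table(path: str | Path, dialect: str = "simple_tsv") -> pd.DataFrame:
    """Read a cohort mutation table.

    ``dialect="maf"`` maps standard MAF column names onto the canonical
    schema; a missing ``patient_id`` column is derived from the first three
    dash-separated fields of ``Tumor_Sample_Barcode`` (TCGA convention).
    Non-SNV rows (indels, multi-base substitutions) are dropped; the count is
    available as ``table.attrs["n_non_snv"]``.
    """
    path = Path(path)
    if dialect not in ("maf", "simple_tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=object, comment="#")
    if dialect == "maf":
        df = df.rename(columns={k: v for k, v in _MAF_MAP.items() if k in df.columns})
        if "patient_id" not in df.columns and "sample_id" in df.columns:
            df["patient_id"] = df["sample_id"].astype(str).str.split("-").str[:3].str.join("-")
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        out = _empty_table()
        out.attrs["n_non_snv"] = 0
        return out
    out, dropped = _normalise(df, str(path))
    out.attrs["n_non_snv"] = dropped
    return out


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> None:
    table[COLUMNS].to_csv(path, sep="\t", index=False)


def apply_qc_filters(table: pd.DataFrame, cfg: QCConfig | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cohort QC filters; total (never raises on data).

    Order: germline frequency, pipeline concordance, hypermutator patients
    (counted on coding point mutations after the first two filters, before
    consolidation), donor age.  Idempotent.
    """
    cfg = cfg or QCConfig()
    report = FilterReport(records_in=len(table))
    df = table

    keep = ~(df["pop_freq"] > cfg.max_pop_freq)  # NaN compares False -> kept
    report.records_removed_per_rule["pop_freq"] = int((~keep).sum())
    df = df[keep]

    keep = ~(df["pipeline_count"] < cfg.min_pipelines)
    keep = keep.fillna(True)
    report.records_removed_per_rule["pipeline_concordance"] = int((~keep).sum())
    df = df[keep]

    per_patient = df.groupby("patient_id").size()
    hyper = set(per_patient.index[per_patient > cfg.max_coding_mutations])
    keep = ~df["patient_id"].isin(hyper)
    report.records_removed_per_rule["hypermutator"] = int((~keep).sum())
    report.patients_removed += [{"patient_id": p, "reason": "hypermutator"} for p in sorted(hyper)]
    df = df[keep]

    keep = ~(df["donor_age"] > cfg.max_donor_age)
    report.records_removed_per_rule["donor_age"] = int((~keep).sum())
    old = set(df.loc[~keep, "patient_id"])
    report.patients_removed += [{"patient_id": p, "reason": "donor_age"} for p in sorted(old)]
    df = df[keep]

    report.records_out = len(df)
    report.validate()
    out = df.reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out, report


def consolidate_patients(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (patient, chrom, pos, alt) records from multiple samples.

    Distinct alts at the same position are kept as distinct site-alleles.
    """
    out = table.drop_duplicates(subset=["patient_id", "chrom", "pos", "alt"], keep="first")
    out = out.reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out
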