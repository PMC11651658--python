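"""CDN calling and CDN-gene summaries.

A CDN (cancer-driving nucleotide) is a missense site-allele whose recurrence
i reaches the threshold i* at which neutral recurrence is improbable.  Genes
harboring at least one CDN ("CDN genes") split into type I (whole-gene
Ka/Ks significantly above 1 in an external per-gene selection scan: w > 1
and q-value < 0.1) and type II (everything else).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .coding import MISSENSE, SYNONYMOUS, CDSModel, count_sites
from .spectrum import RecurrenceSpectrum


@dataclass(frozen=True)
class CDN:
    gene: str
    site_key: str
    cancer_type: str
    i: int
    aa_ref: str
    aa_alt: str
    patients: tuple = ()
    delta_u: float | None = None


@dataclass(frozen=True)
class GeneSelectionRecord:
    """One row of an external per-gene selection table (e.g. a dndscv run)."""

    gene: str
    w: float
    q_value: float

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError(f"{self.gene}: w must be >= 0")
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"{self.gene}: q_value must be in [0, 1]")


@dataclass
class GeneSummary:
    gene: str
    cdn_count: int
    patients_with_cdn: int
    type: str  # "I" | "II"
    in_canonical_list: bool = False


def call_cdns(spec: RecurrenceSpectrum, threshold: int) -> list[CDN]:
    """All missense site-alleles with recurrence >= threshold.

    Sorted by descending i, then lexicographically on site key.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if spec.site_index is None or spec.site_index.empty:
        return []
    hits = spec.site_index[
        (spec.site_index["consequence"] == MISSENSE) & (spec.site_index["i"] >= threshold)
    ]
    cdns = [
        CDN(
            gene=r.gene,
            site_key=r.site_key,
            cancer_type=spec.cancer_type,
            i=int(r.i),
            aa_ref=r.aa_ref,
            aa_alt=r.aa_alt,
            patients=tuple(r.patients),
        )
        for r in hits.itertuples(index=False)
    ]
    return sorted(cdns, key=lambda c: (-c.i, c.site_key))


@dataclass
class GeneAggregate:
    n_type_i: int
    n_type_ii: int
    n_cdn_genes: int
    genes_with_1_2_cdns: int
    frac_1_2: float
    canonical_overlap_pct: dict = field(default_factory=dict)


def summarize_cdn_genes(
    cdns: list[CDN],
    table: pd.DataFrame,
    selection: list[GeneSelectionRecord] | None = None,
    canonical: set[str] | None = None,
) -> tuple[list[GeneSummary], GeneAggregate]:
    """Aggregate CDNs per gene and classify genes as type I or II.

    With an empty selection table every CDN gene is type II (a warning is
    emitted).  ``canonical`` is a set of canonical driver-gene symbols for
    overlap reporting; comparison across cancer types is the caller's concern.
    """
    table_genes = set(table["gene"].dropna()) if len(table) else set()
    for c in cdns:
        if c.gene not in table_genes:
            raise ValueError(f"CDN gene {c.gene} absent from the annotated table")
    selection = selection or []
    if not selection and cdns:
        warnings.warn("empty selection table: all CDN genes classified as type II")
    sig = {r.gene for r in selection if r.w > 1 and r.q_value < 0.1}
    canonical = canonical or set()

    per_gene: dict[str, list[CDN]] = {}
    for c in cdns:
        per_gene.setdefault(c.gene, []).append(c)
    summaries = []
    for gene in sorted(per_gene):
        members = per_gene[gene]
        patients = set().union(*(set(c.patients) for c in members))
        summaries.append(
            GeneSummary(
                gene=gene,
                cdn_count=len(members),
                patients_with_cdn=len(patients),
                type="I" if gene in sig else "II",
                in_canonical_list=gene in canonical,
            )
        )
    n1 = sum(1 for s in summaries if s.type == "I")
    n2 = len(summaries) - n1
    few = sum(1 for s in summaries if s.cdn_count <= 2)
    overlap = {}
    for t in ("I", "II"):
        group = [s for s in summaries if s.type == t]
        overlap[t] = (
            100 * sum(s.in_canonical_list for s in group) / len(group) if group else float("nan")
        )
    agg = GeneAggregate(
        n_type_i=n1,
        n_type_ii=n2,
        n_cdn_genes=len(summaries),
        genes_with_1_2_cdns=few,
        frac_1_2=few / len(summaries) if summaries else float("nan"),
        canonical_overlap_pct=overlap,
    )
    return summaries, agg


def naive_selection_table(annotated: pd.DataFrame, model: CDSModel) -> list[GeneSelectionRecord]:
    """Naive per-gene binomial A/S selection test.

    NOT equivalent to dndscv: no covariates, no trinucleotide mutation-rate
    model.  For each gene, tests whether the missense share of its coding
    mutations exceeds the share expected from the gene's missense/synonymous
    site ratio; w is the ratio of per-site missense to per-site synonymous
    rates, q-values are Benjamini-Hochberg adjusted.  Intended only for fully
    offline runs when no external selection scan is available.
    """
    records = []
    pvals = []
    coding = annotated[annotated["consequence"].isin([MISSENSE, SYNONYMOUS])]
    for g in model.genes:
        sub_model = CDSModel(genes=[g], code=model.code)
        counts = count_sites(sub_model)
        sub = coding[coding["gene"] == g.gene]
        a = int((sub["consequence"] == MISSENSE).sum())
        s = int((sub["consequence"] == SYNONYMOUS).sum())
        if a + s == 0 or counts.L_S == 0:
            continue
        p_a = counts.L_A / (counts.L_A + counts.L_S)
        pval = binomtest(a, a + s, p_a, alternative="greater").pvalue
        w = (a / counts.L_A) / (s / counts.L_S) if s else float("inf")
        records.append((g.gene, w))
        pvals.append(pval)
    if pvals:
        qvals = multipletests(np.asarray(pvals), method="fdr_bh")[1]
    else:
        qvals = []
    return [
        GeneSelectionRecord(gene, min(w, 1e9), float(q))
        for (gene, w), q in zip(records, qvals)
    ]


def cdns_to_frame(cdns: list[CDN]) -> pd.DataFrame:
    cols = ["gene", "site_key", "cancer_type", "i", "aa_ref", "aa_alt", "delta_u"]
    return pd.DataFrame([{c: getattr(x, c) for c in cols} for x in cdns], columns=cols)
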