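"""Cross-cancer sharing of site-alleles: i_max, NC, and CDN sharing classes.

For every mutated site-allele across a set of cohorts, i_max is its largest
recurrence in any cancer type and NC the number of cancer types where it is
observed at all (i > 0).  A site is a multi-type CDN when its recurrence
reaches the calling threshold in two or more cancer types, a single-type CDN
when in exactly one, and a non-CDN otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .coding import MISSENSE
from .spectrum import RecurrenceSpectrum

NON_CDN = "non_cdn"
SINGLE = "single_type_cdn"
MULTI = "multi_type_cdn"


def build_site_matrix(specs: list[RecurrenceSpectrum]) -> pd.DataFrame:
    """Union site-allele x cancer-type recurrence matrix (0 = unobserved).

    Rows are missense site-alleles; the gene symbol is carried in a ``gene``
    column.  Spectra must come from the same CDS model: a site key mapping to
    different genes across spectra raises.
    """
    if len(specs) < 2:
        raise ValueError("need at least two spectra to build a sharing matrix")
    frames = []
    gene_of: dict[str, str] = {}
    for s in specs:
        if s.site_index is None:
            raise ValueError(f"spectrum {s.cancer_type!r} carries no site index")
        sub = s.site_index[s.site_index["consequence"] == MISSENSE]
        for r in sub.itertuples(index=False):
            if gene_of.setdefault(r.site_key, r.gene) != r.gene:
                raise ValueError(f"site {r.site_key} maps to different genes across spectra")
        frames.append(
            pd.DataFrame(
                {"site_key": sub["site_key"], "cancer_type": s.cancer_type, "i": sub["i"]}
            )
        )
    long = pd.concat(frames, ignore_index=True)
    matrix = (
        long.set_index(["site_key", "cancer_type"])["i"]
        .astype(float)
        .unstack(fill_value=0.0)
        .astype(int)
    )
    # preserve input cohort order and include cohorts with no missense hits
    matrix = matrix.reindex(columns=[s.cancer_type for s in specs], fill_value=0)
    matrix.insert(0, "gene", [gene_of[k] for k in matrix.index])
    return matrix


@dataclass
class SharingSummary:
    sites_per_class: dict[str, int]
    genes_per_class: dict[str, int]
    r_per_site: float | None
    r_binned_median: float | None


def sharing_stats(
    matrix: pd.DataFrame,
    thresholds: dict[str, int],
) -> tuple[pd.DataFrame, SharingSummary]:
    """Per-site sharing statistics and class summary.

    ``thresholds`` maps each cancer-type column to its i*.  Per row:
    i_max (largest recurrence over types), NC (types with i > 0), n_cdn_types
    (types at or above threshold) and the sharing class.  The summary reports
    site and gene counts per class and two labeled Pearson correlations
    between i_max and n_cdn_types — per-site over multi-type CDN rows, and
    over per-i_max medians of all CDN rows; the two constructions answer the
    same question at different granularity and neither is canonical.
    """
    types = [c for c in matrix.columns if c != "gene"]
    missing = [t for t in types if t not in thresholds]
    if missing:
        raise ValueError(f"no threshold for cancer type(s): {', '.join(missing)}")
    cells = matrix[types].to_numpy()
    thr = np.array([thresholds[t] for t in types])
    i_max = cells.max(axis=1)
    nc = (cells > 0).sum(axis=1)
    n_cdn_types = (cells >= thr).sum(axis=1)
    cls = np.where(n_cdn_types >= 2, MULTI, np.where(n_cdn_types == 1, SINGLE, NON_CDN))
    stats = pd.DataFrame(
        {
            "gene": matrix["gene"],
            "i_max": i_max,
            "NC": nc,
            "n_cdn_types": n_cdn_types,
            "sharing_class": cls,
        },
        index=matrix.index,
    )
    sites = {k: int((cls == k).sum()) for k in (NON_CDN, SINGLE, MULTI)}
    genes = {k: stats.loc[cls == k, "gene"].nunique() for k in (NON_CDN, SINGLE, MULTI)}

    def _safe_r(x, y) -> float | None:
        if len(x) < 3 or len(set(x)) < 2 or len(set(y)) < 2:
            return None
        return float(pearsonr(x, y)[0])

    multi = stats[stats["sharing_class"] == MULTI]
    r_site = _safe_r(multi["i_max"].to_numpy(), multi["n_cdn_types"].to_numpy())
    cdn_rows = stats[stats["sharing_class"] != NON_CDN]
    med = cdn_rows.groupby("i_max")["n_cdn_types"].median()
    r_binned = _safe_r(med.index.to_numpy(), med.to_numpy())
    return stats, SharingSummary(sites, genes, r_site, r_binned)
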