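"""Per-patient CDN burden vs gene-level mutation burden, and per-gene CDN
multiplicity with an independence expectation.

The CDN-level burden of a patient is the number of distinct CDN site-alleles
they carry; the gene-level burden is the number of CDN genes in which they
carry *any* nonsynonymous mutation (missense or nonsense) — a deliberately
looser notion that mirrors gene-panel diagnostics.  Gene-level burden is
therefore >= CDN-level burden for every patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import CDN
from .coding import MISSENSE, NONSENSE


@dataclass
class BurdenDistribution:
    n_0: int
    n_1: int
    n_2: int
    n_gt2: int
    n: int
    mean: float

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.n_0 / self.n, self.n_1 / self.n, self.n_2 / self.n, self.n_gt2 / self.n)


def _distribution(counts: dict[str, int], n: int, total: int) -> BurdenDistribution:
    vals = np.array(list(counts.values()), dtype=int)
    n_1 = int((vals == 1).sum())
    n_2 = int((vals == 2).sum())
    n_gt2 = int((vals > 2).sum())
    n_0 = n - n_1 - n_2 - n_gt2
    return BurdenDistribution(n_0, n_1, n_2, n_gt2, n, total / n if n else 0.0)


def burden_table(
    annotated: pd.DataFrame,
    cdns: list[CDN],
    n: int,
) -> tuple[BurdenDistribution, BurdenDistribution]:
    """Per-patient burden at CDN level and at gene level.

    Patients absent from the table count in n_0.  The CDN-gene set is taken
    from ``cdns``.
    """
    distinct = annotated["patient_id"].nunique() if len(annotated) else 0
    if n < distinct:
        raise ValueError(f"n={n} smaller than {distinct} distinct patients")

    cdn_counts: dict[str, int] = {}
    for c in cdns:
        for p in c.patients:
            cdn_counts[p] = cdn_counts.get(p, 0) + 1
    cdn_level = _distribution(cdn_counts, n, sum(cdn_counts.values()))

    cdn_genes = {c.gene for c in cdns}
    nonsyn = annotated[
        annotated["consequence"].isin([MISSENSE, NONSENSE])
        & annotated["gene"].isin(cdn_genes)
    ]
    gene_counts = (
        nonsyn.groupby("patient_id")["gene"].nunique().to_dict() if len(nonsyn) else {}
    )
    gene_level = _distribution(gene_counts, n, sum(gene_counts.values()))
    return cdn_level, gene_level


def expected_burden(
    freqs: list[float],
    conditioning: str = "none",
) -> np.ndarray:
    """Distribution of the number of independent CDNs carried by one patient.

    Exact convolution of non-identical Bernoulli indicators with carriage
    probabilities ``freqs`` (the Poisson-binomial law), returned as a pmf
    over counts 0..K.  ``conditioning="at_least_one"`` renormalizes on >= 1.
    """
    if conditioning not in ("none", "at_least_one"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    pmf = np.array([1.0])
    for f in freqs:
        if not 0 <= f <= 1:
            raise ValueError(f"carriage probability {f} outside [0, 1]")
        pmf = np.convolve(pmf, [1 - f, f])
    if conditioning == "at_least_one":
        if len(pmf) == 1:
            raise ValueError("cannot condition on >=1 with no CDNs")
        pmf[0] = 0.0
        total = pmf.sum()
        if total == 0:
            raise ValueError("P(>=1) is zero; cannot condition")
        pmf = pmf / total
    return pmf


def gene_cdn_multiplicity(
    gene: str,
    cdns: list[CDN],
    annotated: pd.DataFrame,
    n: int,
) -> tuple[dict[int, int], np.ndarray]:
    """Observed vs expected per-patient CDN multiplicity for one gene.

    Observed: histogram, over patients carrying at least one mutation in the
    gene, of the number of the gene's CDNs they carry.  Expected: the
    Poisson-binomial law with plug-in per-CDN frequencies i/n, conditioned on
    carrying at least one CDN (both the estimator and the conditioning are
    modeling choices, labeled as such).
    """
    mine = [c for c in cdns if c.gene == gene]
    if not mine:
        raise ValueError(f"gene {gene} has no CDNs")
    mutated_patients = set(annotated.loc[annotated["gene"] == gene, "patient_id"])
    per_patient: dict[str, int] = {p: 0 for p in mutated_patients}
    for c in mine:
        for p in c.patients:
            per_patient[p] = per_patient.get(p, 0) + 1
    observed: dict[int, int] = {}
    for k in per_patient.values():
        observed[k] = observed.get(k, 0) + 1
    expected = expected_burden([c.i / n for c in mine], conditioning="at_least_one")
    return observed, expected


def burden_frame(cdn_level: BurdenDistribution, gene_level: BurdenDistribution) -> pd.DataFrame:
    """Table-shaped export with paired CDN-level / gene-level columns."""
    rows = ["n_0", "n_1", "n_2", "n_gt2", "total_n", "mean"]
    def col(d: BurdenDistribution) -> list[float]:
        return [d.n_0, d.n_1, d.n_2, d.n_gt2, d.n, d.mean]
    return pd.DataFrame({"row": rows, "cdn_level": col(cdn_level), "gene_level": col(gene_level)})
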