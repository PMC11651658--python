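"""Synthetic cohorts with known neutral structure and planted driver sites.

The neutral generator targets the same recurrence law the null model fits:
with per-site Poisson hit rates exponentially mixed across sites (mean nEu
expected mutations per site in the cohort), the marginal per-site recurrence
is geometric with parameter q = nEu / (1 + nEu).  A ``homogeneous`` variant
draws Binomial(n, nEu/n) hits at every site instead.  Planted driver sites
receive additional independent per-patient hits with probability f; counts
add.  Unmutated sites are never materialized, so cohorts at realistic
genome scale stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import io as mio
from .caller import CDN
from .coding import (
    MISSENSE,
    SENSE_CODONS,
    CDSModel,
    GeneCDS,
    classify_substitution,
    site_key,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``nEu`` is the expected number of neutral mutations per site across the
    cohort (n * per-site per-patient rate); each site-allele receives nEu/3,
    so singleton densities match the fractional site-counting convention of
    the spectrum.  ``planted`` lists
    (site_key, per-patient prevalence f) driver sites, which must be missense
    site-alleles of the model.
    """

    n: int
    nEu: float
    rate_model: str = "exponential_mixed"
    planted: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0
    cancer_type: str = "synthetic"

    def __post_init__(self) -> None:
        if self.rate_model not in ("homogeneous", "exponential_mixed"):
            raise ValueError(f"unknown rate model {self.rate_model!r}")
        if not 0 <= self.nEu < 1:
            raise ValueError("nEu must be in [0, 1) (rare-mutation regime)")
        for key, f in self.planted:
            if not 0 <= f <= 1:
                raise ValueError(f"planted prevalence {f} for {key} outside [0, 1]")


@dataclass
class SyntheticTruth:
    planted: dict[str, float]
    realized: dict[str, tuple]  # mutated site_key -> patient ids
    labels: dict[str, str]  # mutated or planted site_key -> "driver" | "neutral"
    neutral_mutated: set = field(default_factory=set)


def make_cds_model(gene_count: int, lengths: int | list[int], seed: int = 0) -> CDSModel:
    """Random in-frame CDS model without internal stops, reproducible by seed.

    ``lengths`` gives codon counts (one int for all genes, or one per gene,
    each >= 2).  Genes start with ATG, alternate +/- strand, and are laid out
    end to end with 100-bp gaps on a single chromosome.
    """
    if gene_count < 0:
        raise ValueError("gene_count must be >= 0")
    if isinstance(lengths, int):
        lengths = [lengths] * gene_count
    if len(lengths) != gene_count:
        raise ValueError("one length per gene required")
    if any(l < 2 for l in lengths):
        raise ValueError("genes need at least 2 codons")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    genes = []
    start = 1
    for g in range(gene_count):
        body = "".join(rng.choice(codons, size=lengths[g] - 1))
        seq = "ATG" + body
        genes.append(
            GeneCDS(
                gene=f"G{g + 1:03d}",
                seq=seq,
                chrom="chr1",
                start=start,
                strand="+" if g % 2 == 0 else "-",
            )
        )
        start += len(seq) + 100
    return CDSModel(genes=genes)


def enumerate_site_alleles(model: CDSModel) -> pd.DataFrame:
    """All single-base site-alleles of a model with genomic coordinates.

    Columns: site_key, gene, chrom, pos, ref, alt (genomic + strand),
    consequence.  Terminal stop codons carry no rows.
    """
    rows = []
    for g in model.genes:
        for offset in range(len(g.seq)):
            ci = offset // 3
            codon = g.seq[ci * 3 : ci * 3 + 3]
            if model.code[codon] == "*":
                continue
            pos_in_codon = offset % 3 + 1
            base = g.seq[offset]
            genomic_pos = g.start + offset if g.strand == "+" else g.end - offset
            for alt in "ACGT":
                if alt == base:
                    continue
                change = classify_substitution(codon, pos_in_codon, alt, model.code)
                ref_g, alt_g = base, alt
                if g.strand == "-":
                    ref_g = ref_g.translate(_COMPLEMENT)
                    alt_g = alt_g.translate(_COMPLEMENT)
                rows.append(
                    {
                        "site_key": site_key(g.gene, offset, alt),
                        "gene": g.gene,
                        "chrom": g.chrom,
                        "pos": genomic_pos,
                        "ref": ref_g,
                        "alt": alt_g,
                        "consequence": change.consequence,
                    }
                )
    return pd.DataFrame(rows)


def _neutral_counts(m: int, n: int, nEu: float, rate_model: str, rng) -> np.ndarray:
    """Per-site neutral patient-hit counts for m sites."""
    if nEu == 0:
        return np.zeros(m, dtype=int)
    if rate_model == "exponential_mixed":
        q = nEu / (1 + nEu)
        counts = rng.geometric(1 - q, size=m) - 1
    else:
        counts = rng.binomial(n, nEu / n, size=m)
    return np.minimum(counts, n)


def simulate_cohort(cfg: SimConfig, model: CDSModel) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a synthetic cohort; returns (mutation table, ground truth).

    Byte-identical outputs for identical config and model.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = enumerate_site_alleles(model)
    site_info = sites.set_index("site_key")
    for key, _ in cfg.planted:
        if key not in site_info.index:
            raise ValueError(f"planted site {key} not in model")
        if site_info.loc[key, "consequence"] != MISSENSE:
            raise ValueError(f"planted site {key} is not a missense site-allele")

    patients = np.array([f"P{i + 1:05d}" for i in range(cfg.n)])
    carriers: dict[str, set[str]] = {}
    if cfg.n > 0 and len(sites):
        # nEu is per site; a site's rate spreads evenly over its 3 alt alleles,
        # so the singleton density S_1/L_S matches the fractional convention
        counts = _neutral_counts(len(sites), cfg.n, cfg.nEu / 3, cfg.rate_model, rng)
        for idx in np.nonzero(counts)[0]:
            who = rng.choice(cfg.n, size=counts[idx], replace=False)
            carriers[sites.at[idx, "site_key"]] = set(patients[who])
    neutral_mutated = set(carriers)
    if cfg.n > 0:
        for key, f in cfg.planted:
            extra = set(patients[rng.random(cfg.n) < f])
            if extra or key in carriers:
                carriers[key] = carriers.get(key, set()) | extra

    rows = []
    for key in sorted(carriers):
        info = site_info.loc[key]
        for p in sorted(carriers[key]):
            rows.append(
                {
                    "patient_id": p,
                    "cancer_type": cfg.cancer_type,
                    "chrom": info["chrom"],
                    "pos": int(info["pos"]),
                    "ref": info["ref"],
                    "alt": info["alt"],
                    "gene": info["gene"],
                    "pop_freq": np.nan,
                    "pipeline_count": pd.NA,
                    "sample_id": p,
                    "donor_age": np.nan,
                }
            )
    table = pd.DataFrame(rows, columns=mio.COLUMNS)
    table = table.sort_values(["patient_id", "chrom", "pos", "alt"]).reset_index(drop=True)

    planted_keys = {k for k, _ in cfg.planted}
    labels = {k: ("driver" if k in planted_keys else "neutral") for k in carriers}
    for k in planted_keys:
        labels.setdefault(k, "driver")
    truth = SyntheticTruth(
        planted=dict(cfg.planted),
        realized={k: tuple(sorted(v)) for k, v in sorted(carriers.items())},
        labels=labels,
        neutral_mutated=neutral_mutated,
    )
    return table, truth


def simulate_recurrence_counts(
    L: int,
    nEu: float,
    n: int,
    rate_model: str = "exponential_mixed",
    rng: np.random.Generator | None = None,
) -> dict[int, int]:
    """Sparse spectrum-level simulation: recurrence tallies over L neutral sites.

    Only mutated sites are drawn: the number of sites with at least one hit
    is Binomial(L, P(X>=1)), then each mutated site's count comes from the
    law conditioned on >= 1 (memoryless for the geometric; truncated-binomial
    inverse-CDF for the homogeneous model).  Exact marginals at any L.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if nEu == 0 or L == 0:
        return {}
    if rate_model == "exponential_mixed":
        q = nEu / (1 + nEu)
        m = rng.binomial(L, q)
        counts = rng.geometric(1 - q, size=m)  # geometric conditioned on >=1
    elif rate_model == "homogeneous":
        u = nEu / n
        p0 = (1 - u) ** n
        m = rng.binomial(L, 1 - p0)
        counts = binom.ppf(rng.uniform(p0, 1, size=m), n, u).astype(int)
    else:
        raise ValueError(f"unknown rate model {rate_model!r}")
    counts = np.minimum(counts, n)
    vals, freq = np.unique(counts, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, freq) if v > 0}


def evaluate_calls(calls: list[CDN], truth: SyntheticTruth) -> tuple[float | None, float, int]:
    """(precision, recall, false-positive count) of calls against truth.

    Precision is None (reported missing) when nothing was called; recall is
    over planted sites.
    """
    called = {c.site_key for c in calls}
    planted = set(truth.planted)
    tp = len(called & planted)
    fp = len(called - planted)
    precision = tp / len(called) if called else None
    recall = tp / len(planted) if planted else float("nan")
    return precision, recall, fp
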