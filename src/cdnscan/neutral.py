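"""Neutral recurrence null: calibration from synonymous singletons, expected
per-recurrence counts, excess tables, and the CDN threshold i*.

Under neutrality the per-site recurrence count follows a geometric law,

    P(X = i) = q^i (1 - q),        q = n E(u) / (1 + n E(u)),

which arises from Poisson hits whose per-site rate is exponentially mixed
across sites.  The parameter is calibrated from the synonymous spectrum as
q = S_1 / L_S (singleton density), so the expected number of missense sites
with recurrence exactly i is L_A q^i (1 - q) and the tail expectation is
E[A_{>=i}] = L_A q^i.  The CDN threshold i* is the smallest i whose neutral
tail expectation falls strictly below one site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .spectrum import RecurrenceSpectrum


@dataclass
class NeutralFit:
    """Calibrated neutral parameters for one cohort.

    Two rate summaries are deliberately kept distinct: ``q`` (= S_1/L_S)
    drives the geometric expectations, while ``nEu_total`` (= sum i*S_i / L_S)
    is the total expected neutral mutations per site; the two differ at
    O(q^2) plus any non-neutral weight in the heavier synonymous classes.
    """

    n: int
    q: float
    nEu_total: float
    Eu: float
    L_A: float
    L_S: float


def estimate_rates(spec: RecurrenceSpectrum) -> NeutralFit:
    """Calibrate the neutral null from the synonymous spectrum.

    q = S_1/L_S; nEu_total = sum(i*S_i)/L_S; the per-site per-patient rate
    E(u) solves S_1 = L_S * n * E(u) * exp(-(n-1) E(u)) (the expected number
    of singleton sites under homogeneous Binomial(n, E(u)) hits), taking the
    smaller root (n*E(u) < 1) by bracketed root-finding.
    """
    if spec.L_S <= 0:
        raise ValueError("L_S must be positive")
    n = spec.n
    S1 = spec.S.get(1, 0)
    q = S1 / spec.L_S
    if not 0 <= q < 1:
        raise ValueError(f"q = {q} outside [0, 1)")
    nEu_total = sum(i * c for i, c in spec.S.items()) / spec.L_S
    if S1 == 0:
        return NeutralFit(n, 0.0, nEu_total, 0.0, spec.L_A, spec.L_S)
    if n < 2:
        # e^{-(n-1)Eu} = 1: linear in Eu
        return NeutralFit(n, q, nEu_total, q / max(n, 1), spec.L_A, spec.L_S)

    def f(eu: float) -> float:
        return n * eu * math.exp(-(n - 1) * eu) - S1 / spec.L_S

    peak = 1.0 / (n - 1)  # maximiser of n*eu*exp(-(n-1)eu)
    if f(peak) < 0:
        raise ValueError("singleton density too high for neutral model")
    eu = brentq(f, 0.0, peak, rtol=1e-12)
    return NeutralFit(n, q, nEu_total, eu, spec.L_A, spec.L_S)


def expected_counts(L_A: float, q: float, i_max: int) -> pd.DataFrame:
    """Expected neutral counts per recurrence class i = 0..i_max.

    Columns: i, expected (= L_A q^i (1-q)), tail (E[A_{>=i}] = L_A q^i) and
    cum_F (= 1 - q^{i+1}, the per-site CDF).
    """
    if not 0 <= q < 1:
        raise ValueError(f"q = {q} outside [0, 1)")
    if i_max < 1:
        raise ValueError("i_max must be >= 1")
    rows = [
        {
            "i": i,
            "expected": L_A * q**i * (1 - q),
            "tail": L_A * q**i,
            "cum_F": 1 - q ** (i + 1),
        }
        for i in range(i_max + 1)
    ]
    return pd.DataFrame(rows)


def compute_istar(L_A: float, q: float) -> int:
    """Smallest recurrence i >= 1 with E[A_{>=i}] = L_A q^i strictly below 1.

    Strict inequality: a tail expectation of exactly 1 pushes i* up by one.
    Returns 1 when q = 0.
    """
    if not 0 <= q < 1:
        raise ValueError(f"q = {q} outside [0, 1)")
    if L_A <= 0:
        raise ValueError("L_A must be positive")
    if q == 0:
        return 1
    i = 1
    while L_A * q**i >= 1:
        i += 1
    return i


def excess_table(observed: dict[int, float], expected: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected counts per recurrence class.

    ``excess = observed - expected``; ``ratio_pct = 100 * excess / observed``
    is the proportion of observed sites in excess of the neutral expectation
    (the putative driver fraction), NaN when nothing is observed.
    """
    exp = dict(zip(expected["i"], expected["expected"]))
    rows = []
    for i in sorted(observed):
        if observed[i] < 0:
            raise ValueError(f"negative observed count at i={i}")
        o, e = observed[i], exp.get(i)
        if e is None:
            raise ValueError(f"no expected count for i={i}")
        excess = o - e
        rows.append(
            {
                "i": i,
                "observed": o,
                "expected": e,
                "excess": excess,
                "ratio_pct": 100 * excess / o if o else math.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_and_expect(spec: RecurrenceSpectrum, i_max: int | None = None) -> tuple[NeutralFit, pd.DataFrame, int]:
    """Convenience: calibrate, tabulate expectations, and compute i*."""
    fit = estimate_rates(spec)
    if i_max is None:
        i_max = max([4, *spec.A.keys()])
    table = expected_counts(spec.L_A, fit.q, i_max)
    return fit, table, compute_istar(spec.L_A, fit.q) if fit.q > 0 else 1
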