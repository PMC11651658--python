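"""Neutral-null calibration, expected counts, excess tables and i*."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdnscan.neutral import (
    compute_istar,
    estimate_rates,
    excess_table,
    expected_counts,
)
from cdnscan.simulate import simulate_recurrence_counts
from cdnscan.spectrum import RecurrenceSpectrum


def test_breast_rate_estimates(tcga_spectra):
    fit = estimate_rates(tcga_spectra["breast"])
    assert float(f"{fit.nEu_total:.3g}") == 1.79e-3
    assert fit.q == pytest.approx(16732 / 9405214, rel=1e-12)


def test_eu_solves_singleton_equation(tcga_spectra):
    spec = tcga_spectra["breast"]
    fit = estimate_rates(spec)
    lhs = spec.L_S * fit.n * fit.Eu * math.exp(-(fit.n - 1) * fit.Eu)
    assert lhs == pytest.approx(spec.S[1], rel=1e-9)
    assert fit.n * fit.Eu < 1  # smaller root chosen


def test_no_singletons_degenerates_to_zero():
    spec = RecurrenceSpectrum("t", 100, {}, {2: 5, 3: 1}, L_A=1000, L_S=500)
    fit = estimate_rates(spec)
    assert fit.q == 0 and fit.Eu == 0
    assert fit.nEu_total == pytest.approx((2 * 5 + 3 * 1) / 500)


def test_singleton_density_too_high_raises():
    # S_1/L_S above the attainable maximum n/(n-1)e^{-1}
    spec = RecurrenceSpectrum("t", 100, {}, {1: 450}, L_A=1000, L_S=1000)
    with pytest.raises(ValueError, match="singleton density"):
        estimate_rates(spec)


def test_expected_counts_closed_form():
    table = expected_counts(1000, 0.1, 3).set_index("i")
    assert table.loc[1, "expected"] == pytest.approx(90)
    assert table.loc[2, "expected"] == pytest.approx(9)
    assert table.loc[3, "tail"] == pytest.approx(1)


def test_expected_counts_match_published_tables(tcga_spectra):
    for cancer, i, printed in [("breast", 1, 38586), ("colon", 2, 280), ("lung", 4, 0.13593)]:
        spec = tcga_spectra[cancer]
        fit = estimate_rates(spec)
        table = expected_counts(spec.L_A, fit.q, 4).set_index("i")
        assert table.loc[i, "expected"] == pytest.approx(printed, rel=0.01)


def test_expected_counts_rejects_bad_q():
    with pytest.raises(ValueError):
        expected_counts(1000, 1.0, 3)
    with pytest.raises(ValueError):
        expected_counts(1000, -0.1, 3)


def test_istar_published_parameters(tcga_spectra):
    for cancer, expected in [("breast", 3), ("lung", 4)]:
        spec = tcga_spectra[cancer]
        fit = estimate_rates(spec)
        assert compute_istar(spec.L_A, fit.q) == expected


def test_istar_strict_inequality_edge():
    # 1000 * 0.1^3 = 1 exactly: not < 1, so the threshold moves to 4
    assert compute_istar(1000, 0.1) == 4
    assert compute_istar(999, 0.1) == 3


def test_istar_q_zero():
    assert compute_istar(1000, 0.0) == 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.floats(1e-5, 0.5),
    st.floats(1e-5, 0.5),
    st.floats(1e3, 1e8),
)
def test_istar_monotone_in_q_and_LA(q1, q2, L_A):
    lo, hi = sorted([q1, q2])
    assert compute_istar(L_A, lo) <= compute_istar(L_A, hi)
    assert compute_istar(L_A, q1) <= compute_istar(L_A * 10, q1)


def test_geometric_normalization_and_tail_consistency():
    q, L_A = 0.01, 1e6
    table = expected_counts(L_A, q, 50)
    assert table["expected"].sum() == pytest.approx(L_A, rel=1e-6)
    # tail at i equals sum of expected classes j >= i
    for i in (1, 3, 10):
        tail = table.loc[table["i"] >= i, "expected"].sum() + L_A * q ** 51
        assert table.loc[table["i"] == i, "tail"].iloc[0] == pytest.approx(tail, rel=1e-9)


def test_excess_table_published_lung(tcga_spectra):
    spec = tcga_spectra["lung"]
    fit = estimate_rates(spec)
    exp = expected_counts(spec.L_A, fit.q, 4)
    table = excess_table({i: spec.A.get(i, 0) for i in range(1, 5)}, exp).set_index("i")
    assert table.loc[4, "ratio_pct"] == pytest.approx(99.41, abs=0.01)


@pytest.mark.parametrize(
    "observed,expected_val,excess,ratio",
    [(10, 2.5, 7.5, 75.0), (5, 5.0, 0.0, 0.0)],
)
def test_excess_arithmetic(observed, expected_val, excess, ratio):
    exp = expected_counts(expected_val / 0.9, 0.0, 1)  # unused shape
    exp.loc[exp["i"] == 1, "expected"] = expected_val
    table = excess_table({1: observed}, exp).set_index("i")
    assert table.loc[1, "excess"] == pytest.approx(excess)
    assert table.loc[1, "ratio_pct"] == pytest.approx(ratio)


def test_excess_zero_observed_is_missing():
    exp = expected_counts(100, 0.1, 2)
    table = excess_table({1: 0}, exp)
    assert np.isnan(table["ratio_pct"].iloc[0])


def test_round_trip_recovers_geometric_parameter():
    """estimate_rates on simulated neutral spectra recovers the singleton mass.

    q_hat = S_1/L_S has exact expectation q(1-q) under the geometric law;
    the mean over replicates must sit within 3 SE of it.
    """
    nEu, L_S, n, reps = 2.6e-3, 2_000_000, 600, 20
    q = nEu / (1 + nEu)
    rng = np.random.default_rng(7)
    qhats = []
    for _ in range(reps):
        S = simulate_recurrence_counts(L_S, nEu, n, "exponential_mixed", rng)
        spec = RecurrenceSpectrum("sim", n, {}, S, L_A=1.0, L_S=L_S)
        qhats.append(estimate_rates(spec).q)
    target = q * (1 - q)
    se_one = math.sqrt(target * (1 - target) / L_S)
    se_mean = se_one / math.sqrt(reps)
    assert abs(np.mean(qhats) - target) < 3 * se_mean
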