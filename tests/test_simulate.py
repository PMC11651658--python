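"""Synthetic-cohort generator: determinism, calibration, planted drivers."""

import numpy as np
import pytest

from cdnscan.coding import annotate_mutations, count_sites
from cdnscan.neutral import estimate_rates
from cdnscan.simulate import (
    SimConfig,
    enumerate_site_alleles,
    evaluate_calls,
    make_cds_model,
    simulate_cohort,
    simulate_recurrence_counts,
    SyntheticTruth,
)
from cdnscan.spectrum import tally_spectrum
from cdnscan.caller import CDN, call_cdns


def test_make_cds_model_deterministic_and_valid():
    m1 = make_cds_model(3, 100, seed=7)
    m2 = make_cds_model(3, 100, seed=7)
    assert [g.seq for g in m1.genes] == [g.seq for g in m2.genes]
    assert m1.validate() == []  # no internal stops
    assert make_cds_model(3, 100, seed=8).genes[0].seq != m1.genes[0].seq


def test_make_cds_model_empty_is_valid():
    model = make_cds_model(0, [])
    assert model.genes == [] and model.validate() == []


def test_make_cds_model_rejects_bad_lengths():
    with pytest.raises(ValueError):
        make_cds_model(1, 1)
    with pytest.raises(ValueError):
        make_cds_model(2, [10])


def test_simulate_cohort_deterministic():
    model = make_cds_model(4, 50, seed=1)
    cfg = SimConfig(n=100, nEu=0.02, seed=42)
    t1, truth1 = simulate_cohort(cfg, model)
    t2, truth2 = simulate_cohort(cfg, model)
    assert t1.equals(t2)
    assert truth1.realized == truth2.realized


def test_simulate_empty_cohort():
    model = make_cds_model(2, 20, seed=1)
    table, truth = simulate_cohort(SimConfig(n=0, nEu=0.01), model)
    assert len(table) == 0 and truth.realized == {}


def test_planted_site_must_be_missense():
    model = make_cds_model(2, 50, seed=2)
    sites = enumerate_site_alleles(model)
    syn = sites[sites.consequence == "synonymous"].site_key.iloc[0]
    with pytest.raises(ValueError, match="missense"):
        simulate_cohort(SimConfig(n=10, nEu=0.01, planted=[(syn, 0.1)]), model)
    with pytest.raises(ValueError, match="not in model"):
        simulate_cohort(SimConfig(n=10, nEu=0.01, planted=[("nope:0:A", 0.1)]), model)


def test_planted_site_reaches_expected_recurrence_and_is_called():
    model = make_cds_model(8, 120, seed=3)
    sites = enumerate_site_alleles(model)
    key = sites[sites.consequence == "missense"].site_key.iloc[10]
    n, f = 500, 0.05
    cfg = SimConfig(n=n, nEu=1e-4, planted=[(key, f)], seed=17)
    table, truth = simulate_cohort(cfg, model)
    i_obs = len(truth.realized[key])
    # Binomial(n, f): mean 25, sd ~4.9
    assert abs(i_obs - n * f) < 4 * np.sqrt(n * f * (1 - f))
    annotated = annotate_mutations(table, model)
    spec = tally_spectrum(annotated, count_sites(model), n)
    cdns = call_cdns(spec, 3)
    assert key in {c.site_key for c in cdns}


def test_neutral_singletons_match_geometric_expectation():
    """A_1 over all site-alleles is within 3 SD of L*q*(1-q)."""
    L, nEu, n = 300_000, 0.003, 500
    q = nEu / (1 + nEu)
    rng = np.random.default_rng(5)
    counts = simulate_recurrence_counts(L, nEu, n, "exponential_mixed", rng)
    expected = L * q * (1 - q)
    sd = np.sqrt(L * q * (1 - q))
    assert abs(counts.get(1, 0) - expected) < 3 * sd


def test_sparse_homogeneous_matches_binomial_expectation():
    L, nEu, n = 200_000, 0.004, 400
    u = nEu / n
    rng = np.random.default_rng(6)
    counts = simulate_recurrence_counts(L, nEu, n, "homogeneous", rng)
    p1 = n * u * (1 - u) ** (n - 1)
    expected = L * p1
    assert abs(counts.get(1, 0) - expected) < 3 * np.sqrt(L * p1 * (1 - p1))
    assert 0 not in counts


def test_cohort_table_round_trips_through_annotation():
    """Emitted genomic records map back to the site keys the generator drew."""
    model = make_cds_model(5, 40, seed=9)
    cfg = SimConfig(n=60, nEu=0.05, seed=13)
    table, truth = simulate_cohort(cfg, model)
    annotated = annotate_mutations(table, model)
    assert annotated.attrs["n_noncoding"] == 0
    got = set(annotated["site_key"])
    # nonsense site-alleles keep their keys too: compare against all realized
    assert got == set(truth.realized)


def test_estimate_rates_round_trip_on_cohort():
    model = make_cds_model(20, 200, seed=21)
    cfg = SimConfig(n=400, nEu=0.01, seed=23)
    table, _ = simulate_cohort(cfg, model)
    annotated = annotate_mutations(table, model)
    counts = count_sites(model)
    spec = tally_spectrum(annotated, counts, cfg.n)
    fit = estimate_rates(spec)
    # per-allele spreading makes S_1/L_S an estimator of q = nEu/(1+nEu)
    # up to O(nEu^2) terms, far below sampling error at this scale
    q = cfg.nEu / (1 + cfg.nEu)
    se = np.sqrt(q * (1 - q) / counts.L_S)
    assert abs(fit.q - q) < 3 * se


def evaluate_fixture(called_keys, planted_keys):
    calls = [
        CDN(gene="g", site_key=k, cancer_type="t", i=3, aa_ref="A", aa_alt="V")
        for k in called_keys
    ]
    truth = SyntheticTruth(
        planted={k: 0.1 for k in planted_keys},
        realized={},
        labels={},
    )
    return evaluate_calls(calls, truth)


def test_evaluate_calls_cases():
    assert evaluate_fixture(["a", "b"], ["a", "b"]) == (1.0, 1.0, 0)
    precision, recall, fp = evaluate_fixture([], ["a"])
    assert precision is None and recall == 0 and fp == 0
    precision, recall, fp = evaluate_fixture(["a", "b", "x"], ["a", "b"])
    assert precision == pytest.approx(2 / 3) and recall == 1.0 and fp == 1
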