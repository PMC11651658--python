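"""Genetic-code classification, site counting and annotation."""

import pytest
from hypothesis import given, settings, strategies as st

from cdnscan.coding import (
    CDSModel,
    GeneCDS,
    annotate_mutations,
    classify_substitution,
    count_sites,
)
from conftest import make_table


@pytest.mark.parametrize(
    "codon,pos,alt,ref_aa,alt_aa,consequence",
    [
        ("ATG", 3, "A", "M", "I", "missense"),
        ("CTG", 3, "A", "L", "L", "synonymous"),
        ("CGA", 1, "T", "R", "*", "nonsense"),
        ("TGG", 2, "A", "W", "*", "nonsense"),
        ("GCC", 1, "A", "A", "T", "missense"),
    ],
)
def test_classify_substitution(codon, pos, alt, ref_aa, alt_aa, consequence):
    change = classify_substitution(codon, pos, alt)
    assert (change.ref_aa, change.alt_aa, change.consequence) == (ref_aa, alt_aa, consequence)


@pytest.mark.parametrize(
    "codon,pos,alt",
    [
        ("TAA", 1, "C"),  # stop codon reference
        ("ATG", 1, "N"),  # invalid base
        ("ATG", 1, "A"),  # alt equals ref
        ("ATG", 4, "C"),  # bad position
    ],
)
def test_classify_substitution_rejects_bad_input(codon, pos, alt):
    with pytest.raises(ValueError):
        classify_substitution(codon, pos, alt)


@pytest.mark.parametrize(
    "codon,L_A,L_S,L_X",
    [
        ("ATG", 3.0, 0.0, 0.0),
        ("CTG", 5 / 3, 4 / 3, 0.0),
        ("TGG", 7 / 3, 0.0, 2 / 3),
    ],
)
def test_count_sites_single_codon_fractional(codon, L_A, L_S, L_X):
    model = CDSModel(genes=[GeneCDS("g", codon)])
    counts = count_sites(model)
    assert counts.L_A == pytest.approx(L_A, abs=1e-12)
    assert counts.L_S == pytest.approx(L_S, abs=1e-12)
    assert counts.L_nonsense == pytest.approx(L_X, abs=1e-12)


def test_per_allele_convention_counts_each_alt():
    model = CDSModel(genes=[GeneCDS("g", "ATG")])
    counts = count_sites(model, convention="per_allele")
    assert (counts.L_A, counts.L_S, counts.L_nonsense) == (9.0, 0.0, 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["ATG", "CTG", "TGG", "GGC", "AAA", "TCT"]), min_size=1, max_size=20))
def test_fractional_counts_sum_to_coding_positions(codons):
    model = CDSModel(genes=[GeneCDS("g", "".join(codons))])
    counts = count_sites(model)
    assert counts.L_A + counts.L_S + counts.L_nonsense == pytest.approx(
        3 * len(codons), abs=1e-9
    )


def test_annotate_plus_strand(toy_model):
    table = make_table([{"patient_id": "P1", "pos": 3, "ref": "G", "alt": "A"}])
    out = annotate_mutations(table, toy_model)
    row = out.iloc[0]
    assert row["gene"] == "gp"
    assert (row["aa_ref"], row["aa_alt"], row["consequence"]) == ("M", "I", "missense")
    assert row["site_key"] == "gp:2:A"


def test_annotate_minus_strand_complements_alleles(toy_model):
    # third coding base of gm sits at genomic 110; coding G>A is genomic C>T
    table = make_table([{"patient_id": "P1", "pos": 110, "ref": "C", "alt": "T"}])
    out = annotate_mutations(table, toy_model)
    row = out.iloc[0]
    assert row["gene"] == "gm"
    assert (row["aa_ref"], row["aa_alt"], row["consequence"]) == ("M", "I", "missense")
    assert row["site_key"] == "gm:2:A"


def test_strand_symmetry_same_site_keys(toy_model):
    """Equivalent coding changes on the two strands annotate identically."""
    plus = annotate_mutations(
        make_table([{"pos": 6, "ref": "G", "alt": "A"}]), toy_model
    ).iloc[0]
    minus = annotate_mutations(
        make_table([{"pos": 107, "ref": "C", "alt": "T"}]), toy_model
    ).iloc[0]
    assert plus["site_key"].split(":")[1:] == minus["site_key"].split(":")[1:]
    assert plus["consequence"] == minus["consequence"]


def test_annotate_empty_table(toy_model):
    out = annotate_mutations(make_table([]), toy_model)
    assert len(out) == 0
    assert "site_key" in out.columns


def test_annotate_drops_and_counts_noncoding(toy_model):
    table = make_table([{"pos": 50, "ref": "A", "alt": "C"}])
    out = annotate_mutations(table, toy_model)
    assert len(out) == 0
    assert out.attrs["n_noncoding"] == 1


def test_annotate_reference_mismatch_raises(toy_model):
    table = make_table([{"pos": 3, "ref": "T", "alt": "A"}])  # model has G at pos 3
    with pytest.raises(ValueError, match="mismatch"):
        annotate_mutations(table, toy_model)


def test_annotation_consistent_with_classify(toy_model):
    """Every annotated record agrees with direct codon classification."""
    gene = toy_model.gene("gp")
    rows = []
    for pos in range(1, 10):  # skip the terminal TGG codon region boundary
        base = gene.seq[pos - 1]
        for alt in "ACGT":
            if alt != base:
                rows.append({"pos": pos, "ref": base, "alt": alt})
    out = annotate_mutations(make_table(rows), toy_model)
    for r in out.itertuples(index=False):
        offset = int(r.site_key.split(":")[1])
        ci = offset // 3
        codon = gene.seq[ci * 3 : ci * 3 + 3]
        direct = classify_substitution(codon, offset % 3 + 1, r.site_key.split(":")[2])
        assert direct.consequence == r.consequence
        assert (direct.ref_aa, direct.alt_aa) == (r.aa_ref, r.aa_alt)


def test_model_validation():
    with pytest.raises(ValueError, match="divisible"):
        CDSModel(genes=[GeneCDS("g", "ATGC")]).validate()
    warnings = CDSModel(genes=[GeneCDS("g", "ATGTAAATG")]).validate()
    assert any("internal stop" in w for w in warnings)
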