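import pandas as pd
import pytest

from cdnscan.coding import CDSModel, GeneCDS
from cdnscan.io import COLUMNS


def make_table(rows):
    """Build a mutation table from dicts with defaults for optional columns."""
    full = []
    for r in rows:
        rec = {
            "patient_id": "P1",
            "cancer_type": "toy",
            "chrom": "chr1",
            "pos": 1,
            "ref": "A",
            "alt": "C",
            "gene": None,
            "pop_freq": None,
            "pipeline_count": None,
            "sample_id": None,
            "donor_age": None,
        }
        rec.update(r)
        full.append(rec)
    df = pd.DataFrame(full, columns=COLUMNS)
    df["pos"] = df["pos"].astype("int64")
    df["pop_freq"] = pd.to_numeric(df["pop_freq"])
    df["donor_age"] = pd.to_numeric(df["donor_age"])
    df["pipeline_count"] = pd.to_numeric(df["pipeline_count"]).astype("Int64")
    return df


@pytest.fixture
def toy_model():
    """Two genes, one per strand.

    gp (+): ATG CTG CGA TGG, genomic 1..12 on chr1.
    gm (-): same codons on the coding strand, genomic 101..112; genomic base
    at 112 is the complement of the first coding base.
    """
    seq = "ATGCTGCGATGG"
    return CDSModel(
        genes=[
            GeneCDS("gp", seq, chrom="chr1", start=1, strand="+"),
            GeneCDS("gm", seq, chrom="chr1", start=101, strand="-"),
        ]
    )


@pytest.fixture
def tcga_spectra():
    from cdnscan.datasets import load_tcga_spectra

    return {s.cancer_type: s for s in load_tcga_spectra()}
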