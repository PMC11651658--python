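"""Genetic-code machinery: substitution classification, missense/synonymous
site counting (L_A, L_S) and mutation-table annotation.

Site counting supports two conventions.  Under ``fractional`` (the default)
each coding position contributes k/3 to a class, where k of its three
alternative bases fall in that class, so L_A + L_S + L_nonsense equals the
number of coding positions.  Under ``per_allele`` every (position, alt) pair
counts as one full site in its class.  Observed recurrence is always keyed
per (position, alt): a mutation recurs only when the identical nucleotide
change recurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from collections import Counter

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"


def standard_code() -> dict[str, str]:
    """Standard genetic code as a 64-entry codon -> amino-acid map ('*' = stop)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


_STANDARD = standard_code()

SENSE_CODONS = tuple(sorted(c for c, aa in _STANDARD.items() if aa != "*"))


@dataclass(frozen=True)
class AAChange:
    ref_aa: str
    alt_aa: str
    codon_index: int  # 0-based position in protein; -1 when unknown
    consequence: str


@dataclass
class GeneCDS:
    """One gene's in-frame CDS anchored to the + genomic strand.

    ``start`` is the 1-based genomic coordinate of the lowest-coordinate base
    of the CDS; for a minus-strand gene the first coding base is therefore at
    genomic position ``start + len(seq) - 1``.
    """

    gene: str
    seq: str
    chrom: str = "chr1"
    start: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def genomic_to_offset(self, pos: int) -> int:
        """0-based CDS offset of a genomic position (strand-aware)."""
        if not self.start <= pos <= self.end:
            raise ValueError(f"position {pos} outside {self.gene}")
        return pos - self.start if self.strand == "+" else self.end - pos


@dataclass
class CDSModel:
    genes: list[GeneCDS] = field(default_factory=list)
    code: dict[str, str] = field(default_factory=standard_code)

    def validate(self) -> list[str]:
        """Return a list of validation warnings; raise on hard errors."""
        warnings: list[str] = []
        for g in self.genes:
            if len(g.seq) % 3 != 0:
                raise ValueError(f"{g.gene}: CDS length {len(g.seq)} not divisible by 3")
            if set(g.seq) - set(_BASES):
                raise ValueError(f"{g.gene}: non-ACGT base in CDS")
            codons = [g.seq[i : i + 3] for i in range(0, len(g.seq), 3)]
            if self.code.get(codons[0]) == "*":
                warnings.append(f"{g.gene}: starts with a stop codon")
            if any(self.code[c] == "*" for c in codons[:-1] if c in self.code):
                warnings.append(f"{g.gene}: internal stop codon")
        return warnings

    def gene(self, name: str) -> GeneCDS:
        for g in self.genes:
            if g.gene == name:
                return g
        raise KeyError(name)


@dataclass
class SiteCounts:
    L_A: float
    L_S: float
    L_nonsense: float
    convention: str = "fractional"


def classify_substitution(
    codon: str,
    position_in_codon: int,
    alt_base: str,
    code: dict[str, str] | None = None,
) -> AAChange:
    """Classify a single-base change of a sense codon.

    ``position_in_codon`` is 1..3.  The reference codon must be a sense codon
    and ``alt_base`` must differ from the current base at that position.
    """
    code = code or _STANDARD
    codon = codon.upper()
    alt_base = alt_base.upper()
    if codon not in code:
        raise ValueError(f"invalid codon {codon!r}")
    if code[codon] == "*":
        raise ValueError(f"reference codon {codon} is a stop codon")
    if position_in_codon not in (1, 2, 3):
        raise ValueError("position_in_codon must be 1, 2 or 3")
    if alt_base not in _BASES:
        raise ValueError(f"invalid base {alt_base!r}")
    if codon[position_in_codon - 1] == alt_base:
        raise ValueError("alt base equals the reference base")
    mutated = codon[: position_in_codon - 1] + alt_base + codon[position_in_codon:]
    ref_aa, alt_aa = code[codon], code[mutated]
    if alt_aa == "*":
        consequence = NONSENSE
    elif alt_aa == ref_aa:
        consequence = SYNONYMOUS
    else:
        consequence = MISSENSE
    return AAChange(ref_aa, alt_aa, -1, consequence)


def _codon_class_counts(code: dict[str, str]) -> dict[str, tuple[int, int, int]]:
    """Per sense codon: (#missense, #synonymous, #nonsense) over its 9 single-base alts."""
    out = {}
    for codon in code:
        if code[codon] == "*":
            continue
        tallies = [0, 0, 0]
        for pos in (1, 2, 3):
            for alt in _BASES:
                if alt == codon[pos - 1]:
                    continue
                cons = classify_substitution(codon, pos, alt, code).consequence
                tallies[(MISSENSE, SYNONYMOUS, NONSENSE).index(cons)] += 1
        out[codon] = tuple(tallies)
    return out


def count_sites(model: CDSModel, convention: str = "fractional") -> SiteCounts:
    """Count missense, synonymous and nonsense sites over a CDS model."""
    if convention not in ("fractional", "per_allele"):
        raise ValueError(f"unknown convention {convention!r}")
    model.validate()
    per_codon = _codon_class_counts(model.code)
    tally = Counter()
    for g in model.genes:
        for i in range(0, len(g.seq), 3):
            codon = g.seq[i : i + 3]
            if model.code[codon] == "*":
                continue  # terminal stop codon carries no sense sites
            a, s, x = per_codon[codon]
            tally["A"] += a
            tally["S"] += s
            tally["X"] += x
    if convention == "fractional":
        la = Fraction(tally["A"], 3)
        ls = Fraction(tally["S"], 3)
        lx = Fraction(tally["X"], 3)
        return SiteCounts(float(la), float(ls), float(lx), convention)
    return SiteCounts(float(tally["A"]), float(tally["S"]), float(tally["X"]), convention)


def site_key(gene: str, cds_offset: int, alt_coding: str) -> str:
    """Canonical identity of a site-allele: gene, 0-based CDS offset, coding-strand alt."""
    return f"{gene}:{cds_offset}:{alt_coding}"


ANNOT_COLUMNS = ["gene", "site_key", "codon_index", "aa_ref", "aa_alt", "consequence"]


def annotate_mutations(table: pd.DataFrame, model: CDSModel) -> pd.DataFrame:
    """Annotate a mutation table against a CDS model.

    Adds ``gene``, ``site_key``, ``codon_index``, ``aa_ref``, ``aa_alt`` and
    ``consequence`` columns.  Records overlapping no gene are dropped and
    counted in ``result.attrs["n_noncoding"]``.  Overlapping genes are
    resolved to the first-listed gene.  Alleles are complemented for
    minus-strand genes before codon lookup; a reference-allele mismatch with
    the model raises, as it indicates a model/table mismatch.
    """
    intervals: dict[str, list[GeneCDS]] = {}
    for g in model.genes:
        intervals.setdefault(g.chrom, []).append(g)

    rows = []
    noncoding = 0
    for rec in table.itertuples(index=False):
        hit = None
        for g in intervals.get(str(rec.chrom), []):
            if g.start <= rec.pos <= g.end:
                hit = g
                break
        if hit is None:
            noncoding += 1
            continue
        offset = hit.genomic_to_offset(int(rec.pos))
        ref_c, alt_c = rec.ref, rec.alt
        if hit.strand == "-":
            ref_c = ref_c.translate(_COMPLEMENT)
            alt_c = alt_c.translate(_COMPLEMENT)
        if hit.seq[offset] != ref_c:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{rec.pos} in {hit.gene}: "
                f"model has {hit.seq[offset]}, table has {ref_c} (coding strand)"
            )
        codon_index = offset // 3
        pos_in_codon = offset % 3 + 1
        codon = hit.seq[codon_index * 3 : codon_index * 3 + 3]
        change = classify_substitution(codon, pos_in_codon, alt_c, model.code)
        rows.append(
            dict(
                rec._asdict(),
                gene=hit.gene,
                site_key=site_key(hit.gene, offset, alt_c),
                codon_index=codon_index,
                aa_ref=change.ref_aa,
                aa_alt=change.alt_aa,
                consequence=change.consequence,
            )
        )
    cols = list(table.columns) + [c for c in ANNOT_COLUMNS if c not in table.columns]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs = dict(table.attrs)
    out.attrs["n_noncoding"] = noncoding
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_cds_model(fasta_path, anchors_path) -> CDSModel:
    """Load a CDS model from a per-gene in-frame CDS FASTA plus an anchor TSV.

    The anchor table has columns gene, chrom, start, strand; FASTA record ids
    are gene symbols and sequences are on the coding strand.
    """
    from Bio import SeqIO

    anchors = pd.read_csv(anchors_path, sep="\t")
    required = {"gene", "chrom", "start", "strand"}
    if not required <= set(anchors.columns):
        raise ValueError(f"anchor table needs columns {sorted(required)}")
    by_gene = {str(r.gene): r for r in anchors.itertuples(index=False)}
    genes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in by_gene:
            raise ValueError(f"no anchor for gene {rec.id}")
        a = by_gene[rec.id]
        genes.append(
            GeneCDS(gene=rec.id, seq=str(rec.seq), chrom=str(a.chrom), start=int(a.start), strand=str(a.strand))
        )
    model = CDSModel(genes=genes)
    model.validate()
    return model


def write_cds_model(model: CDSModel, fasta_path, anchors_path) -> None:
    """Inverse of :func:`load_cds_model`."""
    with open(fasta_path, "w") as fh:
        for g in model.genes:
            fh.write(f">{g.gene}\n{g.seq}\n")
    pd.DataFrame(
        [{"gene": g.gene, "chrom": g.chrom, "start": g.start, "strand": g.strand} for g in model.genes]
    ).to_csv(anchors_path, sep="\t", index=False)
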