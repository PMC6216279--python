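"""Genetic-code tables with stop, start, hungry-codon and anticodon semantics.

A :class:`GeneticCode` wraps an NCBI translation table (via Biopython) and
adds the two pieces of information the fidelity analysis needs beyond the
plain codon->amino-acid map:

* *hungry codons* — codons without an efficiently decoding tRNA.  In the
  vertebrate mitochondrial code (table 2) these are AGA and AGG: they are
  listed as stops in the NCBI table but are not recognised by the
  mitochondrial release factor; ribosomes stall on them.
* *primary codons* — for each amino acid, the codon(s) that form a perfect
  Watson-Crick duplex with the anticodon of the decoding tRNA.  Misreading
  statistics are computed relative to these codons (see
  :mod:`mitofidelity.near_cognate`).  The table-2 map is curated from the 22
  mitochondrially encoded tRNAs; for the standard and bacterial codes only
  the entries needed for the Cys/Met reporter analysis are provided, since
  multi-isoacceptor cytosolic tRNA sets have no single canonical choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data.CodonTable import unambiguous_dna_by_id

STOP = "*"

NUCLEOTIDES = "ACGT"

#: All 64 DNA triplets in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))

SUPPORTED_TABLES = (1, 2, 11)

# Watson-Crick codon of each human mitochondrial tRNA anticodon
# (anticodon 34-36 read 3'->5' against codon 1-3; the primary codon is the
# reverse complement of the anticodon).  Two-box amino acids read the NNY
# pair with G34 (primary NNC), NNR and four-codon boxes use U34 (primary
# NNA); tRNA-Met is the exception, its C34 pairs AUG and reads AUA only via
# base modification.
_MITO_PRIMARY_CODONS: dict[str, frozenset[str]] = {
    "A": frozenset({"GCA"}),
    "C": frozenset({"TGC"}),
    "D": frozenset({"GAC"}),
    "E": frozenset({"GAA"}),
    "F": frozenset({"TTC"}),
    "G": frozenset({"GGA"}),
    "H": frozenset({"CAC"}),
    "I": frozenset({"ATC"}),
    "K": frozenset({"AAA"}),
    "L": frozenset({"TTA", "CTA"}),  # tRNA-Leu(UUR) and tRNA-Leu(CUN)
    "M": frozenset({"ATG"}),
    "N": frozenset({"AAC"}),
    "P": frozenset({"CCA"}),
    "Q": frozenset({"CAA"}),
    "R": frozenset({"CGA"}),
    "S": frozenset({"TCA", "AGC"}),  # tRNA-Ser(UCN) and tRNA-Ser(AGY)
    "T": frozenset({"ACA"}),
    "V": frozenset({"GTA"}),
    "W": frozenset({"TGA"}),
    "Y": frozenset({"TAC"}),
}

# Cytosolic/bacterial entries needed by the reporter analysis: tRNA-Cys
# (anticodon GCA) and initiator-independent elongator tRNA-Met (anticodon
# CAU) have the same Watson-Crick codons in E. coli and human cytosol.
_STANDARD_PRIMARY_CODONS: dict[str, frozenset[str]] = {
    "C": frozenset({"TGC"}),
    "M": frozenset({"ATG"}),
}

_TABLE_NAMES = {
    1: "standard",
    2: "vertebrate mitochondrial",
    11: "bacterial",
}


@dataclass(frozen=True)
class GeneticCode:
    """A total codon->amino-acid map plus start/stop/hungry annotations.

    ``codon_to_aa`` maps all 64 DNA triplets to a one-letter amino acid or
    ``"*"`` for stop.  ``hungry_codons`` are treated as stalling terminators
    rather than efficiently decoded sense codons; they are always a subset
    of ``stop_codons``.
    """

    name: str
    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    hungry_codons: frozenset[str] = frozenset()
    primary_codons: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 DNA triplets")
        if not self.hungry_codons <= self.stop_codons:
            raise ValueError("hungry codons must be a subset of the stop set")

    def amino_acids(self) -> frozenset[str]:
        """The amino acids encoded by at least one sense codon."""
        return frozenset(a for a in self.codon_to_aa.values() if a != STOP)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_hungry(self, codon: str) -> bool:
        return codon in self.hungry_codons

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def load_genetic_code(
    table_id: int, hungry_codons: set[str] | frozenset[str] | None = None
) -> GeneticCode:
    """Load an NCBI translation table as a :class:`GeneticCode`.

    Parameters
    ----------
    table_id
        NCBI translation-table number; tables 1 (standard),
        2 (vertebrate mitochondrial) and 11 (bacterial) are supported.
    hungry_codons
        Stop codons to annotate as hungry (stalling) rather than efficiently
        terminated.  Defaults to ``{AGA, AGG}`` for table 2 and the empty
        set otherwise.

    Raises
    ------
    ValueError
        If ``table_id`` is not a supported table, or a requested hungry
        codon is not a stop codon of the table.
    """
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(
            f"unknown translation table {table_id!r}; supported: {SUPPORTED_TABLES}"
        )
    ncbi = unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: ncbi.forward_table.get(c, STOP) for c in ALL_CODONS}
    stops = frozenset(ncbi.stop_codons)
    if hungry_codons is None:
        hungry = frozenset({"AGA", "AGG"}) if table_id == 2 else frozenset()
    else:
        hungry = frozenset(hungry_codons)
        if not hungry <= stops:
            raise ValueError(
                f"hungry codons {sorted(hungry - stops)} are not stop codons of table {table_id}"
            )
    primary = dict(_MITO_PRIMARY_CODONS) if table_id == 2 else dict(_STANDARD_PRIMARY_CODONS)
    return GeneticCode(
        name=_TABLE_NAMES[table_id],
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(ncbi.start_codons),
        stop_codons=stops,
        hungry_codons=hungry,
        primary_codons=primary,
    )


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))
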