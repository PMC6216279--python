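"""Near-cognate codon neighbourhoods and cognate/near-cognate counting.

A misreading ribosome can accept a tRNA on a codon that differs from one
the tRNA decodes by a single nucleotide.  Two neighbourhood definitions
are provided:

``mode="anticodon"`` (default)
    Near-cognates are the codons one substitution away from the *primary*
    codon(s) of the amino acid — the codon(s) forming a perfect
    Watson-Crick duplex with the decoding tRNA's anticodon (e.g. TGC for
    Cys via anticodon GCA, ATG for Met via anticodon CAU) — excluding all
    cognate codons.  This is the neighbourhood relevant to misreading by a
    specific tRNA, and it is the definition under which the MT-CO1/MT-CO2
    reporter counts are computed.

``mode="union"``
    Near-cognates are the codons at minimum Hamming distance exactly 1
    from the full cognate set.  This is the coarser, purely combinatorial
    neighbourhood (14 codons for Cys under tables 1 and 2, 9 for Met under
    table 1, 14 for Met under table 2).

Both exclude cognates by construction; ``include_stop_neighbors=False``
additionally removes codons that are stops under the code.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codes import ALL_CODONS, STOP, GeneticCode, hamming
from .seqio import CodingSequence

ANTICODON = "anticodon"
UNION = "union"


@dataclass(frozen=True)
class CodonNeighborhood:
    """Cognate and near-cognate codon sets for one amino acid."""

    amino_acid: str
    code: GeneticCode
    cognate_set: frozenset[str]
    near_cognate_set: frozenset[str]
    per_codon_distance: dict[str, int]
    mode: str = ANTICODON

    def __post_init__(self) -> None:
        if self.near_cognate_set & self.cognate_set:
            raise ValueError("near-cognate and cognate sets overlap")


def cognate_set(amino_acid: str, code: GeneticCode) -> frozenset[str]:
    """The codons decoded as ``amino_acid`` under ``code``.

    Stop and hungry codons are never cognate.  Raises ``ValueError`` for
    an amino acid without codons under the table.
    """
    s = frozenset(c for c in ALL_CODONS if code.codon_to_aa[c] == amino_acid)
    if not s:
        raise ValueError(
            f"amino acid {amino_acid!r} has no codon under table {code.table_id}"
        )
    return s


def near_cognate_set(
    amino_acid: str,
    code: GeneticCode,
    include_stop_neighbors: bool = True,
    mode: str = ANTICODON,
) -> CodonNeighborhood:
    """Build the :class:`CodonNeighborhood` of an amino acid.

    In ``anticodon`` mode the neighbourhood is seeded from
    ``code.primary_codons[amino_acid]``; a ``ValueError`` is raised when
    the code carries no anticodon annotation for the amino acid (use
    ``union`` mode there).
    """
    S = cognate_set(amino_acid, code)
    if mode == UNION:
        seeds = S
    elif mode == ANTICODON:
        try:
            seeds = code.primary_codons[amino_acid]
        except KeyError:
            raise ValueError(
                f"no primary (anticodon) codon known for {amino_acid!r} under "
                f"table {code.table_id}; use mode='union'"
            ) from None
        if not seeds <= S:
            raise ValueError(
                f"primary codons {sorted(seeds - S)} of {amino_acid!r} are not "
                f"cognate under table {code.table_id}"
            )
    else:
        raise ValueError(f"unknown neighbourhood mode {mode!r}")

    dist = {c: min(hamming(c, x) for x in S) for c in ALL_CODONS}
    near = frozenset(
        c
        for c in ALL_CODONS
        if c not in S and min(hamming(c, x) for x in seeds) == 1
    )
    if not include_stop_neighbors:
        near = frozenset(c for c in near if code.codon_to_aa[c] != STOP)
    return CodonNeighborhood(
        amino_acid=amino_acid,
        code=code,
        cognate_set=S,
        near_cognate_set=near,
        per_codon_distance=dist,
        mode=mode,
    )


def count_codons(
    cds: CodingSequence,
    neighborhood: CodonNeighborhood,
    include_terminal: bool = False,
) -> tuple[int, int]:
    """Count cognate and near-cognate occurrences in a CDS.

    Counting runs over the sense codons of the body; the terminal
    stop/hungry codon is excluded unless ``include_terminal`` is set (it
    is not decoded as a sense codon).  Returns ``(C_A, NC_A)``.
    """
    if cds.code.table_id != neighborhood.code.table_id:
        raise ValueError(
            f"CDS {cds.gene_id} (table {cds.code.table_id}) and neighbourhood "
            f"(table {neighborhood.code.table_id}) use different codes"
        )
    codons = list(cds.codons)
    if include_terminal and len(cds.terminal_codon) == 3:
        codons.append(cds.terminal_codon)
    S, N = neighborhood.cognate_set, neighborhood.near_cognate_set
    return sum(c in S for c in codons), sum(c in N for c in codons)
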