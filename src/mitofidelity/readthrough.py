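"""Stop-codon context analysis and read-through product prediction.

Human MT-CO1 does not end in a release-factor stop: its terminal codon is
the hungry AGA, on which the mitoribosome slips one nucleotide backwards
(-1) so that a UAG exposed underneath the A site can be recognised.  A
misreading ribosome that decodes the terminus as a sense codon instead
continues into the 3' UTR and, on a polyadenylated message, translates the
polyA tail into a C-terminal poly-lysine stretch.  This module predicts
the geometry (which frames of the UTR contain stops, whether the -1 shift
exposes one at the terminus) and the resulting extended protein with its
molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight as _biopython_mw

from .codes import GeneticCode
from .seqio import CodingSequence, translate

AVERAGE = "average"
MONOISOTOPIC = "monoisotopic"

_WATER = {AVERAGE: 18.0153, MONOISOTOPIC: 18.010565}
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

STOP_IN_UTR = "stop-in-UTR"
END_OF_MESSAGE = "end-of-message"
STOP_AT_TERMINUS = "stop-at-terminus"

DECODE_AS_SENSE = "decode-as-sense"
SKIP = "skip"


@dataclass(frozen=True)
class StopContext:
    """Stop-codon landscape downstream of a CDS.

    ``frame_stops`` maps frame offsets 0 (continuation of the reading
    frame), -1 (one nt toward 5') and +1 (one nt toward 3') to the 0-based
    nt positions, relative to the first UTR nucleotide, at which a stop
    triplet starts.  ``minus1_stop_at_terminus`` records whether shifting
    -1 at the terminal codon itself exposes a stop (the MT-CO1 UAG).
    """

    gene_id: str
    terminal_codon: str
    terminal_hungry: bool
    frame_stops: dict[int, tuple[int, ...]]
    minus1_stop_at_terminus: bool
    window: int
    truncated: bool


def stop_context(
    cds: CodingSequence,
    window: int | None = None,
    decode_code: GeneticCode | None = None,
    treat_hungry_as_stop: bool = False,
) -> StopContext:
    """Scan the 3' UTR for stop codons in frames 0, -1 and +1.

    Stops are judged under ``decode_code`` (default: the CDS's own code).
    By default hungry codons do not count as stops: they stall the
    ribosome but are not recognised by the release factor, and the
    MT-CO1 claim "no stop in frame 0 or -1" holds only for genuine
    release-factor stops (the UTR carries an in-frame AGG).  Set
    ``treat_hungry_as_stop=True`` for the stricter reading.
    """
    code = decode_code if decode_code is not None else cds.code
    stops = set(code.stop_codons)
    if not treat_hungry_as_stop:
        stops -= set(code.hungry_codons)

    utr = cds.utr3
    if window is None:
        window = len(utr)
    truncated = window > len(utr)
    utr = utr[:window]

    # message seen by a ribosome sliding past the terminal codon
    terminal = cds.terminal_codon if len(cds.terminal_codon) == 3 else ""
    ext = terminal + utr
    shift = len(terminal)  # ext index of the first UTR nt

    frame_stops: dict[int, tuple[int, ...]] = {}
    for frame in (0, -1, +1):
        first = shift + frame if terminal else max(frame, 0)
        hits = [
            i - shift
            for i in range(first, len(ext) - 2, 3)
            if ext[i : i + 3] in stops
        ]
        frame_stops[frame] = tuple(hits)

    minus1 = False
    if terminal and len(cds.nt_sequence) >= 3:
        slipped = cds.nt_sequence[-1] + terminal[:2]
        minus1 = slipped in stops or (treat_hungry_as_stop and code.is_hungry(slipped))
    return StopContext(
        gene_id=cds.gene_id,
        terminal_codon=cds.terminal_codon,
        terminal_hungry=cds.terminal_flag == "hungry",
        frame_stops=frame_stops,
        minus1_stop_at_terminus=minus1,
        window=window,
        truncated=truncated,
    )


@dataclass(frozen=True)
class ExtensionResult:
    """Predicted read-through product of a CDS + UTR + polyA message."""

    gene_id: str
    native_protein: str
    extension_peptide: str
    polyK_length: int
    native_mw: float
    extended_mw: float
    termination_reason: str

    @property
    def extended_protein(self) -> str:
        return self.native_protein + self.extension_peptide


def protein_mw(protein: str, mass_set: str = AVERAGE) -> float:
    """Molecular weight of an unmodified peptide in Da.

    Sum of residue masses plus one water; ``mass_set`` selects average
    (default) or monoisotopic atomic masses.  The empty chain weighs one
    water.  Raises ``ValueError`` naming the position of any non-standard
    residue letter.
    """
    if mass_set not in _WATER:
        raise ValueError(f"unknown mass set {mass_set!r}")
    for i, aa in enumerate(protein):
        if aa not in _AA20:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    if not protein:
        return _WATER[mass_set]
    return float(
        _biopython_mw(protein, seq_type="protein", monoisotopic=mass_set == MONOISOTOPIC)
    )


def predict_readthrough(
    cds: CodingSequence,
    polyA_len: int,
    decode_code: GeneticCode,
    terminal_policy: str = DECODE_AS_SENSE,
    suppress_stops: bool = False,
    suppression_residue: str = "W",
    mass_set: str = AVERAGE,
    initiator_as_met: bool = True,
) -> ExtensionResult:
    """Predict the read-through product of ``CDS + terminal + UTR + polyA``.

    Under ``terminal_policy="decode-as-sense"`` the terminal codon is
    decoded under ``decode_code`` (AGA -> Arg in a bacterial system);
    ``"skip"`` drops it without inserting a residue.  Decoding then
    proceeds codon by codon until a stop of ``decode_code`` or the end of
    the message; a trailing partial codon is not decoded.  A terminal or
    downstream stop is read through as ``suppression_residue`` (default
    Trp, the residue inserted at suppressed UGA) when ``suppress_stops``
    is set.  ``polyK_length`` is the length of the terminal poly-Lys run
    of the extended protein.
    """
    if polyA_len < 0:
        raise ValueError("polyA_len must be non-negative")
    if terminal_policy not in (DECODE_AS_SENSE, SKIP):
        raise ValueError(f"unknown terminal policy {terminal_policy!r}")

    native = translate(cds, initiator_as_met=initiator_as_met)
    native_mw = protein_mw(native, mass_set)

    extension: list[str] = []
    reason = END_OF_MESSAGE
    terminal = cds.terminal_codon if len(cds.terminal_codon) == 3 else ""

    blocked = False
    if terminal and terminal_policy == DECODE_AS_SENSE:
        aa = decode_code.translate_codon(terminal)
        if aa == "*":
            if suppress_stops:
                extension.append(suppression_residue)
            else:
                blocked = True
                reason = STOP_AT_TERMINUS
        else:
            extension.append(aa)

    if not blocked:
        message = cds.utr3 + "A" * polyA_len
        for i in range(0, len(message) - 2, 3):
            codon = message[i : i + 3]
            aa = decode_code.translate_codon(codon)
            if aa == "*":
                if suppress_stops:
                    extension.append(suppression_residue)
                    continue
                reason = STOP_IN_UTR
                break
            extension.append(aa)

    ext = "".join(extension)
    extended = native + ext
    polyk = len(extended) - len(extended.rstrip("K"))
    return ExtensionResult(
        gene_id=cds.gene_id,
        native_protein=native,
        extension_peptide=ext,
        polyK_length=polyk,
        native_mw=native_mw,
        extended_mw=protein_mw(extended, mass_set),
        termination_reason=reason,
    )


def insert_codon(cds: CodingSequence, codon: str, index: int = 1) -> CodingSequence:
    """Return a copy of ``cds`` with ``codon`` inserted at codon ``index``.

    Models engineered constructs such as the extra alanine GCG codon
    placed after the initiator ATG of the MT-CO1 cell-free template.
    """
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not a DNA triplet: {codon!r}")
    body = cds.codons
    if not 0 <= index <= len(body):
        raise ValueError(f"codon index {index} outside 0..{len(body)}")
    new_body = "".join(body[:index]) + codon + "".join(body[index:])
    return CodingSequence(
        gene_id=cds.gene_id,
        nt_sequence=new_body,
        terminal_codon=cds.terminal_codon,
        terminal_flag=cds.terminal_flag,
        utr3=cds.utr3,
        source_coords=cds.source_coords,
        code=cds.code,
        utr3_truncated=cds.utr3_truncated,
    )
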