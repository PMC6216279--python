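"""Genome reading and strand-aware CDS/UTR extraction.

Supports annotated GenBank flat files and FASTA plus a BED-like TSV feature
table (columns ``gene_id  start  end  strand  transl_table``, 1-based
inclusive coordinates as in GenBank).  Internally all coordinates are
0-based half-open; the conversion happens in exactly one place
(:func:`_to_internal` / :func:`_to_external`).

Extraction understands the two quirks of mitochondrial annotation that
matter here: CDS whose stop codon is completed by polyadenylation (the
trailing 1-2 nt are dropped and the CDS flagged ``truncated``) and CDS
terminated by a hungry codon (AGA/AGG) rather than a release-factor stop.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .codes import GeneticCode

COMPLETE_STOP = "complete_stop"
HUNGRY = "hungry"
TRUNCATED = "truncated"


@dataclass(frozen=True)
class CDSFeature:
    """A protein-coding feature in GenBank convention (1-based inclusive)."""

    gene_id: str
    start: int
    end: int
    strand: int  # +1 or -1
    transl_table: int = 2

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.gene_id}: strand must be +1 or -1")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.gene_id}: invalid interval {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Genome:
    """A genome sequence with its protein-coding features."""

    genome_id: str
    sequence: str
    features: tuple[CDSFeature, ...]
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingSequence:
    """An extracted, strand-resolved CDS.

    ``nt_sequence`` is the sense-strand codon body (multiple of 3, terminal
    stop/hungry codon excluded); ``terminal_codon`` holds the excluded
    terminal triplet, or the trailing partial codon (possibly empty) for
    CDS completed by polyadenylation.
    """

    gene_id: str
    nt_sequence: str
    terminal_codon: str
    terminal_flag: str  # complete_stop | hungry | truncated
    utr3: str
    source_coords: tuple[int, int, int]  # 1-based inclusive start, end, strand
    code: GeneticCode
    utr3_truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.nt_sequence) % 3:
            raise ValueError(f"{self.gene_id}: CDS body length not a multiple of 3")
        for i, codon in enumerate(self.codons):
            if self.code.is_stop(codon):
                raise ValueError(
                    f"{self.gene_id}: internal stop codon {codon} at codon index {i}"
                )

    @property
    def codons(self) -> list[str]:
        s = self.nt_sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nt_sequence) // 3


def _to_internal(start: int, end: int) -> tuple[int, int]:
    """GenBank 1-based inclusive -> 0-based half-open."""
    return start - 1, end


def _to_external(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open -> GenBank 1-based inclusive."""
    return lo + 1, hi


def read_genome(
    path: str | Path,
    fmt: str = "genbank",
    feature_table: str | Path | None = None,
) -> Genome:
    """Read a genome and its CDS features.

    ``fmt="genbank"`` parses CDS features (coordinates, strand,
    transl_table) from the record itself; ``fmt="fasta"`` takes them from
    ``feature_table``, a TSV with columns gene_id/start/end/strand/
    transl_table.  Omitting the table yields a genome with no features.
    """
    if fmt == "genbank":
        record = SeqIO.read(str(path), "genbank")
        circular = record.annotations.get("topology", "linear") == "circular"
        feats = []
        for f in record.features:
            if f.type != "CDS":
                continue
            gene = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
            table = int(f.qualifiers.get("transl_table", [1])[0])
            start, end = _to_external(int(f.location.start), int(f.location.end))
            feats.append(
                CDSFeature(gene, start, end, 1 if f.location.strand >= 0 else -1, table)
            )
    elif fmt == "fasta":
        text = Path(path).read_text()
        clean = "\n".join(l for l in text.splitlines() if not l.startswith(";"))
        record = SeqIO.read(io.StringIO(clean), "fasta")
        circular = False
        feats = []
        if feature_table is not None:
            df = pd.read_csv(feature_table, sep="\t")
            for row in df.itertuples(index=False):
                feats.append(
                    CDSFeature(
                        str(row.gene_id),
                        int(row.start),
                        int(row.end),
                        1 if str(row.strand) in ("+", "1") else -1,
                        int(row.transl_table),
                    )
                )
    else:
        raise ValueError(f"unknown genome format {fmt!r}")

    seq = str(record.seq).upper()
    for f in feats:
        if f.end > len(seq):
            raise ValueError(
                f"feature {f.gene_id} ({f.start}..{f.end}) exceeds sequence "
                f"length {len(seq)}"
            )
    return Genome(record.id, seq, tuple(feats), circular)


def _slice(genome: Genome, lo: int, hi: int) -> tuple[str, bool]:
    """Slice [lo, hi) with origin wrap-around on circular genomes.

    Returns the slice and a flag telling whether it had to be truncated at
    the end of a linear genome.
    """
    n = len(genome.sequence)
    if hi <= n:
        return genome.sequence[lo:hi], False
    if genome.circular:
        return genome.sequence[lo:] + genome.sequence[: hi - n], False
    return genome.sequence[lo:n], True


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(
    genome: Genome,
    feature: CDSFeature,
    code: GeneticCode,
    utr3_len: int = 0,
) -> CodingSequence:
    """Extract a strand-resolved :class:`CodingSequence` with its 3' UTR.

    The feature interval is taken to include the terminal (possibly
    partial) stop codon, as GenBank CDS features do.  The UTR is the
    ``utr3_len`` nucleotides immediately downstream on the sense strand,
    wrapping across the origin on circular genomes; on linear genomes a
    short UTR is returned with ``utr3_truncated=True``.
    """
    if feature.length < 6:
        raise ValueError(f"feature {feature.gene_id}: shorter than two codons")
    if utr3_len < 0:
        raise ValueError("utr3_len must be non-negative")

    lo, hi = _to_internal(feature.start, feature.end)
    raw, clipped = _slice(genome, lo, hi)
    if clipped:
        raise ValueError(
            f"feature {feature.gene_id} ({feature.start}..{feature.end}) exceeds "
            f"linear genome bounds"
        )
    sense = reverse_complement(raw) if feature.strand == -1 else raw

    rem = len(sense) % 3
    if rem:
        body, terminal, flag = sense[: len(sense) - rem], sense[len(sense) - rem :], TRUNCATED
    else:
        last = sense[-3:]
        if code.is_hungry(last):
            body, terminal, flag = sense[:-3], last, HUNGRY
        elif code.is_stop(last):
            body, terminal, flag = sense[:-3], last, COMPLETE_STOP
        else:
            body, terminal, flag = sense, "", TRUNCATED

    # downstream of the full feature interval, on the sense strand
    if feature.strand == 1:
        utr, utr_trunc = _slice(genome, hi, hi + utr3_len)
    else:
        n = len(genome.sequence)
        a, b = lo - utr3_len, lo
        if a >= 0:
            utr_raw, utr_trunc = genome.sequence[a:b], False
        elif genome.circular:
            utr_raw, utr_trunc = genome.sequence[a % n :] + genome.sequence[:b], False
        else:
            utr_raw, utr_trunc = genome.sequence[0:b], True
        utr = reverse_complement(utr_raw)

    return CodingSequence(
        gene_id=feature.gene_id,
        nt_sequence=body,
        terminal_codon=terminal,
        terminal_flag=flag,
        utr3=utr,
        source_coords=(feature.start, feature.end, feature.strand),
        code=code,
        utr3_truncated=utr_trunc,
    )


def translate(cds: CodingSequence, initiator_as_met: bool = True) -> str:
    """Translate the CDS body, one letter per sense codon.

    The terminal stop/hungry codon is never part of the body.  When
    ``initiator_as_met`` is set (default) the first codon is rendered Met
    whenever it is a start codon of the table, matching the convention of
    protein records for mitochondrial ATT/ATA/ATC initiators.
    """
    aas = [cds.code.translate_codon(c) for c in cds.codons]
    if aas and initiator_as_met and cds.codons[0] in cds.code.start_codons:
        aas[0] = "M"
    return "".join(aas)
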