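"""Discrimination-ratio statistic and genome-wide reporter scan.

For an ordered amino-acid pair (A, B) — A the misreading-gain label, B the
reference label — a CDS with cognate counts C_A, C_B and near-cognate
counts NC_A, NC_B has discrimination ratio

    R = (NC_A / C_A) / (NC_B / C_B).

A protein with large R gains label-A incorporation much faster than
label-B incorporation as the per-codon misreading probability rises, which
makes it a sensitive endogenous misreading reporter.  Human MT-CO1 with
the Cys/Met pair (R = 64.0) is the canonical example; MT-CO2 (R ~ 3.6) is
the matched insensitive control.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import pandas as pd

from .codes import GeneticCode
from .near_cognate import CodonNeighborhood, count_codons, near_cognate_set
from .seqio import CodingSequence, Genome, extract_cds

DEFINED = "defined"
UNDEFINED = "undefined"
INFINITE = "infinite"


@dataclass(frozen=True)
class ReporterStats:
    """Cognate/near-cognate counts and the discrimination ratio for one CDS."""

    gene_id: str
    pair: tuple[str, str]
    C_A: int
    NC_A: int
    C_B: int
    NC_B: int
    ratio: float | None
    flag: str  # defined | undefined | infinite

    @property
    def ratio_display(self) -> str:
        """The ratio rounded to one decimal, as printed in reports."""
        if self.flag == DEFINED:
            return f"{self.ratio:.1f}"
        return self.flag


@dataclass(frozen=True)
class ReporterRanking:
    """Per-genome ranking of reporter candidates for one amino-acid pair.

    ``ranked`` is sorted by ratio descending (ties: larger NC_A, then
    gene_id); ``unranked`` collects undefined/infinite entries; ``skipped``
    maps gene_id to the extraction error that excluded it.
    """

    pair: tuple[str, str]
    ranked: tuple[ReporterStats, ...]
    unranked: tuple[ReporterStats, ...]
    skipped: dict[str, str]

    @property
    def top(self) -> ReporterStats:
        return self.ranked[0]


def reporter_ratio(C_A: int, NC_A: int, C_B: int, NC_B: int) -> tuple[float | None, str]:
    """Compute R = (NC_A/C_A)/(NC_B/C_B) in exact rational arithmetic.

    Returns ``(ratio, flag)``.  A zero cognate count on either side yields
    ``(None, "undefined")``; NC_B = 0 with C_B > 0 yields
    ``(None, "infinite")`` rather than a sentinel number.
    """
    if min(C_A, NC_A, C_B, NC_B) < 0:
        raise ValueError("counts must be non-negative")
    if C_A == 0 or C_B == 0:
        return None, UNDEFINED
    if NC_B == 0:
        return None, INFINITE
    r = Fraction(NC_A, C_A) / Fraction(NC_B, C_B)
    return float(r), DEFINED


def reporter_stats(
    cds: CodingSequence,
    hood_a: CodonNeighborhood,
    hood_b: CodonNeighborhood,
    include_terminal: bool = False,
) -> ReporterStats:
    """Count both channels of a pair in one CDS and form the ratio."""
    C_A, NC_A = count_codons(cds, hood_a, include_terminal=include_terminal)
    C_B, NC_B = count_codons(cds, hood_b, include_terminal=include_terminal)
    ratio, flag = reporter_ratio(C_A, NC_A, C_B, NC_B)
    return ReporterStats(
        cds.gene_id, (hood_a.amino_acid, hood_b.amino_acid), C_A, NC_A, C_B, NC_B, ratio, flag
    )


def _rank(entries: Iterable[ReporterStats]) -> tuple[list[ReporterStats], list[ReporterStats]]:
    defined = [s for s in entries if s.flag == DEFINED]
    other = [s for s in entries if s.flag != DEFINED]
    defined.sort(key=lambda s: (-s.ratio, -s.NC_A, s.gene_id))
    return defined, other


def scan_genome(
    genome: Genome,
    code: GeneticCode,
    pair: tuple[str, str] = ("C", "M"),
    mode: str = "anticodon",
    include_terminal: bool = False,
) -> ReporterRanking:
    """Rank every CDS of a genome as a misreading reporter for ``pair``.

    CDS that fail extraction are reported in ``skipped`` with the error
    message, never dropped silently.
    """
    if not genome.features:
        raise ValueError("genome has no CDS features to scan")
    a, b = pair
    hood_a = near_cognate_set(a, code, mode=mode)
    hood_b = near_cognate_set(b, code, mode=mode)
    entries: list[ReporterStats] = []
    skipped: dict[str, str] = {}
    for feature in genome.features:
        try:
            cds = extract_cds(genome, feature, code)
            entries.append(reporter_stats(cds, hood_a, hood_b, include_terminal))
        except ValueError as exc:
            skipped[feature.gene_id] = str(exc)
    ranked, unranked = _rank(entries)
    return ReporterRanking(pair, tuple(ranked), tuple(unranked), skipped)


def scan_pairs(
    cds: CodingSequence, code: GeneticCode, mode: str = "union"
) -> list[ReporterStats]:
    """Reporter statistics for all ordered amino-acid pairs of one CDS.

    Returns one entry per ordered pair (A, B), A != B, over the amino
    acids encoded by the table; defined entries first, sorted by ratio
    descending.  Defaults to ``union`` neighbourhoods so that every amino
    acid is covered regardless of anticodon annotation.
    """
    aas = sorted(code.amino_acids())
    hoods = {a: near_cognate_set(a, code, mode=mode) for a in aas}
    entries = [
        reporter_stats(cds, hoods[a], hoods[b])
        for a in aas
        for b in aas
        if a != b
    ]
    ranked, unranked = _rank(entries)
    return ranked + unranked


def ranking_frame(ranking: ReporterRanking) -> pd.DataFrame:
    """Tabulate a ranking (defined entries first) as a DataFrame."""
    rows = []
    for rank, s in enumerate(ranking.ranked, start=1):
        rows.append(
            dict(
                rank=rank,
                gene_id=s.gene_id,
                C_A=s.C_A,
                NC_A=s.NC_A,
                C_B=s.C_B,
                NC_B=s.NC_B,
                ratio=s.ratio,
                ratio_display=s.ratio_display,
                flags=s.flag,
            )
        )
    for s in ranking.unranked:
        rows.append(
            dict(
                rank=None,
                gene_id=s.gene_id,
                C_A=s.C_A,
                NC_A=s.NC_A,
                C_B=s.C_B,
                NC_B=s.NC_B,
                ratio=None,
                ratio_display=s.ratio_display,
                flags=s.flag,
            )
        )
    frame = pd.DataFrame(rows)
    frame["rank"] = frame["rank"].astype("Int64")
    return frame


def write_ranking_tsv(ranking: ReporterRanking, path: str | Path) -> None:
    ranking_frame(ranking).to_csv(path, sep="\t", index=False)
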