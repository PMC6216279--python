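"""Synthetic genomes, CDS and assay replicates with known ground truth.

The generators produce inputs with exactly the statistical structure the
analysis assumes — multi-CDS genomes with configurable codon usage and
strand, CDS with *planted* cognate/near-cognate compositions for a chosen
amino-acid pair, and noisy dual-reporter replicate measurements under a
known generative fold change — so every stage of the pipeline can be
tested against construction-time ground truth, without downloads.

Planting is exact by construction: filler codons are drawn only from
codons at Hamming distance >= 2 from both cognate sets of the planted
pair, so they can never leak into a cognate or near-cognate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import ALL_CODONS, GeneticCode, hamming, load_genetic_code
from .near_cognate import cognate_set, near_cognate_set
from .seqio import (
    COMPLETE_STOP,
    HUNGRY,
    CDSFeature,
    CodingSequence,
    Genome,
    reverse_complement,
)


@dataclass(frozen=True)
class PlantedComposition:
    """Requested exact counts for one gene and one amino-acid pair."""

    gene_index: int
    pair: tuple[str, str]
    C_A: int
    NC_A: int
    C_B: int
    NC_B: int


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic multi-CDS genome."""

    n_genes: int = 5
    length_range: tuple[int, int] = (60, 200)  # codons, body incl. start
    codon_usage: dict[str, float] | None = None
    strand_mix: float = 0.0  # fraction of genes on the reverse strand
    table_id: int = 2
    planted: tuple[PlantedComposition, ...] = ()
    seed: int = 0
    circular: bool = True
    intergenic_range: tuple[int, int] = (20, 100)
    hungry_terminal_genes: frozenset[int] = frozenset()

    def code(self) -> GeneticCode:
        return load_genetic_code(self.table_id)


def _usage_weights(
    spec: SyntheticGenomeSpec, code: GeneticCode, allowed: list[str]
) -> np.ndarray:
    if spec.codon_usage is None:
        w = np.ones(len(allowed))
    else:
        w = np.array([spec.codon_usage.get(c, 0.0) for c in allowed], dtype=float)
        if (w < 0).any():
            raise ValueError("codon usage weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("no usable filler codon has positive weight")
    return w / w.sum()


def _planted_for(spec: SyntheticGenomeSpec, gene_index: int) -> PlantedComposition | None:
    hits = [p for p in spec.planted if p.gene_index == gene_index]
    if len(hits) > 1:
        raise ValueError(f"gene {gene_index} has multiple planted compositions")
    return hits[0] if hits else None


def gen_cds(spec: SyntheticGenomeSpec, gene_index: int) -> CodingSequence:
    """Generate one CDS, honouring any planted composition exactly.

    The CDS starts with ATG, contains no internal stop and ends with a
    complete stop codon (or the code's first hungry codon for genes listed
    in ``hungry_terminal_genes``).  Deterministic given ``spec.seed`` and
    ``gene_index``.
    """
    code = spec.code()
    rng = np.random.default_rng([spec.seed, gene_index])
    planted = _planted_for(spec, gene_index)

    start = "ATG"
    placements: list[str] = []
    neutral_from: set[str] = set()

    if planted is not None:
        a, b = planted.pair
        S = {x: cognate_set(x, code) for x in (a, b)}
        N = {
            x: near_cognate_set(x, code, mode="anticodon").near_cognate_set
            for x in (a, b)
        }
        budget = {
            ("C", a): planted.C_A,
            ("N", a): planted.NC_A,
            ("C", b): planted.C_B,
            ("N", b): planted.NC_B,
        }
        # the mandatory ATG start participates in the counts
        for kind, x in budget:
            hit = start in (S[x] if kind == "C" else N[x])
            if hit:
                budget[(kind, x)] -= 1
                if budget[(kind, x)] < 0:
                    raise ValueError(
                        f"gene {gene_index}: planted count for ({kind}, {x}) "
                        f"incompatible with the ATG start codon"
                    )
        stops = set(code.stop_codons)
        other = {a: b, b: a}
        for kind, x in sorted(budget):
            pool_all = S[x] if kind == "C" else N[x]
            y = other[x]
            pool = sorted(pool_all - S[y] - N[y] - stops)
            need = budget[(kind, x)]
            if need and not pool:
                raise ValueError(
                    f"gene {gene_index}: no codon can realise ({kind}, {x}) "
                    f"without touching the {y} counts"
                )
            placements += list(rng.choice(pool, size=need)) if need else []
        neutral_from = S[a] | S[b]
    else:
        neutral_from = set()

    lo, hi = spec.length_range
    n_codons = int(rng.integers(lo, hi + 1))
    n_codons = max(n_codons, 1 + len(placements))

    # filler: sense codons at distance >= 2 from every planted cognate set
    filler_pool = [
        c
        for c in ALL_CODONS
        if not code.is_stop(c)
        and (not neutral_from or min(hamming(c, x) for x in neutral_from) >= 2)
    ]
    weights = _usage_weights(spec, code, filler_pool)
    n_filler = n_codons - 1 - len(placements)
    filler = list(rng.choice(filler_pool, size=n_filler, p=weights))

    interior = placements + filler
    rng.shuffle(interior)
    body = start + "".join(interior)

    if gene_index in spec.hungry_terminal_genes:
        if not code.hungry_codons:
            raise ValueError("code has no hungry codons for a hungry terminal")
        terminal, flag = sorted(code.hungry_codons)[0], HUNGRY
    else:
        terminal, flag = sorted(code.stop_codons - code.hungry_codons)[0], COMPLETE_STOP

    return CodingSequence(
        gene_id=f"synth{gene_index:02d}",
        nt_sequence=body,
        terminal_codon=terminal,
        terminal_flag=flag,
        utr3="",
        source_coords=(0, 0, 1),
        code=code,
    )


def gen_genome(spec: SyntheticGenomeSpec) -> tuple[Genome, list[CodingSequence]]:
    """Generate a genome embedding ``n_genes`` CDS with intergenic spacers.

    Reverse-strand genes are stored reverse-complemented with the feature
    strand set accordingly, so extraction round-trips byte-identically.
    Returns the genome and the generated CDS in gene order.
    """
    code = spec.code()
    rng = np.random.default_rng([spec.seed, 10**6])
    cdss = [gen_cds(spec, i) for i in range(spec.n_genes)]
    n_rev = int(round(spec.strand_mix * spec.n_genes))
    strands = np.array([-1] * n_rev + [1] * (spec.n_genes - n_rev))
    rng.shuffle(strands)

    lo, hi = spec.intergenic_range
    parts: list[str] = []
    features: list[CDSFeature] = []
    pos = 0
    for cds, strand in zip(cdss, strands):
        spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1))))
        parts.append(spacer)
        pos += len(spacer)
        sense = cds.nt_sequence + cds.terminal_codon
        stored = reverse_complement(sense) if strand == -1 else sense
        parts.append(stored)
        features.append(
            CDSFeature(cds.gene_id, pos + 1, pos + len(stored), int(strand), spec.table_id)
        )
        pos += len(stored)
    parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1)))))
    genome = Genome(
        genome_id=f"synthetic-{spec.seed}",
        sequence="".join(parts),
        features=tuple(features),
        circular=spec.circular,
    )
    return genome, cdss


def gen_assay(
    fold_change_true: float,
    n_replicates: int = 6,
    noise_cv: float = 0.1,
    seed: int = 0,
    reference_level: float = 1000.0,
):
    """Generate dual-reporter replicates with a known generative fold change.

    Reference replicates have true signal ratio 1, test replicates
    ``fold_change_true``; each ratio is multiplied by independent unit-mean
    log-normal noise of coefficient of variation ``noise_cv``.  Returns
    ``(test_group, reference_group)`` lists of
    :class:`~mitofidelity.model.DualReporterMeasurement`.
    """
    from .model import DualReporterMeasurement

    if fold_change_true <= 0:
        raise ValueError("fold_change_true must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)

    def noise(size: int) -> np.ndarray:
        if noise_cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)

    test = [
        DualReporterMeasurement(
            test_signal=reference_level * fold_change_true * z,
            reference_signal=reference_level,
            group="test",
        )
        for z in noise(n_replicates)
    ]
    reference = [
        DualReporterMeasurement(
            test_signal=reference_level * z,
            reference_signal=reference_level,
            group="reference",
        )
        for z in noise(n_replicates)
    ]
    return test, reference


def write_genome(genome: Genome, fasta_path, tsv_path, genbank_path=None) -> None:
    """Write a genome as FASTA + feature TSV and optionally GenBank."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        for i in range(0, len(genome.sequence), 60):
            fh.write(genome.sequence[i : i + 60] + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\ttransl_table\n")
        for f in genome.features:
            strand = "+" if f.strand == 1 else "-"
            fh.write(f"{f.gene_id}\t{f.start}\t{f.end}\t{strand}\t{f.transl_table}\n")
    if genbank_path is not None:
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        record = SeqRecord(
            Seq(genome.sequence),
            id=genome.genome_id,
            name=genome.genome_id[:16].replace("-", ""),
            description="synthetic genome",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if genome.circular else "linear",
            },
        )
        for f in genome.features:
            record.features.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end, strand=f.strand),
                    type="CDS",
                    qualifiers={"gene": [f.gene_id], "transl_table": [str(f.transl_table)]},
                )
            )
        SeqIO.write(record, str(genbank_path), "genbank")
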