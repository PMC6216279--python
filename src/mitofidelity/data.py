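"""Packaged reference data.

The package ships a copy of the complete human mitochondrial genome,
NCBI reference NC_001807.4 (16,571 bp), together with the coordinates of
its 13 protein-coding genes.  Note that this is the older human
mitochondrial reference; it differs from the revised Cambridge Reference
Sequence (rCRS, J01415.2 / NC_012920) by roughly forty single-nucleotide
sites and two indels, almost all of them outside or synonymous within the
coding regions.  The consequences for the reporter statistics are
discussed in ``docs/methods.md``.
"""

from __future__ import annotations

from importlib import resources

from .seqio import Genome, read_genome


def load_human_mtdna() -> Genome:
    """Load the bundled human mitochondrial genome (NC_001807.4).

    Returns a circular :class:`~mitofidelity.seqio.Genome` with the 13
    protein-coding CDS features annotated on translation table 2.
    """
    pkg = resources.files("mitofidelity") / "data"
    with resources.as_file(pkg / "human_mtdna_NC_001807.fasta") as fasta, resources.as_file(
        pkg / "human_mtdna_cds.tsv"
    ) as table:
        genome = read_genome(fasta, fmt="fasta", feature_table=table)
    # mtDNA is circular; FASTA carries no topology flag
    return Genome(genome.genome_id, genome.sequence, genome.features, circular=True)
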