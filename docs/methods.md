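# Methods

## Scope and model

The package treats a coding sequence as an ordered list of sense codons
decoded by tRNAs under a fixed genetic code, and asks how often a
misreading event at a *near-cognate* codon would insert a given labelled
amino acid. Everything downstream — the discrimination ratio, the genome
scan, the incorporation model — is arithmetic on four per-CDS counts:
cognate and near-cognate occurrences for the gain label A and the
reference label B.

### Near-cognate definition

Two neighbourhood modes are implemented, and the distinction matters.

* **anticodon mode** (default for reporter statistics). Each amino acid
  is assigned its *primary codon(s)*: the codon that forms a perfect
  Watson–Crick duplex with the anticodon of the decoding tRNA. For the
  vertebrate mitochondrial code this is well defined — there are exactly
  22 mitochondrially encoded tRNAs, one per codon family box — and the
  full 20-amino-acid map is curated in `codes.py` (G34 anticodons pair
  NNC, U34 anticodons pair NNA, tRNA-Met's modified C34 pairs ATG and
  reads ATA only through base modification; Leu and Ser have two
  isoacceptors each). The near-cognate set is every codon one
  substitution away from a primary codon, minus all cognates. For Cys
  (primary TGC) this gives 8 codon types, for mitochondrial Met (primary
  ATG) 8 types — note that ATA is cognate, and AGA/AGG, although one step
  from ATA, are *not* near-cognate to the Met tRNA's anticodon.
* **union mode.** The purely combinatorial alternative: every codon at
  minimum Hamming distance exactly 1 from the full cognate set (14 types
  for Cys under tables 1 and 2; 9 for Met under table 1, 14 under
  table 2). This mode is defined for every amino acid under every
  supported table and is the surface checked against a brute-force
  64-codon enumeration in the tests.

The anticodon definition was adopted after calibrating both modes against
the published MT-CO1/MT-CO2 counts. Union-mode counting on MT-CO1 yields
130 near-cognate codons for both Cys and Met; anticodon-mode counting
yields 96 and 48 — the published values — and 26 for Met on MT-CO2. This
is also the biologically meaningful neighbourhood: misreading is a
property of a specific tRNA's codon–anticodon duplex, not of the codon
set as a whole. For codes without a curated anticodon map (cytosolic and
bacterial tRNA sets have multiple isoacceptors per amino acid and no
single canonical choice), anticodon mode is populated only for Cys and
Met — the two labels the assay uses, identical in E. coli — and other
amino acids must use union mode explicitly.

### Counting policy

Counting runs over the sense codons of the CDS body. The terminal codon
(stop or hungry) is excluded by default: it is not decoded as a sense
codon. The published Met count of 48 is reproduced under this default;
the policy only matters in union mode, where MT-CO1's terminal AGA would
otherwise contribute a spurious Met near-cognate (it is Hamming-1 from
ATA). Codons near-cognate to both members of a pair are counted for each
independently.

### Discrimination ratio

R = (NC_A/C_A)/(NC_B/C_B), computed in exact rational arithmetic
(`fractions.Fraction`) and only then converted to float. Human-readable
output rounds to one decimal; the full-precision value is always retained
in machine output. Zero cognate counts flag the ratio `undefined`,
NC_B = 0 flags it `infinite`; neither is ever a sentinel number, and
flagged entries are listed after the ranked ones, never interleaved.
Ranking ties break by larger NC_A, then lexicographic gene id.

## Reference data

The package bundles the complete human mitochondrial genome as plain
FASTA plus a 13-row CDS table: NCBI reference **NC_001807.4** (16,571 bp).
The revised Cambridge Reference Sequence (NC_012920 / J01415.2, 16,569 bp)
differs from it at roughly forty single-nucleotide sites and two indels;
all 13 CDS were validated in the bundled record (correct start codons, no
internal stops, expected protein lengths, AGA/AGG hungry terminals on
MT-CO1/MT-ND6, incomplete T/TA stops on the polyadenylation-completed
genes). The choice has one visible consequence: the Cys near-cognate
count of MT-CO2 computes to 28 on this record where the published value
(computed on the rCRS) is 29 — a one-codon difference consistent with a
single synonymous site, e.g. a TAT/TAC Tyr codon. The corresponding
acceptance test asserts the published 29 and is expected to fail on the
bundled record; MT-CO1 (1, 96, 32, 48; R = 64.0) and MT-CO2's Met channel
(10, 26) reproduce exactly. MT-CO2's ratio on this record is 3.6 versus
the published rounding of 3.8 (exact arithmetic on the published counts
gives 3.718).

## CDS extraction conventions

* External interfaces use GenBank 1-based inclusive coordinates; the
  internal representation is 0-based half-open, with the conversion
  centralised in `seqio.py`.
* The feature interval includes the terminal codon. A trailing 1–2 nt
  remainder (stop completed by polyadenylation) is dropped from the codon
  list and the CDS flagged `truncated`; a full terminal triplet is
  flagged `hungry` if in the code's hungry set, else `complete_stop` if a
  stop, else the CDS is `truncated` with an empty terminal.
* 3′ UTR extraction takes the requested number of nucleotides immediately
  downstream on the sense strand, wrapping across the origin on circular
  genomes (mtDNA is circular) and truncating with a warning flag on
  linear ones.
* Alternative initiator codons (ATT/ATA/ATC/GTG where the table allows)
  translate as Met by default, matching protein-record convention and the
  residue counts the reporter statistic relies on (32 Met in MT-CO1
  includes its initiator); a flag restores literal translation.
* Internal stop codons abort extraction with the codon index named;
  genome scans collect such genes under `skipped` rather than dropping
  them silently.

## Read-through analysis

* Frame convention: frame 0 continues the CDS reading frame into the
  UTR; −1 is one nucleotide toward 5′ (the first −1 triplet uses the last
  nucleotide of the terminal codon); +1 is one toward 3′.
* The `minus1_stop_at_terminus` flag tests the triplet formed by the last
  nucleotide of the penultimate codon plus the first two of the terminal
  codon — the MT-CO1 geometry in which a UAG underlies the AGA.
* Hungry codons are **not** counted as stops by default in UTR scans:
  they stall the ribosome but are not release-factor substrates, and the
  stop-free property of the MT-CO1 UTR holds for genuine stops only (the
  UTR contains an in-frame AGG at offset 3). `treat_hungry_as_stop=True`
  restores the stricter reading.
* Read-through decoding proceeds under a caller-chosen code (table 1 for
  the bacterial cell-free system, where AGA is Arg), terminates at the
  first stop of that code or the message end, and never decodes a
  trailing partial codon. Stop suppression, when requested, inserts Trp
  (the residue dominantly inserted at suppressed UGA).
* Molecular weights use average atomic masses by default (monoisotopic
  available), one water per chain, no N-terminal formylation, no Met
  excision. These conventions reproduce 57.1 kDa for the 514-residue
  cell-free construct (native MT-CO1 with an Ala inserted after the
  initiator) and 62.1 kDa for its read-through product
  (+Arg, +23 UTR-encoded residues, +17 Lys from the 51-nt polyA).

## Incorporation model

Parameters: ε — probability that one near-cognate codon is decoded by
the labelled amino acid's tRNA in one translation event (dimensionless,
pooled over codons and positions); ρ — stop read-through probability
(carried on the parameter object for completeness; the read-through
geometry module treats read-through deterministically). The closed form,
its initial slope NC_A/C_A − NC_B/C_B, the binomial per-molecule
simulator (delta-method standard error on the ratio of means) and the
bracketed-root inversion (`brentq` on [0, 1], xtol 1e-12) are described
in `model.py`. The model is first order: label gain at near-cognate
sites only, neglecting the second-order loss of label at cognate sites
misread by other tRNAs. No numeric ε is asserted anywhere — absolute
misreading levels are not recoverable from gel-read fold changes — so all
ε-related tests are property-based (round-trip identity, simulator/closed
form agreement within three Monte Carlo standard errors).

Dual-reporter normalisation uses the mean of per-replicate test/reference
signal ratios, scaled so the reference group's mean is exactly 1, with
SEM and n reported per group; the convenience significance test is a
two-sided two-sample t test with Welch correction on by default.

## Synthetic data

The generators emulate the structural features the analysis depends on:
multi-CDS genomes with configurable codon usage and strand mix, planted
cognate/near-cognate compositions, hungry or complete terminals, and
replicate dual-reporter measurements with unit-mean log-normal noise of
stated CV (signals are positive and ratio-scaled, making multiplicative
noise the natural choice). Planting is exact by construction: placements
are drawn from the anticodon-mode near sets and cognate sets of the pair
(mutually disjoint pools, stops excluded), and filler codons only from
codons at Hamming distance ≥ 2 from both cognate sets, so a planted
composition can never drift. The mandatory ATG start participates in the
Met budget and infeasible requests fail loudly. What the generators do
*not* emulate: real mitochondrial base composition and codon-usage bias,
overlapping genes, tRNA punctuation, or any position dependence of
misreading — so passing synthetic tests validates the bookkeeping and the
statistics, not biological realism.

Default problem sizes (513-codon planted CDS mirroring MT-CO1, 10⁵
simulated molecules, ε grid up to 0.05, 6–1000 assay replicates) keep the
full suite and the acceptance script in the seconds-to-minute range while
leaving Monte Carlo standard errors small against the tested effects.

## Known limitations

* The anticodon map for tables 1/11 covers Cys and Met only; extending it
  requires curating isoacceptor sets per organism.
* Near-cognate neighbourhoods are unweighted: no wobble-position
  weighting, tRNA-abundance weighting or mismatch-geometry scoring.
* The bundled NC_001807.4 record is not the revised Cambridge sequence;
  see above for the one count it shifts. Any rCRS-derived FASTA + CDS
  table can be supplied through `read_genome` to remove the discrepancy.
* Spliced CDS are out of scope (mitochondrial genes are unspliced).
* No kinetic model of frameshifting or release-factor competition; ε is
  pooled, not codon- or position-specific.
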