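"""Predict the read-through product of the MT-CO1 cell-free construct.

MT-CO1 ends on the hungry codon AGA: the mitoribosome stalls, slips one
nucleotide backwards and terminates on a hidden UAG.  A ribosome that
instead decodes the terminus as a sense codon (AGA = Arg in a bacterial
system) runs into the 69-nt 3' UTR — which contains no stop in frame — and
then translates the 51-nt polyA tail into 17 lysines.  The cell-free
construct carries an extra Ala codon after the start codon.
"""

import mitofidelity as mf

genome = mf.load_human_mtdna()
code2 = mf.load_genetic_code(2)
code1 = mf.load_genetic_code(1)

features = {f.gene_id: f for f in genome.features}
co1 = mf.extract_cds(genome, features["MT-CO1"], code2, utr3_len=69)

ctx = mf.stop_context(co1, window=69)
print(f"terminal codon: {ctx.terminal_codon} (hungry: {ctx.terminal_hungry})")
print(f"-1 shift at the terminus exposes a stop: {ctx.minus1_stop_at_terminus}")
print(f"stops in 69-nt UTR, frame  0: {list(ctx.frame_stops[0])}")
print(f"stops in 69-nt UTR, frame -1: {list(ctx.frame_stops[-1])}")

construct = mf.insert_codon(co1, "GCG", index=1)  # Ala after the initiator
result = mf.predict_readthrough(construct, polyA_len=51, decode_code=code1)
print(f"\nnative construct: {len(result.native_protein)} aa, "
      f"{result.native_mw / 1000:.1f} kDa")
print(f"read-through product: {len(result.extended_protein)} aa, "
      f"{result.extended_mw / 1000:.1f} kDa "
      f"({result.termination_reason}, poly-Lys tract {result.polyK_length})")
print(f"extension peptide: {result.extension_peptide}")
print(
    "\nThe ~5 kDa mass shift between the two products is what separates "
    "native and read-through bands on a gel."
)
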