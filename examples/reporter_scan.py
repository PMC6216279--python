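"""Rank the 13 human mtDNA proteins as endogenous misreading reporters.

A misreading mitoribosome occasionally decodes a near-cognate codon with
the tRNA of a labelled amino acid.  A protein whose mRNA is rich in
near-cognate codons for one label (Cys) but whose own sequence carries few
cognate codons for it — while the reference label (Met) behaves the
opposite way — amplifies misreading into a measurable label-ratio shift.
The discrimination ratio R = (NC_Cys/C_Cys)/(NC_Met/C_Met) quantifies
this.
"""

import mitofidelity as mf

genome = mf.load_human_mtdna()
code = mf.load_genetic_code(2)  # vertebrate mitochondrial code

ranking = mf.scan_genome(genome, code, pair=("C", "M"))
print(mf.ranking_frame(ranking).to_string(index=False))

top = ranking.top
print(
    f"\n{top.gene_id} is the most sensitive reporter: R = {top.ratio_display} "
    f"({top.NC_A} near-cognate vs {top.C_A} cognate Cys codons, "
    f"{top.NC_B} vs {top.C_B} for Met)."
)
print(
    "Genes listed without a rank lack Cys codons entirely, so their ratio "
    "is undefined rather than zero."
)
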