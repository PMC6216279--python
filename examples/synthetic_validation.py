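"""Validate the pipeline end-to-end on synthetic ground truth.

A synthetic genome with a planted high-discrimination gene must rank that
gene first, and noisy dual-reporter replicates generated at a known fold
change must normalise back to it.
"""

import mitofidelity as mf

spec = mf.SyntheticGenomeSpec(
    n_genes=8,
    length_range=(80, 160),
    seed=123,
    strand_mix=0.5,
    planted=(mf.PlantedComposition(3, ("C", "M"), 1, 60, 12, 6),),  # R = 120
)
genome, _ = mf.gen_genome(spec)
code = spec.code()

ranking = mf.scan_genome(genome, code, ("C", "M"))
top = ranking.top
print(f"planted gene synth03 ranks first: {top.gene_id == 'synth03'} "
      f"(R = {top.ratio_display}, expected 120.0)")

test, ref = mf.gen_assay(fold_change_true=1.5, n_replicates=8, noise_cv=0.15, seed=9)
res = mf.normalize_dual_reporter(test, ref)
t_stat, p = mf.group_difference_test(test, ref)
print(f"\nnoisy assay (CV 15%, n=8): fold change "
      f"{res.fold_change:.3f} +/- {res.test.sem:.3f} SEM (truth 1.5)")
print(f"Welch t test vs reference group: t = {t_stat:.2f}, p = {p:.2g}")
print(
    "\nBoth stages recover the planted truth, which is what qualifies the "
    "generators as test oracles for the analysis."
)
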