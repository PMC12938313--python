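"""Covariate-adjusted synergy biomarker discovery on the 14-model panel.

Per gene, an ANCOVA of the combination index on expression + subtype + IC50
gates significance (F p <= 0.1); Spearman rho with C.I. orients the call
(rho <= -0.2 synergy-associated, rho >= +0.2 additive-associated); each list
feeds Fisher's-exact overrepresentation against the pathway collection.
"""

from gbmsynergy import SimulationConfig, biomarker_pipeline, simulate_expression_cohort

coh = simulate_expression_cohort(SimulationConfig(seed=3), kind="pdx")
res = biomarker_pipeline(coh.expr, coh.panel_phenotypes(), coh.gene_sets)

print(f"{len(res['synergy_genes'])} synergy-associated and "
      f"{len(res['additive_genes'])} additive-associated genes selected "
      f"out of {len(res['ancova'])} tested")
print("\nsynergy-list overrepresentation (fold enrichment > 1):")
print(res["ora_synergy"].head(3).to_string(index=False))
# The planted SYNERGY_PROGRAM set (50 genes coupled to low C.I.) should top
# the table with a large fold enrichment and tiny FDR; decoys should not.
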