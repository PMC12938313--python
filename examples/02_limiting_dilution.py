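"""Estimate sphere-initiating (stem-cell) frequencies by limiting dilution.

Simulates four treatment arms at the study's published frequencies
(1 in 87 control down to 1 in 1348 for the combination), estimates each
frequency under the single-hit Poisson model and tests all pairs.
"""

from gbmsynergy import estimate_frequency, pairwise_comparison_table, simulate_elda

truths = {"DMSO": 87, "ATO": 167, "AUM001": 295, "combo": 1348}
groups = []
for i, (name, one_in) in enumerate(truths.items()):
    wc = simulate_elda(1 / one_in, wells_per_dose=12, seed=100 + i, group=name)
    groups.append(wc)
    est = estimate_frequency(wc)
    print(f"{name:>7}: 1 GSC in {est.one_in:6.0f} cells "
          f"(95% CI {est.ci_low:.0f}-{est.ci_high:.0f}, true {one_in})")

print("\npairwise likelihood-ratio tests (chi-squared, 1 df):")
print(pairwise_comparison_table(groups).to_string(index=False))
# Small p-values mean the sphere-initiating frequency genuinely differs
# between arms; the combination depletes stem cells far below either agent.
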