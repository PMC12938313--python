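"""Fit single-agent dose-response curves and score combination synergy.

Simulates one resistant, strongly synergistic screening model, fits the
median-effect model to each single agent, evaluates the Chou-Talalay
combination index over the 12 x 4 dose grid and calls the interaction.
"""

from gbmsynergy import (
    SimulationConfig,
    ci_grid,
    classify_interaction,
    default_panel_truth,
    fit_median_effect,
    min_ci,
    normalize_viability,
    simulate_viability_panel,
)
from gbmsynergy.simulate import PanelTruth

# the most resistant model of the default panel (IC50 5 µM, alpha 2.5)
model = default_panel_truth().models[-1]
truth = PanelTruth(models=(model,))
records, matrices = simulate_viability_panel(
    SimulationConfig(seed=0, noise_cv=0.05), truth
)

fit1 = fit_median_effect(normalize_viability(records, model.model_id, "drug1"))
fit2 = fit_median_effect(normalize_viability(records, model.model_id, "drug2"))
print(f"drug 1 (ATO-like):    m = {fit1.m:.2f}, IC50 = {fit1.Dm:.2f} µM "
      f"(true {model.Dm1:.2f})")
print(f"drug 2 (partner):     m = {fit2.m:.2f}, IC50 = {fit2.Dm:.2f} µM "
      f"(true {model.Dm2:.2f})")

grid = ci_grid(matrices[model.model_id], fit1, fit2)
lowest, best = min_ci(grid)  # restricted to cells with fa >= 0.2
call = classify_interaction(lowest)
print(f"lowest C.I. = {lowest:.2f} at d1 = {best.d1:.3g} µM + "
      f"d2 = {best.d2:.3g} µM (fa = {best.fa:.2f}) -> {call.label}")
# A combination index below 1 means the measured effect needed less drug than
# Loewe additivity predicts from the two single-agent curves: synergy.
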