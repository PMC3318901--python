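"""MRM verification: transition masses, single-marker ROC, merged panel.

First recomputes every packaged Q1/Q3 transition from its peptide
sequence and reports printed-value discrepancies; then simulates a
9 NA vs 14 MA cohort for three markers, scores each by ROC, and merges
them into one logistic panel.
"""

from uroquant import (
    SimulationConfig,
    delta_for_auc,
    fit_panel,
    load_reference_transitions,
    marker_roc,
    simulate_mrm_cohort,
    validate_transition_table,
)

transitions = load_reference_transitions()
findings = validate_transition_table(transitions, tolerance_mz=0.25)
print(f"{len(transitions)} reference transitions; {len(findings)} printed values deviate:")
for f in findings:
    print(f"  {f.analyte_name} {f.sequence} {f.which}: printed {f.printed_mz}, computed {f.computed_mz:.2f}")
print("(deviations are findings about the printed table, e.g. a mislabeled fragment)")

targets = {"A1AT": 0.849, "AGP1": 0.873, "PSCA": 0.825}
config = SimulationConfig(
    seed=3,
    marker_effect_sizes={m: delta_for_auc(a) for m, a in targets.items()},
)  # default cohort: 9 NA vs 14 MA
records, truth = simulate_mrm_cohort(config)

print(f"\nsimulated cohort: {config.n_na} NA vs {config.n_ma} MA samples")
print(f"{'marker':<6} {'true AUC':>9} {'empirical':>10} {'sens%':>6} {'spec%':>6}")
for marker in targets:
    roc = marker_roc(records, marker)
    print(
        f"{marker:<6} {truth.marker_true_auc[marker]:>9.3f} {roc.auc:>10.3f} "
        f"{roc.sens_at_optimal:>6.1f} {roc.spec_at_optimal:>6.1f}"
    )

panel = fit_panel(records, list(targets))
print(f"\nmerged 3-marker panel ({panel.method}): AUC = {panel.roc.auc:.3f}")
print("Sensitivity/specificity are at the Youden-optimal cutoff; the merged")
print("panel typically outperforms each single marker, at small-cohort noise.")
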