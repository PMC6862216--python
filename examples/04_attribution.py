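"""Attribute each expression change to mRNA stability or transcription.

A gene whose mRNA changes with a concordant half-life change and quiet
pre-mRNA is stability-driven; a concordant pre-mRNA (intronic) change
with an unchanged half-life is transcription-driven.
"""

from mrnafate import (
    SimConfig, attribute_table, fit_decay_table, filter_half_lives,
    fold_change, fpkm_table, normalize_to_reference, quantify_counts,
    simulate_dataset, stability_table, summarize_layers,
)
from mrnafate.synthetic import attribution_accuracy

sim = simulate_dataset(SimConfig(seed=17))
expr = quantify_counts(sim.steady_counts, sim.models, sim.steady_samples)
chase_expr = normalize_to_reference(fpkm_table(sim.chase_counts, sim.models))
fits = filter_half_lives(fit_decay_table(chase_expr, sim.chase_samples))
stability = stability_table(fits)

fc_mrna = fold_change(expr, sim.steady_samples, "mRNA")
fc_pre = fold_change(expr, sim.steady_samples, "pre-mRNA")
attribution = attribute_table(fc_mrna, fc_pre, stability)

summary, _ = summarize_layers(fc_mrna, fc_pre, stability)
print(summary.to_string(index=False))

print("\ndriver breakdown for changed mRNAs:")
print(attribution.driver.value_counts().to_string())

acc = attribution_accuracy(sim.truth, attribution)
print(f"\nattribution accuracy on designed genes: {acc:.1%}")
print("-> each designed gene's recovered class and driver match the")
print("   kinetic parameter that was actually perturbed.")
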