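"""Train the downsampling consensus ensemble and call significant pairs.

Labels come from the training tier of planted interactions only (a 1.39%
positive class); 20 XGBoost models per downsampling rate then score every
negative pair, and pairs called positive by >= 70% of the models are
deemed significant. Watch recall fall and specificity rise as more
negatives enter training.
"""

import mirtarget as mt

panels, truth = mt.simulate_panels(mt.SimulationConfig(seed=7))
table = mt.build_feature_table(panels)
training = mt.InteractionDB(
    "synthetic-training", "training", frozenset(truth.pairs_by_tier("training"))
)
labels = mt.assign_labels(table, [training])
print(f"positives: {labels.n_positive}/{labels.n_pairs} "
      f"({labels.positive_fraction_pct}%)")

config = mt.EnsembleConfig(
    downsample_rates=(0.01, 0.05, 0.1, 0.5, 1.0), n_models=20, base_seed=7
)
result = mt.run_suite(table, labels, config)
print(mt.metric_summary(result).round(3))
print("\nsignificant pairs per (rate, frequency threshold):")
print(result.grid())
# Counts shrink with stricter thresholds and with heavier negative
# sampling -- the ensemble trades recall for precision exactly as intended.
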