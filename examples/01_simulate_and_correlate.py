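"""Simulate a multi-cohort study and build the correlation feature table.

Generates 8 cancer-type-like cohorts with 500 planted miRNA->gene effects,
computes per-cohort Pearson correlations over co-expressing samples, and
shows that planted pairs carry much stronger correlation signal than the
null background.
"""

import numpy as np

import mirtarget as mt

config = mt.SimulationConfig(seed=7)
panels, truth = mt.simulate_panels(config)
table = mt.build_feature_table(panels)

print(f"cohorts: {len(panels)}, samples/cohort: {len(panels[0].samples)}")
print(f"pairs retained: {table.n_pairs} ({table.n_dropped} dropped, "
      f"max {table.max_missing} missing cohorts allowed)")

planted = {(p.mirna, p.gene) for p in truth.pairs}
is_planted = table.values.index.isin(planted)
mean_abs_planted = float(table.values.abs()[is_planted].mean().mean())
mean_abs_null = float(table.values.abs()[~is_planted].mean().mean())
print(f"mean |r| planted pairs: {mean_abs_planted:.3f}")
print(f"mean |r| null pairs:    {mean_abs_null:.3f}")
# Planted pairs correlate strongly in their active cohorts; null pairs sit
# near zero, so the per-cohort correlation vector separates the classes.
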