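"""Accuracy as a function of the per-class gene number.

With 5 planted markers per class, cross-validated accuracy should rise
until the panel captures all markers (n = 5) and then plateau — the
saturating curve that motivates choosing a turning-point panel size.
"""

import toonet as tn

cfg = tn.SimulationConfig(n_classes=8, samples_per_class=[40] * 8,
                          n_genes=800, markers_per_class=5,
                          marker_effect=3.0, seed=21)
matrix, labels, _ = tn.simulate(cfg)
matrix = tn.normalize_by_sample_sum(matrix)

table = tn.sweep_feature_number(
    matrix, labels,
    tn.CVConfig(k=10, repeats=1, model_kind="logistic", seed=7),
    n_values=[1, 2, 3, 4, 5, 7, 10])

print(table.to_string(index=False,
                      formatters={"mean_accuracy": "{:.3f}".format}))
# The curve should flatten once n reaches the number of true markers per
# class; extra genes past that point add noise, not information.
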