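"""Generate a synthetic tumor cohort with planted tissue-of-origin markers.

The default configuration mirrors the 15-class reference cohort's unequal
class sizes (scaled to 750 samples), with 10 marker genes per class
upregulated 8-fold and 1,850 uninformative background genes.
"""

import toonet as tn

cfg = tn.SimulationConfig(seed=1)
matrix, labels, truth = tn.simulate(cfg)

print(f"cohort: {matrix.n_samples} samples x {matrix.n_genes} genes")
sizes = {c: labels.class_labels.count(c) for c in labels.classes()}
print(f"class sizes (min..max): {min(sizes.values())}..{max(sizes.values())}")
print(f"largest class: {max(sizes, key=sizes.get)}")
print(f"planted markers: {len(truth.all_markers())} "
      f"({cfg.markers_per_class} per class, {cfg.marker_effect}x fold-change)")
lib = matrix.values.sum(axis=1)
print(f"library size CV across samples: {lib.std() / lib.mean():.2f}")
# The class-size spread and library-size variation are what the normalization
# and stratified cross-validation downstream have to cope with.
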