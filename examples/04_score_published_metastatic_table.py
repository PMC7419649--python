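"""Score the bundled published 20-sample metastatic prediction table.

The table lists, for each metastatic sample, the class predicted by the
neural network, the class predicted by the logistic baseline, and the true
label.  Merged-class spellings (COADREAD vs "COAD + READ") are harmonized
before comparison.
"""

import toonet as tn
from toonet import reference

table = reference.load_metastatic_predictions()
for column in ("predicted_by_NN", "predicted_by_logistic"):
    acc = tn.prediction_table_accuracy(table, column)
    print(f"{column}: {acc:.0%} of {len(table)} metastatic samples correct")
# 80% vs 70%: the network generalizes to metastatic biopsies better than the
# logistic baseline trained on the same 150-gene panel.
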