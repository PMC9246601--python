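"""The evaluation metrics and stratified cross-validation.

Accuracy, macro one-vs-rest ROC AUC and Cohen's kappa (plain and
quadratic-weighted) from a confusion matrix / score table, plus
class-stratified fold assembly.
"""

import numpy as np

from swarmnas.evaluation import (
    accuracy_from_confusion,
    auc_ovr,
    cohen_kappa,
    stratified_kfold,
)

cm = np.array([[25, 5], [5, 15]])
print(f"accuracy: {accuracy_from_confusion(cm):.3f}")          # (25+15)/50
print(f"kappa:    {cohen_kappa(cm):.5f}")                      # po=0.8, pe=0.52
print(f"kappa_q:  {cohen_kappa(cm, 'quadratic'):.5f}")
# Binary quadratic weighting coincides with the unweighted value.

rng = np.random.default_rng(0)
labels = rng.integers(0, 3, 60)
scores = rng.random((60, 3))
macro, per_class = auc_ovr(scores, labels)
print(f"macro AUC on random scores: {macro:.3f}")  # near 0.5: no signal
print("per-class:", [f"{a:.3f}" for a in per_class])

folds = stratified_kfold(np.array([0] * 20 + [1] * 10), k=10, rng_seed=0)
print("fold sizes:", [len(f) for f in folds])
# every fold gets exactly 2 of class 0 + 1 of class 1
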