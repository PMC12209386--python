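"""The confusion-matrix metric suite and one-vs-all evaluation.

Builds the reported two- and three-class test confusions and derives every
scalar metric from them, then shows a ROC/AUC sweep on synthetic scores.
"""

import numpy as np

from subtremor import ConfusionMatrix, binary_metrics, one_vs_all_metrics, roc_auc

# two-class test outcome: 10/10 PD correct, 9/10 ET correct (1 ET -> PD)
cm2 = ConfusionMatrix(np.array([[10, 0], [1, 9]]), ["PD", "ET"])
m = binary_metrics(cm2, positive="PD")
print("PD vs ET:")
print(f"  accuracy {m.accuracy:.3f}  sensitivity {m.sensitivity:.3f}  "
      f"precision {m.precision:.3f}  specificity {m.specificity:.3f}  "
      f"FPR {m.fpr:.3f}")

# three-class outcome: normal 10/10, PD 9/10 (1 -> normal), ET 9/10 (1 -> normal)
cm3 = ConfusionMatrix(np.array([[10, 0, 0], [1, 9, 0], [1, 0, 9]]),
                      ["normal", "PD", "ET"])
print(f"three-class accuracy: {100 * cm3.n_correct / cm3.total:.1f}%")
for cls, ms in one_vs_all_metrics(cm3).items():
    print(f"  {cls:7s} vs rest: sensitivity {ms.sensitivity:.3f}  "
          f"precision {ms.precision:.3f}  F1 {ms.f1:.3f}  NPV {ms.npv:.3f}")

# ROC: scores that mostly (but not perfectly) rank positives above negatives
rng = np.random.default_rng(0)
labels = np.repeat([1, 0], 50)
scores = np.where(labels == 1, rng.normal(1.0, 0.7, 100), rng.normal(0.0, 0.7, 100))
roc = roc_auc(scores, labels)
print(f"ROC on noisy scores: AUC {roc.auc:.3f} "
      "(1.0 = perfect separation, 0.5 = chance)")
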