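"""The evaluation statistics on small worked examples.

Shows AUC with a DeLong confidence interval, the DeLong paired-AUC test,
the exact McNemar test on discordant pairs, Fisher's exact test on
localization contingency tables, and the Dice coefficient.
"""

import numpy as np

from wsus import (delong_test, dice_coefficient, fisher_exact_2x2,
                  mcnemar_exact, roc_auc)

labels = np.array([0, 0, 1, 1])
scores = np.array([0.1, 0.4, 0.35, 0.8])
est = roc_auc(scores, labels)
print(f"AUC of 4 hand-scored cases: {est.auc:.2f} "
      f"(3 of 4 malignant/benign pairs correctly ordered)")

rng = np.random.default_rng(0)
lab = np.r_[np.zeros(50, int), np.ones(50, int)]
arm1 = lab + rng.normal(0, 0.8, 100)
arm2 = lab + rng.normal(0, 0.8, 100)
res = delong_test(arm1, arm2, lab)
print(f"DeLong paired test: AUC {res.auc1:.3f} vs {res.auc2:.3f}, "
      f"z = {res.z:.2f}, p = {res.p:.3f} (same cases, correlated curves)")

print(f"exact McNemar, 10 vs 0 discordant pairs: p = {mcnemar_exact(10, 0):.5f}")
print(f"exact McNemar, 6 vs 6 discordant pairs:  p = {mcnemar_exact(6, 6):.2f}")

# localization contingency tables (correct/incorrect by class)
for table in [((99, 1), (100, 0)), ((96, 4), (98, 2)), ((97, 3), (100, 0))]:
    p = fisher_exact_2x2(np.array(table))
    print(f"Fisher exact on {table}: p = {p:.2f}")

a = np.zeros((20, 20), dtype=bool)
a[5:15, 5:15] = True
b = np.zeros((20, 20), dtype=bool)
b[8:18, 5:15] = True
print(f"Dice of two 100-px masks overlapping by 70 px: "
      f"{dice_coefficient(a, b):.2f}")
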