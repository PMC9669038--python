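"""Reader-vs-model statistics: metrics, AUC, t-tests, volume, crosstab.

The evaluation module consumes explicit confusion counts or call tables, so
reader-study results (per-radiologist accuracies, per-case calls) can be
compared against the model without re-running any imaging.
"""

import numpy as np

from sarcopipe import (
    ConfusionCounts,
    TumorGeometry,
    compare_groups,
    metrics,
    misdiagnosis_crosstab,
    roc_auc,
    tumor_volume,
)

# confusion counts for a hypothetical 63+200 patient evaluation
m = metrics(ConfusionCounts(tp=56, fn=7, tn=183, fp=17))
print(f"accuracy {m.accuracy:.1f}%  SS-Avg {m.ss_avg:.1f}%  "
      f"sensitivity {m.sensitivity:.1f}%  specificity {m.specificity:.1f}%")

# ROC over per-case scores
rng = np.random.default_rng(0)
scores = np.concatenate([rng.normal(2.0, 1.5, 63), rng.normal(-1.5, 1.5, 200)])
labels = np.array([True] * 63 + [False] * 200)
_, auc = roc_auc(scores, labels)
print(f"AUC of the score distribution: {auc:.4f}")

# per-reader accuracies, with and without model support
unaided = [71.0, 69.5, 72.8, 47.0, 48.9, 46.8]
aided = [83.1, 82.4, 83.8, 87.8, 88.1, 87.4]
t, p = compare_groups(aided, unaided, variance_rule="student")
print(f"aided vs unaided sensitivity: t = {t:.2f}, two-sided p = {p:.4f}")

# tumor volume from the three measured diameters (cm)
g = TumorGeometry(length=8.0, width=6.0, height=7.0)
print(f"volume, protocol formula:  {tumor_volume(g):.1f} cm^3")
print(f"volume, ellipsoid formula: {tumor_volume(g, 'ellipsoid'):.1f} cm^3")

# which cases each side gets wrong (majority of ensembles / readers)
model_calls = {"case1": [True] * 20 + [False] * 4, "case2": [True] * 18 + [False] * 6}
reader_calls = {"case1": [False] * 4 + [True] * 2, "case2": [False] * 5 + [True]}
labels = {"case1": "sarcoma_group", "case2": "leiomyoma"}
print("misdiagnosis crosstab:", misdiagnosis_crosstab(model_calls, reader_calls, labels))

# Each printed value is recomputed from its inputs at run time; the t-test
# compares the six readers' values as two independent samples.
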