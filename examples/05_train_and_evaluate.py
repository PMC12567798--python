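"""Train a gradient-boosted toxin classifier and score held-out data.

Uses the default synthetic benchmark (400/400 training, 100/100 test),
fallback PSSM profiles and training-data-mined motifs, then reports the
ten balanced performance measures on the held-out set.
"""

import numpy as np

from seqtox.classifier import predict, train
from seqtox.descriptors import featurize
from seqtox.evaluation import (
    auc_from_scores,
    counts_from_predictions,
    metrics_from_counts,
    round3,
)
from seqtox.motif_mining import discover_motifs
from seqtox.sequence_io import Dataset
from seqtox.synthetic_data import make_benchmark

bench = make_benchmark("default")
ms = discover_motifs(bench.train_pos, bench.train_neg, top_k=50)

train_ds = Dataset(bench.train_pos.records + bench.train_neg.records)
test_ds = Dataset(bench.test_pos.records + bench.test_neg.records)
y_tr = np.array([1] * 400 + [0] * 400)
y_te = np.array([1] * 100 + [0] * 100)

fm_tr = featurize(train_ds, motif_set=ms)
fm_te = featurize(test_ds, motif_set=ms)
print(f"feature matrix: {fm_tr.shape}")

model = train(fm_tr, y_tr, algorithm="xgboost", seed=1)
pred = predict(model, fm_te)
counts = counts_from_predictions(y_te, pred["label"].to_numpy())
report = metrics_from_counts(counts)
report.AUC = auc_from_scores(pred["probability"].to_numpy(), y_te)

print(f"held-out confusion counts: TP={counts.tp:.0f} TN={counts.tn:.0f} "
      f"FP={counts.fp:.0f} FN={counts.fn:.0f}")
for name, value in report.to_dict().items():
    print(f"  {name:>12} = {round3(value):.3f}")
# MCC is the balanced headline measure; OPM combines predictive values,
# class-wise recalls, accuracy and normalized MCC into one [0,1] score.
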