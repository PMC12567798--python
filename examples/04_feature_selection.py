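"""Run the four-stage feature-selection cascade on planted signal.

Five informative columns are hidden among noise; the cascade
(zero-variance removal, Pearson filter, graphical ensemble selection,
RFECV with the one-standard-error rule) should isolate them.
"""

import numpy as np
import pandas as pd

from seqtox.feature_selection import select_features

rng = np.random.default_rng(3)
n = 300
bits = rng.integers(0, 2, size=(n, 5))
y = (bits.sum(axis=1) >= 3).astype(int)  # majority vote of 5 latent bits
info = bits * 2.5 + rng.normal(size=(n, 5))
noise = rng.normal(size=(n, 60))
fm = pd.DataFrame(
    np.hstack([info, noise]),
    columns=[f"info{i}" for i in range(5)] + [f"noise{i}" for i in range(60)],
)
fm["duplicate_of_info0"] = fm["info0"]
fm["constant"] = 1.0

final, report, graph = select_features(
    fm, y, top_k=20, seed=0, n_members=10, n_estimators=60, cv_folds=5
)
for stage in report.stages:
    print(f"{stage.name:>18}: {stage.n_in:>3} in, {len(stage.dropped):>3} dropped, "
          f"{stage.n_out:>3} out")
print("final features:", final)
# expected: the constant and duplicated columns disappear in stages 1-2,
# and the five informative columns dominate the final set
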