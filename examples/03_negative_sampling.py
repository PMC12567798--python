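"""Build a balanced negative set by clustering and elbow selection.

Negatives vastly outnumber positives in real toxin data, so the
negative pool is clustered in feature space and each cluster
contributes representatives proportional to its size — rare sequence
families stay represented, unlike plain random undersampling.
"""

from seqtox.descriptors import DescriptorConfig, featurize
from seqtox.negative_sampling import elbow_select, kmeans_fit, sample_representatives, sse_curve
from seqtox.synthetic_data import SyntheticSpec, generate

pos, neg, _ = generate(SyntheticSpec(n_pos=40, n_neg=600, seed=5))
config = DescriptorConfig(families=("aac", "dpc", "groups"))  # quick profile
fm = featurize(neg, config)

curve = sse_curve(fm, range(2, 13), seed=0)
k = elbow_select(curve)
print("SSE by k:", {kk: round(v) for kk, v in sorted(curve.items())})
print(f"elbow-selected k = {k}")

model = kmeans_fit(fm, k, seed=0)
ids = sample_representatives(model, n_total=len(pos), seed=0)
print(f"sampled {len(ids)} negatives (one per positive) across {k} clusters")
print("cluster sizes:", model.cluster_sizes().tolist())
# every non-empty cluster contributes at least one representative
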