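"""Clean a FASTA file and extract the full descriptor matrix.

Builds a small synthetic dataset (with two deliberately invalid
records), applies the validity rules, and featurizes the survivors.
"""

from seqtox.descriptors import featurize
from seqtox.sequence_io import Dataset, ProteinRecord, clean_sequences
from seqtox.synthetic_data import SyntheticSpec, generate

pos, _, _ = generate(SyntheticSpec(n_pos=5, n_neg=1, seed=1))
records = list(pos.records)
records.append(ProteinRecord("too_short", "ACDEFGHIK"))
records.append(ProteinRecord("has_X", "ACDEFGHIKLMNPQRSTVWYX" * 2))
ds = Dataset(records)

clean, rejected = clean_sequences(ds)
print(f"kept {len(clean)} of {len(ds)} records")
for r in rejected:
    print(f"  rejected {r.id}: {r.reason}")

fm = featurize(clean)
print(f"feature matrix: {fm.shape[0]} sequences x {fm.shape[1]} features")
row = fm.iloc[0]
print(f"first sequence ({fm.index[0]}):")
for name in ["C", "CC", "Schneider.Xd.28", "PSSM_C", "length"]:
    print(f"  {name:>18} = {row[name]:.4f}")
# 'C' is the cysteine fraction, 'CC' the CC-dipeptide fraction — both
# elevated in toxin-like sequences; PSSM_C is the pooled conservation
# score for cysteine from the profile provider.
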