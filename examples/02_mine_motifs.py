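"""Mine discriminative minimotifs from labelled training sequences.

Motifs are literal substrings present in at least one toxin and absent
from every non-toxin; they become 50 binary features.  Mining uses
labels, so in cross-validation it must run inside each training fold.
"""

from seqtox.motif_mining import discover_motifs, encode_motifs
from seqtox.synthetic_data import make_benchmark

bench = make_benchmark("tiny")
ms = discover_motifs(bench.train_pos, bench.train_neg, top_k=50)
print(f"mined {len(ms)} motifs; top 5 by positive coverage:")
for m in ms.motifs[:5]:
    print(f"  {m:>6}  present in {ms.coverage[m]} of {len(bench.train_pos)} toxins")

seq = bench.train_pos.records[0].sequence
flags = encode_motifs(seq, ms)
print(f"first toxin sequence carries {int(flags.sum())} of the {len(ms)} motifs")
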