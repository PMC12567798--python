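"""Reproduce a method-comparison table from printed confusion counts.

Given TP/TN/FP/FN per method on a shared blind test set, the evaluation
module derives all count-based measures at three decimals — the
arithmetic behind published comparison tables.
"""

from seqtox.evaluation import ConfusionCounts, compare_table, format_table

blind_test = [
    ("final-predictor", ConfusionCounts(225, 457, 17, 54)),
    ("transformer-baseline", ConfusionCounts(203, 469, 5, 76)),
    ("rf-baseline", ConfusionCounts(194, 451, 23, 85)),
    ("weakest-baseline", ConfusionCounts(172, 278, 196, 107)),
]

table = compare_table(blind_test, n_inputs=753)
print(format_table(table))
# Note the transformer baseline's near-perfect PPV/specificity paired
# with much weaker NPV/sensitivity: a biased predictor. The OPM column
# penalizes exactly this imbalance.
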