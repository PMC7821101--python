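"""The marker-based mock screen: precision and group-score separation.

A 9:1 mixture of marker-negative cells (6,100 control barcodes) and
marker-positive cells (860 barcodes).  The marker is the phenotype:
detected positives are photoactivated 2,000 ms, true negatives 100 ms,
and barcodes are counted per sorted population.  Scoring 2-sgRNA groups
against the sorted-negative reference separates the two libraries.
"""

from optenrich import RunConfig, run_mock_screen

res = run_mock_screen(RunConfig(seed=1))
d = res.diagnostics
print(f"cells {d['cells']}, marker-positive {d['positive_cells']}, "
      f"detected {d['detected']}, sorted positive {d['sorted_positive']}")
print(f"photoactivation precision: {res.precision:.4f} "
      "(fraction of mCherry-positive cells that carry the marker)")
for ref in ("sorted_negative", "unanalyzed"):
    print(f"reference {ref:16s}: group AUC {res.auc[ref]:.4f}, "
          f"group-mean gap {res.gap[ref]:.1f} log2 units")
print("The sorted-negative reference outperforms the unanalyzed one because")
print("the unanalyzed sample still contains the positive subpopulation.")
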