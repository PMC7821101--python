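"""Score a tiny count table: epsilon, Mann-Whitney p, eta, eFDR hits.

The phenotypic score of an sgRNA is the depth-normalized log2 ratio of
its reads in the sorted sample over a reference, centered so the median
nontargeting score is exactly 0.  Gene scores combine the mean sgRNA
epsilon with a Mann-Whitney test against the nontargeting controls:
eta = |epsilon| * (-ln p).  Hits are called where eta clears an empirical
FDR computed from randomly regrouped sgRNAs.
"""

import numpy as np
import pandas as pd

from optenrich import CountTable, efdr_curve, phenotypic_scores
from optenrich.scoring import collapse_gene, score_genes, simulated_negatives

rng = np.random.default_rng(0)
n_genes, m = 30, 10
ids = [f"G{i:02d}_sg{j}" for i in range(n_genes) for j in range(m)]
ids += [f"NT_sg{j}" for j in range(22)]
gene = [f"G{i:02d}" for i in range(n_genes) for _ in range(m)] + ["NONTARGETING"] * 22
tss = [f"{g}_T1" if g != "NONTARGETING" else "" for g in gene]

base = rng.integers(150, 250, len(ids))
enriched = base.copy()
enriched[:m] = enriched[:m] * 6  # gene G00 is a planted hit
frame = pd.DataFrame({"gene": gene, "tss": tss,
                      "sorted": enriched, "reference": base},
                     index=pd.Index(ids, name="sgrna_id"))
table = CountTable(frame)

eps = phenotypic_scores(table, "sorted", "reference")
print(f"epsilon of hit sgRNAs:  {eps.iloc[:m].mean():.2f} (log2 units)")
print(f"epsilon of nontargeting median: {eps[table.nontargeting_ids].median():.3f}")

tss_scores = score_genes(eps, table.frame[["gene", "tss"]])
genes = collapse_gene(tss_scores)
simneg = simulated_negatives(eps, eps[table.nontargeting_ids].to_numpy(),
                             group_size=10, n_groups=3000, seed=1)
curve, hits = efdr_curve(genes["eta"].to_numpy(), simneg["eta"].to_numpy(),
                         target=0.001)
print(f"eta cutoff at eFDR <= 0.1%: {curve.chosen_cutoff:.2f}")
print("hits:", list(genes.index[hits]),
      f"(eta = {genes.loc[hits, 'eta'].iloc[0]:.1f})")
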