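"""Build the screening sgRNA library and simulate a transduced population.

The canonical library has 544 genes (481 with one transcription start
site, 63 with two), 10 sgRNAs per TSS, and 22 nontargeting controls —
6,092 sgRNAs total.  Cells receive at most one sgRNA (low-MOI contract);
hit-gene cells express the enlarged-nucleus phenotype with probability
penetrance x per-sgRNA efficacy.
"""

from optenrich import EffectModel, build_library, simulate_population_frame
from optenrich.library import default_efficacies

lib = build_library(481, 63, 10, 22, seed=0)
print(f"library: {len(lib.genes)} genes, {lib.n_sgrnas} sgRNAs "
      f"({len(lib.nontargeting_ids)} nontargeting)")

effects = EffectModel(
    hit_genes=frozenset(list(lib.genes)[:5]),
    effect_size=2.0,        # hit nuclei are drawn from a 2x-shifted area law
    penetrance=0.6,
    sgrna_efficacy=default_efficacies(lib, seed=0),
)
pop = simulate_population_frame(lib, effects, n_cells=50_000,
                                infected_fraction=0.95, seed=1)
infected = pop["sgrna_id"] != ""
carriers = pop["gene"].isin(effects.hit_genes)
print(f"cells: {len(pop)}, infected: {infected.mean():.1%}, "
      f"hit-sgRNA carriers: {carriers.sum()}")
print(f"phenotype rate among carriers: "
      f"{pop.loc[carriers, 'true_phenotype'].mean():.2f} "
      f"(penetrance x mean efficacy)")
print(f"median nucleus area: {pop['area_um2'].median():.0f} um^2; "
      f"carriers with phenotype: "
      f"{pop.loc[carriers & pop.true_phenotype, 'area_um2'].median():.0f} um^2")
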