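"""Select high-confidence interactors and quantify an siRNA screen.

The high-confidence tier requires >8-fold enrichment over the ligase-only
control in both biological replicates in at least one condition, >= 2
peptides, and no documented interaction with the bait. The screen effect
matrix expresses each readout under each knockdown as a fold change vs the
luciferase control siRNA (2^-ddCt, geometric mean over screen replicates).
"""

from proxilogic.calling import call_specific, select_hci
from proxilogic.networks import ppi_graph
from proxilogic.proteomics import log2_impute
from proxilogic.qpcr import cluster_effects, screen_effect_matrix
from proxilogic.simulate import (BAIT_PROTEIN, SimulationConfig,
                                 simulate_catalogs_ppi, simulate_ct_table,
                                 simulate_miniturbo)

config = SimulationConfig(seed=1)
table, design, truth = simulate_miniturbo(config)
matrix = log2_impute(table)
_, ppi_edges, _ = simulate_catalogs_ppi(config)
graph = ppi_graph(ppi_edges, score_cutoff=0.0)

calls = [call_specific(matrix, design, "wt", tr)
         for tr in ("untreated", "IL1")]
hci = select_hci(calls, matrix, design, ppi_known=graph,
                 bait_protein=BAIT_PROTEIN, ratio_threshold=8.0)
n_known = int(hci["known_interactor"].sum())
print(f"candidates {len(hci)}, selected {int(hci['selected'].sum())} "
      f"({n_known} excluded as already-documented interactors)")

ct, ct_truth = simulate_ct_table(config)
effects = screen_effect_matrix(ct, control_sirna="Luc", housekeeping="GUSB")
print("\nknockdown effects on readouts (fold change vs siLuc, IL-1):")
il1 = effects.xs("IL1", axis=1, level="treatment")
print(il1.loc[list(config.readout_genes)].round(2).to_string())

clusters = cluster_effects(il1.T, k=3, seed=config.seed)
print("\nknockdown clusters:",
      {k: int(v) for k, v in clusters.labels.items()})
print("\nRatios < 1 mark readouts that depend on the knocked-down "
      "regulator; the clusters group knockdowns with similar effects.")
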