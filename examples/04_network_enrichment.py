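"""Catalog annotation, first neighbors and subnetwork enrichment.

Interactors are annotated against transcription-factor / epigenetic
catalogs, known bait interactors are expanded to their first neighbors,
and the interactor subnetwork's edge count is tested against the
Chung-Lu degree-product null (Poisson tail).
"""

from proxilogic.calling import call_specific, specific_set
from proxilogic.networks import (annotate_catalog, build_subnetwork,
                                 known_and_neighbors, network_enrichment_p,
                                 ppi_graph)
from proxilogic.proteomics import log2_impute
from proxilogic.simulate import (BAIT_PROTEIN, SimulationConfig,
                                 simulate_catalogs_ppi, simulate_miniturbo)

config = SimulationConfig(seed=1)
table, design, _ = simulate_miniturbo(config)
matrix = log2_impute(table)
interactors = set()
for tr in ("untreated", "IL1"):
    interactors |= specific_set(call_specific(matrix, design, "wt", tr))
interactors -= {BAIT_PROTEIN}

catalog, ppi_edges, ppi_truth = simulate_catalogs_ppi(config)
labels, tallies = annotate_catalog(sorted(interactors), catalog)
print(f"{len(interactors)} interactors: "
      f"{tallies['fraction']['TF']:.0%} transcription factors, "
      f"{tallies['fraction'].get('epigenetic', 0):.0%} epigenetic regulators")
print("TF families:", tallies["tf_families"])

graph = ppi_graph(ppi_edges, score_cutoff=0.0)
known, redundant, unique, overlap = known_and_neighbors(interactors, graph,
                                                        BAIT_PROTEIN)
print(f"\n{len(known)} known bait interactors; {redundant} redundant "
      f"first neighbors, {len(unique)} unique, {len(overlap)} of them "
      f"inside the interactome")

sub, rate = build_subnetwork(interactors, graph)
enr = network_enrichment_p(sub.nodes, graph, mode="poisson")
print(f"\nsubnetwork: {enr.n_nodes} nodes ({rate:.0%} mapped), "
      f"{enr.m_observed} edges observed vs {enr.lam_expected:.1f} expected "
      f"-> p = {enr.p_value:.3g}")
print("\np below 0.05 would mean the interactors are more interconnected "
      "than random proteins of the same degrees.")
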