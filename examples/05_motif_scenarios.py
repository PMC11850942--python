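"""Motif co-occurrence under peak windows: direct, composite or tethered.

Scans bait and partner PWMs over 1000-bp windows around simulated ChIP
peak summits (exact score-distribution thresholds at p <= 1e-4), tests
bait-motif enrichment against the genome background, classifies each peak
into recruitment scenarios and annotates peaks to their nearest TSS.
"""

from proxilogic import motifs as M
from proxilogic.simulate import BAIT_PROTEIN, SimulationConfig, simulate_motif_genome

config = SimulationConfig(seed=1)
seqs, peaks, pwms, tss, truth = simulate_motif_genome(config)
windows = M.peak_windows(peaks, seqs, flank=config.window_flank)
hits = M.scan(windows, pwms, pvalue_threshold=1e-4)
print(f"{len(hits)} motif hits in {len(windows)} windows "
      f"({len(truth.motif_placements)} planted)")

bait_pwm = next(p for p in pwms if p.name == BAIT_PROTEIN)
pi0 = M.estimate_background_rate(seqs, bait_pwm, n_windows=2000, seed=1)
k = hits.loc[hits["motif_id"] == BAIT_PROTEIN, "peak_id"].nunique()
fold, p = M.enrichment_vs_background(k, len(windows), max(pi0, 1e-4))
print(f"bait motif: {k}/{len(windows)} windows vs background rate "
      f"{pi0:.3f} -> fold {fold:.2f}, p = {p:.2g}")

partner_ids = {p.name: [p.name] for p in pwms if p.name != BAIT_PROTEIN}
calls, fractions = M.classify_scenarios(hits, [BAIT_PROTEIN], partner_ids,
                                        peak_ids=list(peaks["name"]))
print("\nscenario fractions per partner:")
print(fractions.round(2).to_string())

peak_genes = M.annotate_peaks_to_genes(peaks, tss)
gm = M.gene_motif_table(hits, peak_genes)
print(f"\n{len(gm)} genes annotated to peaks; motif combinations:")
print(M.motif_combination_counts(gm).head(6).to_string())
print("\nComposite peaks carry bait + partner motifs (co-binding in cis); "
      "partner-only peaks suggest tethered recruitment of the bait "
      "through protein-protein interaction.")
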