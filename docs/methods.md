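# Methods

This note documents the models, estimators and numerical choices behind
`proxilogic`, what the synthetic-data generators do and do not emulate,
and where the design was genuinely open.

## Proximity-labeling interactor calling

The quantification unit is the protein group with per-sample raw
intensities (0 = not detected). Intensities are log2-transformed and
missing values replaced by a fixed constant (default 9), which models
detection-limit censoring: the constant must sit below the smallest
observed log2 intensity, and the code warns when it does not. No
between-sample normalization is applied to pulldown data — equalizing
column distributions would erase the bait-vs-control enrichment the
experiment is designed to produce.

Contrasts use the two-sided pooled-variance Student t with
df = nA + nB − 2. The replication unit defaults to all six columns per
group (2 biological × 3 technical replicates); averaging technical
replicates first (`replicate_unit: bio_mean`) is available because the
correct unit is debatable — technical replicates are not independent, so
the default slightly overstates df, which the high planted effect sizes
make immaterial here. Degenerate rows (zero pooled variance) give t = 0,
p = 1 at equal means and a p floored at 1e-300 otherwise. Raw p-values
are used for filtering (LFC ≥ 2 together with −log10 p ≥ 1.3, both
inclusive); no multiple-testing correction is applied, because the calling
rule conjoins three independent control contrasts (ligase-only EV,
no-doxycycline, no-biotin), which empirically suppresses the per-protein
false-call rate far below the nominal 5% of one test (see
`test_no_planting_yields_near_zero_false_calls`). Whether the mutant-bait
interactomes should be called against all three controls or EV only is
not determined by the calling rule itself; the default is all three, and
the `controls` argument switches it.

Dependence classification is pure set algebra over the wild-type,
DNA-binding-deficient (E/I) and dimerization-deficient (FL/DD)
interactomes. High-confidence selection computes per-biological-replicate
enrichment ratios 2^(mean bait − mean EV) with technical replicates
averaged on the log2 scale, and requires ratio > 8 (strict) in both
replicates in ≥ 1 condition, ≥ 2 peptides or an explicit allowlist, and
no documented bait edge in the supplied PPI network.

## qPCR screen

ΔCt subtracts the housekeeping gene's mean Ct per sample; replicate Ct
values aggregate by arithmetic mean (undetermined reactions are set to a
configurable ceiling, default 40). Effects of knockdowns are fold changes
2^−ΔΔCt against the control siRNA, computed separately per condition and
screen replicate and then combined by geometric mean — ratios are
multiplicative, so averaging on the log scale is the consistent choice
when the replicate-combination scale is not dictated. Clustering runs
k-means (k default 6, fixed seed, n_init 10) on log2 ratios over the rows
of the matrix passed in (transpose to cluster knockdowns); clusters are
relabeled by the leaf order of an average-linkage dendrogram of the
centroids under correlation distance, which makes labels deterministic
and permutation-stable. Correlation distance is undefined for constant
centroids; the code falls back to Euclidean in that degenerate case.
ChIP-qPCR recovery is 2^−(Ct_IP − Ct_1% input), on the
percent-of-1%-input scale (equal Cts → 1).

## Knockdown transcriptomics

NormExp models the observed spot intensity as x = s + b with
s ~ Exponential(α) and b ~ N(μ, σ²); the corrected value is
E[s | x] = μ_s|x + σ φ(z)/Φ(z), z = μ_s|x/σ, μ_s|x = x − μ − σ²/α,
computed in log space so it stays finite deep in the left tail, plus an
offset (default 1). Parameters are estimated per array by moments: μ, σ
from the negative-control spots (σ = 0 falls back to 1 with a warning),
α = mean(all probes) − μ floored at 1e-6. Moment estimation was chosen
over maximum likelihood / saddle-point refinements for transparency; the
conditional-expectation formula itself agrees with R limma's
`normexp.signal` to ~1e-5 and with direct numeric integration to < 1e-3
(tested). Quantile normalization maps each column onto the row-means of
the sorted columns, resolving ties by the average rank; it is idempotent.
Probe collapse keeps, per gene, the probe with maximal mean intensity
across samples, ties broken toward the lexicographically smaller probe id.
Unmapped probes are kept through normalization (control probes inform the
background fit) and dropped at collapse.

The moderated t shrinks the per-gene pooled variance toward a prior:
s̃² = (d₀ s₀² + d_g s²)/(d₀ + d_g), t̃ = LFC/(s̃·√(1/nA+1/nB)) with
d₀ + d_g degrees of freedom. (d₀, s₀²) are estimated by moment matching
on log s² with digamma/trigamma corrections and Newton inversion of the
trigamma — the same scheme limma's `fitFDist` uses, and the test suite
verifies exact agreement with `eBayes` (t and p to 1e-9). `d0_mode`
selects the empirical-Bayes estimate ("eb"), the ordinary t (d₀ = 0) or
fully pooled variance (d₀ = ∞, normal reference); the mode exists because
the exact moderation options (trend/robust fits) are a free choice in any
such analysis. The two-group contrast covers the design used here; array
weights and duplicate-spot correlation are intentionally out of scope.

Gene sets: stimulus-induced = up-regulated DEGs (LFC ≥ 1, −log10 p ≥ 1.3)
of stimulated vs unstimulated under the control siRNA;
knockdown-affected = stimulus-induced genes with
|log2(siControl/siTarget)| ≥ 1 in stimulated samples — the twofold rule
is two-sided because both directions count as "affected"; jointly
regulated = bait-affected ∩ partner-affected. Shift tests use the
Mann–Whitney U, exact for untied samples of ≤ 8 each, otherwise the
tie-corrected normal approximation with continuity correction.

## Network statistics

The subnetwork null is Chung–Lu: under degree sequence d and M background
edges, the expected induced edge count of node set S is
λ = Σ_{i<j∈S} min(1, d_i d_j / 2M), and p = P(Poisson(λ) ≥ m). This is a
documented, reproducible stand-in for proprietary database scorers whose
internals are unpublished; a degree-binned permutation mode (add-one
p-value over ≥ 1000 resamples, 10 quantile bins) validates it. Symbol
matching to catalogs is case-insensitive exact with no alias resolution;
the PPI evidence-score cutoff (default 0.4) is configurable. First
neighbor bookkeeping counts, for the known bait interactors K, all their
edges except those to the bait ("redundant"), deduplicates them
("unique") and intersects with the input interactome.

## Motif scanning

Coordinates are BED 0-based half-open throughout; windows are
[summit − 500, summit + 500), truncated and flagged at contig ends, with
the interval midpoint standing in when no summit column exists. PWMs are
pseudocount-smoothed (default 0.25) position probability matrices; scores
are Σ log2(p_i(b)/q(b)); N-containing offsets are skipped; the reverse
strand is scored by the reverse-complemented matrix, and the reported
offset is the forward-strand match start. The hit threshold per PWM is
derived from the exact null score distribution: a dynamic program over
positions convolving integer-discretized scores (granularity 1e-3 bits)
with background weights. Because per-position rounding can shift a word's
grid score by up to half a grain, all comparisons between float scores
and grid scores carry a slack of granularity × (w/2 + 0.5); two genuinely
distinct word scores are never that close in practice. The DP tail agrees
with exhaustive 4^w enumeration to 1e-9 for w ≤ 6 (tested).

The background hit rate π₀ is estimated from uniformly sampled genome
windows (seeded, default 10,000) rather than an analytic composition —
operationally equivalent to scanning the whole genome at desk scale.
Enrichment is the one-sided binomial tail P(Bin(n, π₀) ≥ k). For scenario
calls, overlapping hits of one PWM collapse to a presence boolean; peaks
are assigned to the nearest TSS (ties keep all tied genes).

## Synthetic data

All generators are pure functions of (config, seed); each draws from its
own stream keyed by (seed, generator name), so adding one generator never
perturbs another. Defaults encode the study design the package targets:

- **Proteomics**: 2 biological × 3 technical replicates; baits EV / wt /
  E_I / FL_DD × untreated / IL-1, plus no-dox, no-biotin and parental
  controls; 2000 background proteins, log2 baseline N(18, 2.5); 12
  planted interactors in each of 5 dependence classes
  (independent, DNA-binding-dependent, dimerization-dependent, both,
  IL-1-specific), elevated by 6 log2 only in the bait/treatment
  combinations their class dictates; bait protein maximally enriched in
  bait-expressing samples. Biological noise sd 0.5 log2, technical noise
  sd 0.25 (technical replicates share the biological draw). Left-censoring
  at a hard detection floor (log2 = 14 > impute constant 9) reports
  sub-floor values as missing — matching what constant imputation assumes,
  not missing-at-random. Baseline spread and floor were chosen once so a
  few percent of values are censored, as on real runs. Per-protein
  intensity distributions of real instruments are not emulated
  (no peptide-level effects, no batch drift); passing tests demonstrate
  the statistics, not instrument realism.
- **Ct tables**: Ct = baseline − log2(relative expression) + N(0, 0.15);
  planted knockdown efficacy 0.25 on the target's own transcript; readouts
  respond to regulators through a planted dependency matrix; 3 screen
  replicates × 2 qPCR replicates; IL-1 induces readouts by 3 log2.
- **Expression arrays**: intensity = truncated-normal background
  (μ 50, σ 10) + exponential-like signal; 1–2 probes per gene plus 100
  negative-control probes; 2 arrays per condition; planted induction
  3 + Exponential(1) log2 — heterogeneous across genes, since
  between-gene effect spread is exactly what the co-regulation
  correlation measures; bait-dependent genes lose induction under bait
  knockdown, co-regulated genes under either knockdown.
- **Motif genomes**: 2 × 30 kb at GC 0.41; consensus words planted at
  recorded offsets/strands under peaks cycling through composite /
  bait-only / partner-only / none scenarios.
- **Catalogs/PPI**: preferential-attachment (Barabási–Albert) graph over
  planted interactors + background proteins; exactly 47% of planted
  interactors carry a TF-family label and 20% an epigenetic label; 10
  known bait edges planted to exercise the novelty rule.

Ground truth serializes to JSON beside every written dataset
(`write_dataset` emits TSV/FASTA/BED/PFM/JSON plus a manifest).

## Pipeline and problem sizes

`pipeline.run_all` executes every stage in dependency order on one seed
and reports all counts; the default simulated run completes in a few
seconds on one CPU. The acceptance script uses the generator defaults
above (2000 background proteins, 1500 genes, 40 peaks, 2000 background
windows for π₀, 5000 permutations for the toy network) — sizes chosen so
the whole reproduction stays interactive while keeping the planted-truth
recovery rates stable across seeds.

## Known limitations

- The t-test replication unit treats technical replicates as independent
  (see above); the bio_mean mode is the conservative alternative.
- NormExp moment estimation is less efficient than MLE for very dim
  arrays; with ≥ 10 negative controls per array it is adequate.
- The Chung–Lu/Poisson null ignores degree correlations and clustering;
  the permutation mode is the check.
- Nearest-TSS assignment is a deliberate simplification of
  promoter/enhancer annotation; no distance cutoff is applied.
- Catalog matching does not resolve gene-symbol aliases.
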