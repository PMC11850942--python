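"""Synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here: a
label-free protein-quantification table from a miniTurbo proximity-labeling
design with bait variants and negative-control classes, qPCR Ct tables with
planted knockdown efficacies, probe-level expression matrices with planted
stimulus-induced and co-regulated gene sets, small genomes with motifs
planted under peak windows, and transcription-factor / epigenetic catalogs
with a scale-free protein-protein-interaction graph.

All generators are pure functions of (config, seed): a fixed seed yields
byte-identical output. Each generator draws from its own random stream
(see :mod:`proxilogic._rng`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stream
from .proteomics import ProteinQuantTable

BAITS = ("EV", "wt", "E_I", "FL_DD")
TREATMENTS = ("untreated", "IL1")
CONTROL_CLASSES = ("full_labeling", "no_dox", "no_biotin", "parental")

#: Bait-mutant dependence classes for planted interactors. Membership in the
#: bait-variant interactomes follows the biology of the two point mutants:
#: a DNA-binding-dependent partner is lost with the DNA-binding-deficient
#: mutant (E_I), a dimerization-dependent partner with the
#: dimerization-deficient mutant (FL_DD).
DEPENDENCE_CLASSES = (
    "independent",
    "dna_binding_dependent",
    "dimerization_dependent",
    "both",
    "condition_specific",
)

# which bait variants retain the planted interaction, per class
_CLASS_BAITS = {
    "independent": {"wt", "E_I", "FL_DD"},
    "dna_binding_dependent": {"wt", "FL_DD"},
    "dimerization_dependent": {"wt", "E_I"},
    "both": {"wt"},
    "condition_specific": {"wt", "E_I", "FL_DD"},
}

BAIT_PROTEIN = "BAIT_RELA"


@dataclass
class SimulationConfig:
    """Study-design parameters shared by the generators.

    The defaults encode the proximity-labeling design this package targets:
    two biologically independent experiments with three technical replicates
    per sample, four expression constructs (ligase-only EV, wild-type bait,
    DNA-binding-deficient E_I, dimerization-deficient FL_DD), an IL-1
    stimulation arm, and three negative-control classes (EV full labeling,
    no doxycycline, no biotin) plus parental cells.
    """

    seed: int = 0
    n_background_proteins: int = 2000
    n_planted_per_class: int = 12
    effect_size_log2: float = 6.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 18.0
    baseline_sd_log2: float = 2.5
    detection_floor_log2: float = 14.0
    impute_value: float = 9.0
    n_bio_replicates: int = 2
    n_tech_replicates: int = 3
    baits: tuple = BAITS
    treatments: tuple = TREATMENTS
    control_classes: tuple = CONTROL_CLASSES
    # qPCR screen
    sirna_targets: tuple = ("RELA", "HCI01", "HCI02", "HCI03", "HCI04", "HCI05")
    readout_genes: tuple = ("IL8", "NFKBIA", "CXCL2")
    housekeeping_gene: str = "GUSB"
    control_sirna: str = "Luc"
    kd_efficacy: float = 0.25
    ct_noise_sd: float = 0.15
    n_screen_replicates: int = 3
    n_ct_replicates: int = 2
    il1_induction_log2: float = 3.0
    # expression arrays
    n_genes: int = 1500
    n_negative_control_probes: int = 100
    n_induced_genes: int = 100
    n_bait_dependent_genes: int = 40
    n_coregulated_genes: int = 20
    expression_effect_log2: float = 3.0
    expression_noise_sd: float = 0.25
    n_arrays_per_condition: int = 2
    # motif genome
    n_chromosomes: int = 2
    chromosome_length: int = 30_000
    gc_content: float = 0.41
    n_peaks: int = 40
    n_tss_genes: int = 40
    window_flank: int = 500
    # catalogs / PPI
    n_catalog_proteins: int = 600
    ppi_attachment: int = 3
    tf_fraction: float = 0.47

    def validate(self) -> None:
        counts = {
            "n_background_proteins": self.n_background_proteins,
            "n_bio_replicates": self.n_bio_replicates,
            "n_tech_replicates": self.n_tech_replicates,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_planted_per_class < 0:
            raise ValueError("n_planted_per_class must be >= 0")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be > 0")
        if self.detection_floor_log2 <= self.impute_value:
            raise ValueError(
                "detection_floor_log2 must exceed the impute constant so "
                "imputed values sit strictly below observed ones"
            )
        if not 0 < self.kd_efficacy <= 1:
            raise ValueError("kd_efficacy must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth recorded next to every simulated dataset."""

    planted_interactors: dict = field(default_factory=dict)  # protein -> class
    bait_protein: str = BAIT_PROTEIN
    knockdown_efficacies: dict = field(default_factory=dict)  # sirna -> efficacy
    dependency_matrix: dict = field(default_factory=dict)  # readout -> {regulator: ratio}
    induced_genes: list = field(default_factory=list)
    bait_dependent_genes: list = field(default_factory=list)
    coregulated_genes: list = field(default_factory=list)
    coregulation_partner: str = ""
    motif_placements: list = field(default_factory=list)  # dicts: peak, motif, offset, strand
    peak_scenarios: dict = field(default_factory=dict)  # peak -> scenario
    known_bait_edges: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# proximity-labeling proteomics
# ---------------------------------------------------------------------------

def _sample_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for treatment in config.treatments:
        for bio in range(1, config.n_bio_replicates + 1):
            for tech in range(1, config.n_tech_replicates + 1):
                for bait in config.baits:
                    rows.append((f"{bait}_{treatment}_b{bio}_t{tech}",
                                 bait, treatment, "full_labeling", bio, tech))
                rows.append((f"nodox_{treatment}_b{bio}_t{tech}",
                             "wt", treatment, "no_dox", bio, tech))
                rows.append((f"nobiotin_{treatment}_b{bio}_t{tech}",
                             "wt", treatment, "no_biotin", bio, tech))
                rows.append((f"parental_{treatment}_b{bio}_t{tech}",
                             "parental", treatment, "parental", bio, tech))
    return pd.DataFrame(
        rows, columns=["sample", "bait", "treatment", "control_class",
                       "bio_rep", "tech_rep"],
    )


def simulate_miniturbo(config: SimulationConfig):
    """Simulate a proximity-labeling protein-quantification experiment.

    Background proteins are drawn log-normal in every sample including the
    negative controls (non-specific labeling). Planted interactors are
    elevated by ``effect_size_log2`` only in the bait/treatment combinations
    their dependence class dictates; the bait protein itself is maximally
    enriched in all bait-expressing full-labeling samples. Log2 intensities
    below ``detection_floor_log2`` are reported as 0 (left-censoring at the
    detection limit).

    Returns (ProteinQuantTable, SampleDesign DataFrame, GroundTruth).
    """
    config.validate()
    rng = stream(config.seed, "miniturbo")
    design = _sample_design(config)

    protein_ids = [f"BG{i:05d}" for i in range(config.n_background_proteins)]
    truth = GroundTruth()
    for cls in DEPENDENCE_CLASSES:
        for j in range(config.n_planted_per_class):
            pid = f"INT_{cls}_{j:02d}"
            protein_ids.append(pid)
            truth.planted_interactors[pid] = cls
    protein_ids.append(BAIT_PROTEIN)
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("duplicate protein ids")

    n_prot = len(protein_ids)
    n_samp = len(design)
    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2,
                          size=n_prot)

    # planted effect per (protein, sample)
    effect = np.zeros((n_prot, n_samp))
    bait_expressing = (
        design["control_class"].to_numpy() == "full_labeling"
    ) & (design["bait"].isin(["wt", "E_I", "FL_DD"]).to_numpy())
    for i, pid in enumerate(protein_ids):
        if pid == BAIT_PROTEIN:
            effect[i, bait_expressing] = config.effect_size_log2 + 4.0
            continue
        cls = truth.planted_interactors.get(pid)
        if cls is None:
            continue
        in_bait = design["bait"].isin(_CLASS_BAITS[cls]).to_numpy() & (
            design["control_class"].to_numpy() == "full_labeling")
        if cls == "condition_specific":
            in_bait &= design["treatment"].to_numpy() == "IL1"
        effect[i, in_bait] = config.effect_size_log2

    # biological noise shared by technical replicates; independent technical
    # noise at half the biological sd
    group_key = design[["bait", "treatment", "control_class", "bio_rep"]].apply(
        tuple, axis=1)
    groups = {g: np.flatnonzero(group_key == g) for g in group_key.unique()}
    log2 = np.empty((n_prot, n_samp))
    for g, cols in groups.items():
        bio = rng.normal(0.0, config.noise_sd_log2, size=n_prot)
        tech = rng.normal(0.0, config.noise_sd_log2 / 2.0,
                          size=(n_prot, len(cols)))
        log2[:, cols] = baseline[:, None] + effect[:, cols] + bio[:, None] + tech

    raw = np.power(2.0, log2)
    raw[log2 < config.detection_floor_log2] = 0.0

    peptides = rng.poisson(10, size=n_prot) + 1
    # a few planted interactors are single-peptide identifications, so the
    # peptide rule of high-confidence selection is exercised
    planted_idx = [i for i, p in enumerate(protein_ids)
                   if p in truth.planted_interactors]
    if planted_idx:
        single = rng.choice(planted_idx, size=max(1, len(planted_idx) // 20),
                            replace=False)
        peptides[single] = 1

    intensities = pd.DataFrame(raw, index=protein_ids,
                               columns=design["sample"].tolist())
    annotations = pd.DataFrame({
        "majority_ids": [[f"{p}_UP"] for p in protein_ids],
        "gene_names": [[p] for p in protein_ids],
        "peptides": peptides,
        "reverse": False,
        "contaminant": False,
        "site_only": False,
    }, index=protein_ids)
    table = ProteinQuantTable(annotations=annotations, intensities=intensities)
    return table, design, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(config: SimulationConfig):
    """Simulate a qPCR Ct table for a targeted siRNA screen.

    Ct values follow ``baseline − log2(relative expression) + noise``.
    Each planted knockdown multiplies its own transcript by the configured
    efficacy; readout genes respond to regulator knockdowns according to a
    planted dependency matrix (ratio < 1 means the readout depends on the
    regulator). IL-1 stimulation induces the readout genes.

    Returns (long-format CtTable DataFrame, GroundTruth).
    """
    config.validate()
    rng = stream(config.seed, "ct_table")
    genes = list(dict.fromkeys(
        list(config.readout_genes) + [config.housekeeping_gene]
        + list(config.sirna_targets)))
    base_ct = {g: rng.uniform(18.0, 28.0) for g in genes}

    truth = GroundTruth()
    sirnas = [config.control_sirna] + list(config.sirna_targets)
    for s in config.sirna_targets:
        truth.knockdown_efficacies[s] = config.kd_efficacy
    # planted dependency: each readout depends on RELA plus one other
    # regulator; remaining knockdowns leave it untouched
    regs = [s for s in config.sirna_targets if s != "RELA"]
    for i, readout in enumerate(config.readout_genes):
        dep = {"RELA": 0.3}
        if regs:
            dep[regs[i % len(regs)]] = 0.4
        truth.dependency_matrix[readout] = dep

    rows = []
    for treatment in config.treatments:
        for sirna in sirnas:
            for screen_rep in range(1, config.n_screen_replicates + 1):
                sample = f"si{sirna}_{treatment}_r{screen_rep}"
                for gene in genes:
                    mult = 1.0
                    if gene in config.readout_genes:
                        if treatment == "IL1":
                            mult *= 2.0 ** config.il1_induction_log2
                        dep = truth.dependency_matrix[gene]
                        if sirna in dep:
                            eff = truth.knockdown_efficacies.get(sirna, 1.0)
                            # knockdown removes (1-eff) of the regulator;
                            # the readout drops toward its dependency ratio
                            mult *= dep[sirna] + (1 - dep[sirna]) * eff
                    if gene == sirna:
                        mult *= truth.knockdown_efficacies.get(sirna, 1.0)
                    ct0 = base_ct[gene] - np.log2(mult)
                    for rep in range(1, config.n_ct_replicates + 1):
                        rows.append((gene, sample, sirna, treatment,
                                     screen_rep, rep,
                                     ct0 + rng.normal(0.0, config.ct_noise_sd)))
    ct = pd.DataFrame(rows, columns=["gene", "sample", "sirna", "treatment",
                                     "screen_rep", "replicate", "ct"])
    return ct, truth


# ---------------------------------------------------------------------------
# expression arrays
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig):
    """Simulate a probe-level single-channel expression experiment.

    Probe intensities are a non-negative normal background plus an
    exponential-like signal. Genes carry one or two probes; negative-control
    probes carry no gene assignment. Planted stimulus-induced genes gain
    ``expression_effect_log2`` under IL-1 with the control siRNA;
    bait-dependent genes lose the induction under bait knockdown, and
    co-regulated genes lose it under either the bait or the partner
    knockdown.

    Returns (ExpressionMatrix, GroundTruth).
    """
    from .transcriptome import ExpressionMatrix

    config.validate()
    rng = stream(config.seed, "expression")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    truth = GroundTruth()
    truth.induced_genes = genes[: config.n_induced_genes]
    truth.bait_dependent_genes = genes[: config.n_bait_dependent_genes]
    truth.coregulated_genes = genes[: config.n_coregulated_genes]
    truth.coregulation_partner = "PARTNER"

    sirnas = ["Luc", "RELA", "PARTNER"]
    samples = [f"si{s}_{t}_a{a}" for s in sirnas for t in config.treatments
               for a in range(1, config.n_arrays_per_condition + 1)]
    meta = pd.DataFrame(
        [(s.split("_")[0][2:], s.split("_")[1]) for s in samples],
        index=samples, columns=["sirna", "treatment"])

    # per-gene baseline signal on log2 scale; induction magnitudes vary
    # between genes (log2 fold >= the configured effect), as they do on
    # real arrays — gene-to-gene spread is what the co-regulation
    # correlation measures
    base = rng.normal(7.0, 1.2, size=config.n_genes)
    induction = config.expression_effect_log2 + rng.exponential(
        1.0, size=config.n_genes)
    lfc = np.zeros((config.n_genes, len(samples)))
    il1 = (meta["treatment"] == "IL1").to_numpy()
    si = meta["sirna"].to_numpy()
    for gi, g in enumerate(genes):
        if g not in set(truth.induced_genes):
            continue
        induced_in = il1.copy()
        if g in set(truth.coregulated_genes):
            induced_in &= si == "Luc"
        elif g in set(truth.bait_dependent_genes):
            induced_in &= si != "RELA"
        lfc[gi, induced_in] = induction[gi]

    probes, probe_gene, rows = [], [], []
    for gi, g in enumerate(genes):
        n_probes = 1 + (gi % 2)
        for p in range(n_probes):
            pid = f"P{gi:05d}_{p}"
            probes.append(pid)
            probe_gene.append(g)
            affinity = rng.normal(0.0, 0.3)
            noise = rng.normal(0.0, config.expression_noise_sd,
                               size=len(samples))
            sig = np.power(2.0, base[gi] + affinity + lfc[gi] + noise)
            rows.append(sig)
    signal = np.vstack(rows)
    # negative-control probes: background only
    for j in range(config.n_negative_control_probes):
        probes.append(f"NEG{j:04d}")
        probe_gene.append("")
    signal = np.vstack([signal, np.zeros((config.n_negative_control_probes,
                                          len(samples)))])
    background = np.clip(
        rng.normal(50.0, 10.0, size=signal.shape), 0.0, None)
    intensities = pd.DataFrame(background + signal, index=probes,
                               columns=samples)
    em = ExpressionMatrix(
        intensities=intensities,
        probe_gene=pd.Series(probe_gene, index=probes),
        is_negative_control=pd.Series(
            [g == "" for g in probe_gene], index=probes),
        sample_meta=meta,
    )
    return em, truth


# ---------------------------------------------------------------------------
# motif genome
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _consensus_pwm(name: str, consensus: str, strength: float = 0.85):
    from .motifs import PWM
    w = len(consensus)
    probs = np.full((w, 4), (1 - strength) / 3)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = strength
    return PWM(name=name, probs=probs)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


DEFAULT_MOTIFS = {
    "BAIT_RELA": "GGGAATTTCC",
    "PARTNER_TFE3": "CACGTGAC",
    "PARTNER_GLIS2": "GACCCCCCGC",
}


def simulate_motif_genome(config: SimulationConfig):
    """Simulate a small genome with motifs planted under peak windows.

    Random background sequence at the configured GC content; consensus words
    of the bait and partner motifs are planted at recorded offsets and
    strands within the +/-``window_flank`` bp windows of chosen peak summits.
    Peaks are assigned composite / bait-only / partner-only / none scenarios
    round-robin. Genes are placed with recorded TSS coordinates near peaks.

    Returns (sequences dict, peaks DataFrame, PWM list, TSS DataFrame,
    GroundTruth).
    """
    config.validate()
    rng = stream(config.seed, "motif_genome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {}
    for c in range(1, config.n_chromosomes + 1):
        seq = rng.choice(4, size=config.chromosome_length, p=p)
        sequences[f"chr{c}"] = "".join(_BASES[seq])

    pwms = [_consensus_pwm(name, cons) for name, cons in DEFAULT_MOTIFS.items()]
    partner_names = [n for n in DEFAULT_MOTIFS if n != "BAIT_RELA"]

    truth = GroundTruth()
    chroms = sorted(sequences)
    flank = config.window_flank
    peaks = []
    scenarios = ["composite", "bait_only", "partner_only", "none"]
    spacing = config.chromosome_length // (config.n_peaks // len(chroms) + 1)
    mutable = {c: list(sequences[c]) for c in chroms}
    for i in range(config.n_peaks):
        chrom = chroms[i % len(chroms)]
        summit = flank + spacing * (i // len(chroms)) + spacing // 2
        if summit + flank >= config.chromosome_length:
            continue
        pid = f"peak{i:03d}"
        scen = scenarios[i % len(scenarios)]
        to_plant = []
        if scen in ("composite", "bait_only"):
            to_plant.append("BAIT_RELA")
        if scen in ("composite", "partner_only"):
            # partners rotate with the scenario block, so every partner
            # appears in both composite and partner-only peaks
            to_plant.append(
                partner_names[(i // len(scenarios)) % len(partner_names)])
        for motif in to_plant:
            cons = DEFAULT_MOTIFS[motif]
            offset = int(rng.integers(-flank + 10, flank - 10 - len(cons)))
            strand = "+" if rng.random() < 0.5 else "-"
            word = cons if strand == "+" else _revcomp(cons)
            start = summit + offset
            mutable[chrom][start:start + len(word)] = list(word)
            truth.motif_placements.append(
                {"peak": pid, "motif": motif, "offset": offset,
                 "strand": strand, "chrom": chrom, "start": start})
        truth.peak_scenarios[pid] = scen
        peaks.append((chrom, summit - flank, summit + flank, pid, summit))
    sequences = {c: "".join(mutable[c]) for c in chroms}
    peaks = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name",
                                         "summit"])

    tss_rows = []
    for j in range(config.n_tss_genes):
        chrom = chroms[j % len(chroms)]
        pos = int(rng.integers(0, config.chromosome_length))
        tss_rows.append((f"TSSG{j:03d}", chrom, pos,
                         "+" if rng.random() < 0.5 else "-"))
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])
    return sequences, peaks, pwms, tss, truth


# ---------------------------------------------------------------------------
# catalogs and PPI
# ---------------------------------------------------------------------------

TF_FAMILIES = ("C2H2 ZF", "bZIP", "bHLH", "Homeodomain", "Nuclear receptor",
               "Rel", "Forkhead")
EPI_ROLES = ("writer", "reader", "eraser", "remodeler")
EPI_COMPLEXES = ("SWI/SNF", "NuRD", "PRC2", "SAGA", "COMPASS")


def simulate_catalogs_ppi(config: SimulationConfig):
    """Simulate TF / epigenetic-regulator catalogs and a scale-free PPI graph.

    Proteins receive at most one TF-family label and at most one epigenetic
    role/complex label. The PPI graph is generated by preferential
    attachment (heavy-tailed degree distribution); a set of known
    bait-interactor edges is planted and recorded in the ground truth.

    Returns (catalog DataFrame, PPI edge DataFrame, GroundTruth).
    """
    config.validate()
    rng = stream(config.seed, "catalogs_ppi")
    # the catalog/PPI universe covers the planted interactors (same id
    # scheme as simulate_miniturbo) plus background proteins
    planted = [f"INT_{cls}_{j:02d}" for cls in DEPENDENCE_CLASSES
               for j in range(config.n_planted_per_class)]
    n_bg = max(config.n_catalog_proteins - len(planted), 0)
    proteins = planted + [f"BG{i:05d}" for i in range(n_bg)]

    # exactly tf_fraction of the planted interactors carry a TF label, so
    # a perfect interactor call recovers that fraction; background
    # proteins get labels at the same rates
    n_tf_planted = int(round(config.tf_fraction * len(planted)))
    tf_proteins = planted[:n_tf_planted]
    n_epi_planted = int(round(0.2 * len(planted)))
    epi_proteins = planted[n_tf_planted:n_tf_planted + n_epi_planted]
    bg = proteins[len(planted):]
    n_tf_bg = int(round(config.tf_fraction * len(bg)))
    tf_proteins = tf_proteins + list(
        rng.choice(bg, size=n_tf_bg, replace=False))
    remaining = [p for p in bg if p not in set(tf_proteins)]
    n_epi_bg = int(round(0.2 * len(bg)))
    epi_proteins = epi_proteins + list(
        rng.choice(remaining, size=min(n_epi_bg, len(remaining)),
                   replace=False))
    rows = []
    for p in tf_proteins:
        rows.append((p, "TF", TF_FAMILIES[int(rng.integers(len(TF_FAMILIES)))],
                     "none", ""))
    for p in epi_proteins:
        rows.append((p, "epigenetic", "",
                     EPI_ROLES[int(rng.integers(len(EPI_ROLES)))],
                     EPI_COMPLEXES[int(rng.integers(len(EPI_COMPLEXES)))]))
    catalog = pd.DataFrame(rows, columns=["symbol", "catalog", "family",
                                          "role", "complexes"])

    g = nx.barabasi_albert_graph(config.n_catalog_proteins,
                                 config.ppi_attachment,
                                 seed=int(rng.integers(2**31)))
    mapping = dict(enumerate(proteins))
    g = nx.relabel_nodes(g, mapping)
    truth = GroundTruth()
    # documented (known) bait interactors are planted interactors when
    # available, so the novelty rule of high-confidence selection bites
    pool = planted if len(planted) >= 10 else proteins
    known = list(rng.choice(pool, size=min(10, len(pool)), replace=False))
    edges = []
    for a, b in g.edges():
        edges.append((a, b, float(np.round(rng.uniform(0.4, 1.0), 3))))
    for kprot in known:
        edges.append((BAIT_PROTEIN, kprot,
                      float(np.round(rng.uniform(0.7, 1.0), 3))))
        truth.known_bait_edges.append(kprot)
    ppi = pd.DataFrame(edges, columns=["protein_a", "protein_b", "score"])
    return catalog, ppi, truth


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate every input and write it under ``outdir`` with a manifest.

    Tables are written as TSV, sequences as FASTA, peaks as BED (0-based
    half-open), motifs as JASPAR-style PFM text and ground truth as JSON.
    Returns the manifest mapping artifact names to relative paths.
    """
    from .motifs import write_jaspar
    from .proteomics import write_protein_groups

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    table, design, pt = simulate_miniturbo(config)
    write_protein_groups(table, outdir / "proteinGroups.tsv")
    design.to_csv(outdir / "sample_design.tsv", sep="\t", index=False)
    (outdir / "truth_proteomics.json").write_text(pt.to_json())
    manifest.update(proteinGroups="proteinGroups.tsv",
                    sample_design="sample_design.tsv",
                    truth_proteomics="truth_proteomics.json")

    ct, ctt = simulate_ct_table(config)
    ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    (outdir / "truth_ct.json").write_text(ctt.to_json())
    manifest.update(ct_table="ct_table.tsv", truth_ct="truth_ct.json")

    em, et = simulate_expression(config)
    em.to_tsv(outdir / "expression.tsv")
    (outdir / "truth_expression.json").write_text(et.to_json())
    manifest.update(expression="expression.tsv",
                    truth_expression="truth_expression.json")

    seqs, peaks, pwms, tss, mt = simulate_motif_genome(config)
    with open(outdir / "genome.fasta", "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    write_jaspar(pwms, outdir / "motifs.pfm")
    tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    (outdir / "truth_motifs.json").write_text(mt.to_json())
    manifest.update(genome="genome.fasta", peaks="peaks.bed",
                    motifs="motifs.pfm", tss="tss.tsv",
                    truth_motifs="truth_motifs.json")

    catalog, ppi, kt = simulate_catalogs_ppi(config)
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    (outdir / "truth_ppi.json").write_text(kt.to_json())
    manifest.update(catalog="catalog.tsv", ppi="ppi.tsv",
                    truth_ppi="truth_ppi.json")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
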