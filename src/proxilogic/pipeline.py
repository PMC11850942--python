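"""End-to-end pipeline orchestration with a validated config and run report.

``run_all`` executes every stage in dependency order on a simulated (or
previously written) dataset: proteomics ingestion and interactor calling
per bait and treatment, Venn partitions and dependence classification,
catalog/network annotation, high-confidence selection, the siRNA screen
effect matrix and clustering, knockdown transcriptomics and gene sets,
subnetwork enrichment, and motif scenario classification. The resulting
RunReport holds every stage count and echoes the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import calling, motifs, networks, qpcr, transcriptome
from .proteomics import log2_impute, read_protein_groups, read_sample_design
from .simulate import (BAIT_PROTEIN, GroundTruth, SimulationConfig,
                       simulate_catalogs_ppi, simulate_ct_table,
                       simulate_expression, simulate_miniturbo,
                       simulate_motif_genome)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds, mode switches and paths for a pipeline run."""

    seed: int = 0
    # thresholds (legend defaults)
    lfc_proteomics: float = 2.0
    p_log: float = 1.3
    lfc_deg: float = 1.0
    kd_fold: float = 2.0
    hci_ratio: float = 8.0
    min_peptides: int = 2
    # modes
    replicate_unit: str = "all"       # all | bio_mean
    d0_mode: str = "eb"               # eb | none | pooled
    network_null: str = "poisson"     # poisson | permutation
    screen_k: int = 6
    motif_pvalue: float = 1e-4
    # inputs (None -> simulate)
    input_dir: str = None
    simulate: dict = field(default_factory=dict)

    _THRESHOLDS = ("lfc_proteomics", "p_log", "lfc_deg", "kd_fold",
                   "hci_ratio", "min_peptides", "motif_pvalue")

    def validate(self) -> "PipelineConfig":
        for name in self._THRESHOLDS:
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be > 0")
        if self.replicate_unit not in ("all", "bio_mean"):
            raise ConfigError(f"unknown replicate_unit: {self.replicate_unit}")
        if self.d0_mode not in ("eb", "none", "pooled"):
            raise ConfigError(f"unknown d0_mode: {self.d0_mode}")
        if self.network_null not in ("poisson", "permutation"):
            raise ConfigError(f"unknown network_null: {self.network_null}")
        return self


def validate_config(source) -> PipelineConfig:
    """Load and validate a config from YAML path, mapping or PipelineConfig.

    Unknown keys are rejected by name; thresholds must be positive.
    """
    if isinstance(source, PipelineConfig):
        return source.validate()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)
             if not f.name.startswith("_")}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return PipelineConfig(**data).validate()
    except TypeError as exc:
        raise ConfigError(str(exc))


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    def summary(self) -> str:
        lines = [f"proxilogic {self.version} run (seed {self.seed})"]
        for key in sorted(self.counts):
            lines.append(f"  {key}: {self.counts[key]}")
        return "\n".join(lines)


def run_all(config, outdir=None, simulate: bool = True) -> RunReport:
    """Run every pipeline stage in dependency order; return the RunReport.

    With ``simulate`` (default) the inputs come from the synthetic-data
    generators under the configured seed; otherwise ``config.input_dir``
    must point at a directory written by :func:`proxilogic.simulate.write_dataset`.
    """
    cfg = validate_config(config)
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate)
    counts = {}

    # --- proteomics: ingest + interactor calling -------------------------
    if simulate:
        table, design, prot_truth = simulate_miniturbo(sim_cfg)
    else:
        if not cfg.input_dir:
            raise DataError("input_dir required when simulate is off")
        indir = Path(cfg.input_dir)
        pg = indir / "proteinGroups.tsv"
        if not pg.exists():
            raise DataError(f"missing input: {pg}")
        design = read_sample_design(indir / "sample_design.tsv")
        table = read_protein_groups(pg, design=design)
        prot_truth = GroundTruth.from_json(
            (indir / "truth_proteomics.json").read_text())
    matrix = log2_impute(table, impute=sim_cfg.impute_value)

    call_sets = {}
    for bait in ("wt", "E_I", "FL_DD"):
        for treatment in ("untreated", "IL1"):
            calls = calling.call_specific(
                matrix, design, bait, treatment,
                lfc_threshold=cfg.lfc_proteomics,
                neg_log10_p_threshold=cfg.p_log)
            s = calling.specific_set(calls) - {BAIT_PROTEIN}
            call_sets[(bait, treatment)] = s
            counts[f"interactors_{bait}_{treatment}"] = len(s)

    venn = calling.venn_partition({
        "untreated": call_sets[("wt", "untreated")],
        "IL1": call_sets[("wt", "IL1")]})
    counts["interactors_union_wt"] = venn.union_size
    dependence = {
        tr: calling.classify_dependence(call_sets[("wt", tr)],
                                        call_sets[("E_I", tr)],
                                        call_sets[("FL_DD", tr)])
        for tr in ("untreated", "IL1")}
    for tr, labels in dependence.items():
        counts[f"dependence_labels_{tr}"] = {
            lab: sum(v == lab for v in labels.values())
            for lab in sorted(set(labels.values()))}

    # --- catalogs, known interactors, HCI --------------------------------
    catalog, ppi_edges, ppi_truth = simulate_catalogs_ppi(sim_cfg)
    graph = networks.ppi_graph(ppi_edges, score_cutoff=0.0)
    union_set = call_sets[("wt", "untreated")] | call_sets[("wt", "IL1")]
    _, tallies = networks.annotate_catalog(sorted(union_set), catalog)
    counts["tf_fraction_of_interactors"] = round(
        tallies["fraction"].get("TF", 0.0), 4)
    known, redundant, unique, overlap = networks.known_and_neighbors(
        union_set, graph, BAIT_PROTEIN)
    counts["known_interactors"] = len(known)
    counts["redundant_neighbors"] = redundant
    counts["unique_neighbor_overlap"] = len(overlap)

    wt_calls = [calling.call_specific(matrix, design, "wt", tr,
                                      cfg.lfc_proteomics, cfg.p_log)
                for tr in ("untreated", "IL1")]
    hci = calling.select_hci(wt_calls, matrix, design, ppi_known=graph,
                             bait="wt", bait_protein=BAIT_PROTEIN,
                             ratio_threshold=cfg.hci_ratio,
                             min_peptides=cfg.min_peptides)
    hci_set = set(hci.index[hci["selected"]]) - {BAIT_PROTEIN} \
        if len(hci) else set()
    counts["hci_selected"] = len(hci_set)

    # --- siRNA screen -----------------------------------------------------
    ct, ct_truth = simulate_ct_table(sim_cfg)
    effects = qpcr.screen_effect_matrix(
        ct, control_sirna=sim_cfg.control_sirna,
        housekeeping=sim_cfg.housekeeping_gene,
        readout_genes=list(sim_cfg.readout_genes))
    clusters = qpcr.cluster_effects(effects.T, k=cfg.screen_k, seed=cfg.seed)
    counts["screen_clusters"] = int(clusters.labels.nunique())
    counts["screen_knockdowns"] = int(effects.shape[1] // 2)

    # --- knockdown transcriptomics ---------------------------------------
    em, expr_truth = simulate_expression(sim_cfg)
    corrected, _ = transcriptome.normexp_correct(em, offset=1.0)
    log_q = transcriptome.quantile_normalize(np.log2(corrected))
    genes = transcriptome.collapse_probes(log_q, em.probe_gene)
    meta = em.sample_meta

    def samples(sirna, treatment):
        sel = (meta["sirna"] == sirna) & (meta["treatment"] == treatment)
        return list(meta.index[sel])

    induced = transcriptome.moderated_t(
        genes, samples("Luc", "IL1"), samples("Luc", "untreated"),
        d0_mode=cfg.d0_mode)
    kd_ratios = {
        target: transcriptome.knockdown_ratios(
            genes, samples("Luc", "IL1"), samples(target, "IL1"))
        for target in ("RELA", "PARTNER")}
    gene_sets = transcriptome.define_gene_sets(
        induced, kd_ratios, bait="RELA", lfc_threshold=cfg.lfc_deg,
        neg_log10_p_threshold=cfg.p_log,
        kd_log2_threshold=float(np.log2(cfg.kd_fold)))
    for name, s in gene_sets.items():
        counts[f"geneset_{name}"] = len(s)
    corr = transcriptome.correlate_effects(
        kd_ratios["RELA"], kd_ratios["PARTNER"],
        {"all": list(genes.index),
         "stimulus_induced": sorted(gene_sets["stimulus_induced"]),
         "jointly_regulated": sorted(
             gene_sets.get("jointly_regulated_PARTNER", set()))})
    counts["pearson_r_jointly_regulated"] = (
        round(float(corr.loc["jointly_regulated", "r"]), 4)
        if "jointly_regulated" in corr.index else None)

    # --- subnetwork enrichment -------------------------------------------
    # planted co-regulated genes have no PPI entry in the synthetic graph;
    # use the interactor union as the demonstration subnetwork
    sub, rate = networks.build_subnetwork(union_set, graph)
    enr = networks.network_enrichment_p(
        sub.nodes, graph, mode=cfg.network_null, seed=cfg.seed)
    counts["subnetwork_nodes"] = enr.n_nodes
    counts["subnetwork_edges"] = enr.m_observed
    counts["subnetwork_mapping_rate"] = round(rate, 4)
    counts["network_p"] = float(enr.p_value)

    # --- motif scenarios ---------------------------------------------------
    seqs, peaks, pwms, tss, motif_truth = simulate_motif_genome(sim_cfg)
    windows = motifs.peak_windows(peaks, seqs, flank=sim_cfg.window_flank)
    hits = motifs.scan(windows, pwms, pvalue_threshold=cfg.motif_pvalue)
    partner_ids = {p.name: [p.name] for p in pwms if p.name != BAIT_PROTEIN}
    scen, frac = motifs.classify_scenarios(
        hits, [BAIT_PROTEIN], partner_ids,
        peak_ids=list(peaks["name"]))
    counts["motif_hits"] = int(len(hits))
    counts["scenario_fractions"] = {
        partner: {s: round(float(v), 4) for s, v in row.items()}
        for partner, row in frac.iterrows()}
    peak_genes = motifs.annotate_peaks_to_genes(peaks, tss)
    gm = motifs.gene_motif_table(hits, peak_genes)
    counts["genes_with_peaks"] = int(len(gm))

    report = RunReport(config=dataclasses.asdict(cfg), seed=cfg.seed,
                       version=__version__, counts=counts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report.summary() + "\n")
        (outdir / "config_resolved.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(cfg)))
    return report
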