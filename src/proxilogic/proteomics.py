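"""Ingestion of label-free protein-quantification tables.

Reads proteinGroups-style TSV output of a label-free quantification run,
maps intensity columns to a sample design, log2-transforms intensities and
imputes missing (zero) values with a constant that sits below the detection
limit. No between-sample normalization is applied: pulldown experiments
are left unnormalized on purpose, to preserve the enrichment differences
between bait and control samples that the downstream tests quantify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: proteinGroups.txt-style column names
_PG_COLUMNS = {
    "majority_ids": "Majority protein IDs",
    "gene_names": "Gene names",
    "peptides": "Peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
}
QC_FLAGS = ("reverse", "contaminant", "site_only")


class ParseError(ValueError):
    """Raised when an input table does not match the expected dialect."""


@dataclass
class ProteinQuantTable:
    """Protein-group intensity table.

    ``annotations`` is indexed by protein-group id and carries majority
    protein IDs, gene symbols (both as lists), peptide counts and the three
    QC flags. ``intensities`` shares the index and holds one raw-intensity
    column per sample (0 = not detected).
    """

    annotations: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self):
        if not self.annotations.index.equals(self.intensities.index):
            raise ValueError("annotations and intensities must share an index")
        if self.annotations.index.has_duplicates:
            raise ParseError("duplicate protein group id")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if (vals < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def samples(self) -> list:
        return list(self.intensities.columns)

    def flagged(self, flags=QC_FLAGS) -> pd.Series:
        """Boolean Series: row carries any of the given QC flags."""
        mask = pd.Series(False, index=self.annotations.index)
        for f in flags:
            mask |= self.annotations[f].astype(bool)
        return mask


@dataclass
class LogIntensityMatrix:
    """Protein x sample log2 intensities with an imputation mask."""

    values: pd.DataFrame
    mask: pd.DataFrame  # True where the value was imputed
    impute_value: float = 9.0
    peptides: pd.Series = field(default=None)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("no missing values allowed after imputation")


def read_protein_groups(path, design: pd.DataFrame = None,
                        dialect: str = "proteinGroups",
                        intensity_prefix: str = "Intensity ") -> ProteinQuantTable:
    """Read a protein-quantification TSV.

    ``dialect='proteinGroups'`` expects the standard tab-separated layout
    with "Majority protein IDs", "Gene names", "Peptides", the three QC
    columns (marked with "+") and one "Intensity <sample>" column per
    sample; ``dialect='wide'`` expects an ``id`` column, the annotation
    columns by their internal names and bare sample columns. Rows flagged
    reverse / contaminant / site-only are marked, not dropped. If a sample
    design is given, intensity columns must exactly match its sample ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "proteinGroups":
        missing = [c for c in _PG_COLUMNS.values() if c not in df.columns]
        if missing:
            raise ParseError(f"missing required column(s): {', '.join(missing)}")
        idx = df["id"] if "id" in df.columns else df.index.astype(str)
        ann = pd.DataFrame({
            "majority_ids": df[_PG_COLUMNS["majority_ids"]].fillna("").str.split(";"),
            "gene_names": df[_PG_COLUMNS["gene_names"]].fillna("").str.split(";"),
            "peptides": pd.to_numeric(df[_PG_COLUMNS["peptides"]]).astype(int),
            "reverse": df[_PG_COLUMNS["reverse"]].fillna("") == "+",
            "contaminant": df[_PG_COLUMNS["contaminant"]].fillna("") == "+",
            "site_only": df[_PG_COLUMNS["site_only"]].fillna("") == "+",
        })
        ann.index = idx.to_numpy()
        int_cols = [c for c in df.columns if c.startswith(intensity_prefix)
                    and c != "Intensity"]
        inten = df[int_cols].apply(pd.to_numeric)
        inten.columns = [c[len(intensity_prefix):] for c in int_cols]
        inten.index = ann.index
    elif dialect == "wide":
        required = ["id", "majority_ids", "gene_names", "peptides",
                    "reverse", "contaminant", "site_only"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"missing required column(s): {', '.join(missing)}")
        ann = pd.DataFrame({
            "majority_ids": df["majority_ids"].fillna("").str.split(";"),
            "gene_names": df["gene_names"].fillna("").str.split(";"),
            "peptides": pd.to_numeric(df["peptides"]).astype(int),
            "reverse": df["reverse"].astype(str).isin(["True", "+", "1"]),
            "contaminant": df["contaminant"].astype(str).isin(["True", "+", "1"]),
            "site_only": df["site_only"].astype(str).isin(["True", "+", "1"]),
        })
        ann.index = df["id"].to_numpy()
        sample_cols = [c for c in df.columns if c not in required]
        inten = df[sample_cols].apply(pd.to_numeric)
        inten.index = ann.index
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if design is not None:
        extra = set(inten.columns) - set(design["sample"])
        absent = set(design["sample"]) - set(inten.columns)
        if extra or absent:
            raise ParseError(
                f"sample columns do not match design (not in design: "
                f"{sorted(extra)}; missing from table: {sorted(absent)})")
        inten = inten[list(design["sample"])]
    return ProteinQuantTable(annotations=ann, intensities=inten)


def write_protein_groups(table: ProteinQuantTable, path,
                         intensity_prefix: str = "Intensity ") -> None:
    """Write a table back to the proteinGroups-style TSV dialect."""
    ann = table.annotations
    out = pd.DataFrame({
        "id": ann.index,
        _PG_COLUMNS["majority_ids"]: [";".join(x) for x in ann["majority_ids"]],
        _PG_COLUMNS["gene_names"]: [";".join(x) for x in ann["gene_names"]],
        _PG_COLUMNS["peptides"]: ann["peptides"].to_numpy(),
        _PG_COLUMNS["reverse"]: np.where(ann["reverse"], "+", ""),
        _PG_COLUMNS["contaminant"]: np.where(ann["contaminant"], "+", ""),
        _PG_COLUMNS["site_only"]: np.where(ann["site_only"], "+", ""),
    })
    for s in table.samples:
        out[f"{intensity_prefix}{s}"] = table.intensities[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_design(path) -> pd.DataFrame:
    """Read a sample-design TSV and validate replicate uniqueness."""
    design = pd.read_csv(path, sep="\t")
    required = ["sample", "bait", "treatment", "control_class", "bio_rep",
                "tech_rep"]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise ParseError(f"missing design column(s): {', '.join(missing)}")
    key = design[["bait", "treatment", "control_class", "bio_rep", "tech_rep"]]
    if key.duplicated().any():
        raise ParseError("duplicate (bait, treatment, control_class, bio, "
                         "tech) combination in design")
    return design


def log2_impute(table: ProteinQuantTable, impute: float = 9.0) -> LogIntensityMatrix:
    """Log2-transform intensities; impute zeros with a fixed constant.

    The impute constant is meant to sit below the lowest measured intensity
    (detection-limit censoring); if it does not, a warning is emitted and
    values are left as computed. No normalization is applied.
    """
    raw = table.intensities.to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("negative intensity")
    mask = raw == 0
    with np.errstate(divide="ignore"):
        log2 = np.log2(raw)
    log2[mask] = impute
    observed = log2[~mask]
    if observed.size and impute >= observed.min():
        warnings.warn(
            f"impute constant {impute} is not below the smallest observed "
            f"log2 intensity {observed.min():.3f}", UserWarning)
    values = pd.DataFrame(log2, index=table.intensities.index,
                          columns=table.intensities.columns)
    return LogIntensityMatrix(
        values=values,
        mask=pd.DataFrame(mask, index=values.index, columns=values.columns),
        impute_value=impute,
        peptides=table.annotations["peptides"].copy(),
    )


def filter_qc(table: ProteinQuantTable, drop_flags=QC_FLAGS) -> ProteinQuantTable:
    """Drop rows carrying any of the given QC flags."""
    keep = ~table.flagged(drop_flags) if drop_flags else pd.Series(
        True, index=table.annotations.index)
    return ProteinQuantTable(annotations=table.annotations[keep].copy(),
                             intensities=table.intensities[keep].copy())


def aggregate_bio_replicates(matrix: LogIntensityMatrix,
                             design: pd.DataFrame) -> pd.DataFrame:
    """Mean of technical replicates on the log2 scale, per biological replicate.

    Returns a protein x group matrix with MultiIndex columns
    (bait, treatment, control_class, bio_rep).
    """
    cols = {}
    for key, sub in design.groupby(["bait", "treatment", "control_class",
                                    "bio_rep"]):
        cols[key] = matrix.values[sub["sample"].tolist()].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["bait", "treatment", "control_class", "bio_rep"])
    return out
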