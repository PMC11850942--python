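"""qPCR quantification for the targeted siRNA screen and ChIP-qPCR.

Relative expression follows the comparative-Ct convention: Ct values are
normalized against a housekeeping gene (ΔCt = Ct_gene − Ct_housekeeping)
and fold changes between conditions are 2^−ΔΔCt. Knockdown-effect matrices
are computed against a control siRNA, averaged across screen replicates on
the ratio scale (geometric mean), clustered by k-means, and ordered by
hierarchical clustering of the cluster centroids. ChIP recoveries are
expressed as percent of a 1% input aliquot: % input = 2^−(Ct_IP − Ct_1%input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

CT_CEILING = 40.0


def _aggregate_ct(ct: pd.DataFrame, ct_ceiling: float = CT_CEILING) -> pd.DataFrame:
    """Arithmetic mean of replicate Ct values per (gene, sample).

    Undetermined Ct values (NaN, no amplification) are set to the ceiling
    before averaging.
    """
    df = ct.copy()
    df["ct"] = df["ct"].fillna(ct_ceiling).clip(upper=ct_ceiling)
    return df.groupby(["gene", "sample"], sort=False)["ct"].mean().unstack(
        "sample")


def delta_ct(ct: pd.DataFrame, housekeeping: str = "GUSB") -> pd.DataFrame:
    """ΔCt per (gene, sample): mean Ct(gene) − mean Ct(housekeeping).

    ``ct`` is a long table with columns gene, sample, replicate, ct.
    """
    mean_ct = _aggregate_ct(ct)
    if housekeeping not in mean_ct.index:
        raise ValueError(f"housekeeping gene {housekeeping!r} missing")
    hk = mean_ct.loc[housekeeping]
    if hk.isna().any():
        bad = list(hk.index[hk.isna()])
        raise ValueError(f"housekeeping Ct missing for sample(s): {bad}")
    return mean_ct.sub(hk, axis=1)


def fold_change(dct_test, dct_ref):
    """Relative fold change 2^−(ΔCt_test − ΔCt_ref)."""
    return 2.0 ** -(np.asarray(dct_test, dtype=float)
                    - np.asarray(dct_ref, dtype=float))


def percent_input(ct_ip, ct_input_1pct):
    """ChIP-qPCR recovery relative to a 1% input aliquot.

    % input = 2^−(Ct_IP − Ct_1%input), reported on the percent-of-1%-input
    scale (equal Cts → 1).
    """
    return 2.0 ** -(np.asarray(ct_ip, dtype=float)
                    - np.asarray(ct_input_1pct, dtype=float))


def screen_effect_matrix(ct: pd.DataFrame, control_sirna: str = "Luc",
                         housekeeping: str = "GUSB",
                         readout_genes=None) -> pd.DataFrame:
    """Knockdown-effect matrix of a multi-replicate siRNA screen.

    ``ct`` is long-format with columns gene, sample, sirna, treatment,
    screen_rep, replicate, ct. For every treatment and screen replicate,
    each readout's ΔCt under each knockdown is compared with the control
    siRNA (fold change 2^−ΔΔCt); screen replicates are averaged on the
    ratio scale (geometric mean). Returns a readout-gene × (siRNA,
    treatment) DataFrame; the control-siRNA columns are identically 1.
    Readouts missing for a knockdown stay NaN (absent, not zero). The
    knockdown target's own transcript row doubles as the efficiency QC.
    """
    meta = ct[["sample", "sirna", "treatment", "screen_rep"]].drop_duplicates()
    meta = meta.set_index("sample")
    dct = delta_ct(ct, housekeeping=housekeeping)
    genes = (list(readout_genes) if readout_genes is not None
             else [g for g in dct.index if g != housekeeping])

    log_ratios = {}
    for (treatment, rep), sub in meta.groupby(["treatment", "screen_rep"]):
        by_sirna = {s: idx for s, idx in sub.groupby("sirna").groups.items()}
        if control_sirna not in by_sirna:
            raise ValueError(f"control siRNA {control_sirna!r} missing for "
                             f"{treatment} replicate {rep}")
        ctrl_sample = sub.index[sub["sirna"] == control_sirna][0]
        for sirna in by_sirna:
            sample = sub.index[sub["sirna"] == sirna][0]
            dd = dct.loc[genes, sample] - dct.loc[genes, ctrl_sample]
            log_ratios.setdefault((sirna, treatment), []).append(-dd)
    cols = {}
    for key, reps in log_ratios.items():
        cols[key] = 2.0 ** pd.concat(reps, axis=1).mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["sirna", "treatment"])
    return out.sort_index(axis=1)


@dataclass
class ClusterResult:
    labels: pd.Series          # observation -> cluster id (centroid-ordered)
    centroids: pd.DataFrame    # cluster id x feature, in leaf order
    leaf_order: list           # cluster ids as ordered by the dendrogram


def cluster_effects(effect: pd.DataFrame, k: int = 6, seed: int = 0,
                    n_init: int = 10) -> ClusterResult:
    """K-means clustering of knockdown-effect patterns, dendrogram-ordered.

    Rows of ``effect`` are the observations (transpose first to cluster the
    knockdowns of a readout × knockdown matrix). Clustering runs on log2
    ratios with Euclidean distance and a fixed seed; clusters are then
    ordered by average-linkage hierarchical clustering of the centroids
    under correlation distance, and relabeled 0..k−1 in leaf order so the
    assignment is deterministic.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.log2(effect.to_numpy(dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("effect matrix must be strictly positive and finite")
    k = min(k, len(effect))
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw_labels = km.fit_predict(x)
    if k == 1:
        order = [0]
    else:
        cent = km.cluster_centers_
        # correlation distance is undefined for constant centroids; fall
        # back to Euclidean in that degenerate case
        if np.allclose(cent.std(axis=1), 0) or cent.shape[1] < 2:
            dist = pdist(cent, metric="euclidean")
        else:
            dist = pdist(cent, metric="correlation")
            dist = np.nan_to_num(dist, nan=1.0)
        link = hierarchy.linkage(dist, method="average")
        order = list(hierarchy.leaves_list(link))
    relabel = {old: new for new, old in enumerate(order)}
    labels = pd.Series([relabel[l] for l in raw_labels], index=effect.index,
                       name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=range(k), columns=effect.columns)
    return ClusterResult(labels=labels, centroids=centroids,
                         leaf_order=list(range(k)))
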