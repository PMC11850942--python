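"""Catalog annotation and protein-interaction-network statistics.

Interactor sets are annotated against transcription-factor and
epigenetic-regulator catalogs, flagged for documented bait interactions,
expanded to first neighbors, and assembled into induced subnetworks whose
edge counts are tested against a degree-aware null model (Chung–Lu
degree-product expectation with a Poisson tail, or a degree-binned
permutation).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def load_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").fillna("")
    required = ["symbol", "catalog", "family", "role", "complexes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing catalog column(s): {', '.join(missing)}")
    return df


def annotate_catalog(proteins, catalog: pd.DataFrame):
    """Annotate proteins against TF / epigenetic catalogs.

    Symbol matching is case-insensitive exact. Returns (per-protein label
    DataFrame, tally dict). Tallies count per family, role and complex and
    give the fraction of the input found in each catalog; proteins absent
    from every catalog are labeled "unclassified". A protein present in
    both catalogs is counted once per catalog.
    """
    proteins = list(proteins)
    cat = catalog.copy()
    cat["_sym"] = cat["symbol"].str.upper()
    per_cat = {c: g.set_index("_sym") for c, g in cat.groupby("catalog")}
    rows = []
    for p in proteins:
        key = str(p).upper()
        row = {"protein": p, "tf_family": "", "epi_role": "",
               "epi_complexes": "", "catalogs": []}
        for cname, sub in per_cat.items():
            if key in sub.index:
                rec = sub.loc[key]
                if isinstance(rec, pd.DataFrame):
                    rec = rec.iloc[0]
                row["catalogs"].append(cname)
                if cname == "TF":
                    row["tf_family"] = rec["family"]
                else:
                    row["epi_role"] = rec["role"]
                    row["epi_complexes"] = rec["complexes"]
        if not row["catalogs"]:
            row["catalogs"] = ["unclassified"]
        rows.append(row)
    labels = pd.DataFrame(rows).set_index("protein")
    n = len(proteins)
    tallies = {
        "n_input": n,
        "fraction": {c: sum(c in r for r in labels["catalogs"]) / n if n else 0.0
                     for c in list(per_cat) + ["unclassified"]},
        "tf_families": labels.loc[labels["tf_family"] != "", "tf_family"]
        .value_counts().to_dict(),
        "epi_roles": labels.loc[labels["epi_role"] != "", "epi_role"]
        .value_counts().to_dict(),
        "epi_complexes": labels.loc[labels["epi_complexes"] != "",
                                    "epi_complexes"].value_counts().to_dict(),
    }
    return labels, tallies


# ---------------------------------------------------------------------------
# PPI graphs
# ---------------------------------------------------------------------------

def load_ppi(path, score_cutoff: float = 0.4) -> nx.Graph:
    """Load an undirected PPI edge list (TSV: protein_a, protein_b, score).

    Edges below the evidence-score cutoff are dropped; self-loops are
    removed and duplicate edges collapse to the maximal score.
    """
    df = pd.read_csv(path, sep="\t")
    return ppi_graph(df, score_cutoff=score_cutoff)


def ppi_graph(edges: pd.DataFrame, score_cutoff: float = 0.4) -> nx.Graph:
    g = nx.Graph()
    for a, b, s in edges[["protein_a", "protein_b", "score"]].itertuples(
            index=False):
        if a == b or s < score_cutoff:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=float(s))
    return g


def known_and_neighbors(interactor_set, ppi: nx.Graph, bait):
    """Known bait interactors, their redundant neighbors, and the overlap.

    K = members of the input set with a documented edge to the bait.
    The redundant neighbor count sums the degrees of K excluding their
    edges to the bait; the unique neighbors are that multiset deduplicated
    (bait excluded), and the overlap is their intersection with the input
    set.  Returns (K, redundant_count, unique_neighbors, overlap).
    """
    interactors = set(interactor_set)
    if bait not in ppi:
        return set(), 0, set(), set()
    known = interactors & set(ppi.neighbors(bait))
    redundant = 0
    unique = set()
    for k in known:
        nbrs = set(ppi.neighbors(k)) - {bait}
        redundant += len(nbrs)
        unique |= nbrs
    return known, redundant, unique, unique & interactors


def build_subnetwork(gene_set, ppi: nx.Graph):
    """Induced subgraph on the mapped symbols of a gene set.

    Returns (subgraph, mapping_rate) where the mapping rate is the fraction
    of the input found as nodes of the background network.
    """
    genes = set(gene_set)
    mapped = genes & set(ppi.nodes)
    sub = ppi.subgraph(mapped).copy()
    rate = len(mapped) / len(genes) if genes else 0.0
    return sub, rate


@dataclass
class NetworkEnrichment:
    n_nodes: int
    m_observed: int
    lam_expected: float
    p_value: float
    mode: str
    background_edges: int


def network_enrichment_p(nodes, background: nx.Graph, mode: str = "poisson",
                         n_permutations: int = 1000, seed: int = 0,
                         n_degree_bins: int = 10) -> NetworkEnrichment:
    """Test whether a node set carries more edges than a degree-aware null.

    Poisson mode: the expected edge count is the Chung–Lu degree-product
    sum λ = Σ_{i<j} min(1, d_i d_j / 2M) over node pairs (d = degree in the
    background network of M edges) and p = P(Poisson(λ) ≥ m). Permutation
    mode resamples node sets of the same degree-bin composition and reports
    the add-one empirical tail.
    """
    missing = set(nodes) - set(background.nodes)
    if missing:
        raise ValueError(f"nodes absent from background: {sorted(missing)}")
    nodes = sorted(set(nodes))
    sub = background.subgraph(nodes)
    m = sub.number_of_edges()
    M = background.number_of_edges()
    deg = dict(background.degree())
    d = np.array([deg[v] for v in nodes], dtype=float)
    if len(nodes) >= 2 and M > 0:
        prod = np.minimum(1.0, np.outer(d, d) / (2.0 * M))
        lam = float(np.triu(prod, k=1).sum())
    else:
        lam = 0.0

    if mode == "poisson":
        if m == 0:
            p = 1.0
        else:
            p = float(stats.poisson.sf(m - 1, lam)) if lam > 0 else P_FLOOR
            p = max(p, P_FLOOR)
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        all_nodes = list(background.nodes)
        degrees = np.array([deg[v] for v in all_nodes], dtype=float)
        # degree-binned resampling: quantile bins over the background
        qs = np.quantile(degrees, np.linspace(0, 1, n_degree_bins + 1))
        qs[-1] += 1
        bin_of = np.digitize(degrees, qs[1:-1])
        bins = {}
        for v, b in zip(all_nodes, bin_of):
            bins.setdefault(b, []).append(v)
        node_bins = [int(np.digitize([deg[v]], qs[1:-1])[0]) for v in nodes]
        hits = 0
        for _ in range(n_permutations):
            sample = []
            for b in node_bins:
                pool = bins[b]
                sample.append(pool[rng.integers(len(pool))])
            perm_m = background.subgraph(set(sample)).number_of_edges()
            if perm_m >= m:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return NetworkEnrichment(n_nodes=len(nodes), m_observed=m,
                             lam_expected=lam, p_value=p, mode=mode,
                             background_edges=M)
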