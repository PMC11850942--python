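"""Interactor calling against multiple negative-control classes.

A protein is a specific bait interactor only if it is enriched — log2 fold
change >= 2 together with -log10 p >= 1.3 from a two-sided pooled-variance
Student t test — against *every* negative-control class: the ligase-only
(empty vector) control, the no-doxycycline control (no bait expression) and
the no-biotin control (no labeling). Interactor sets called for the
wild-type bait and for the DNA-binding-deficient and dimerization-deficient
point mutants are then partitioned by set algebra into dependence classes,
and a high-confidence tier is selected by per-replicate enrichment ratios,
peptide evidence and novelty against a known-interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import LogIntensityMatrix, aggregate_bio_replicates

P_FLOOR = 1e-300

#: default thresholds: LFC >= 2 (fourfold) and -log10 p >= 1.3 (p <= 0.05),
#: both inclusive
DEFAULT_LFC = 2.0
DEFAULT_NEG_LOG10_P = 1.3

CONTROL_CONTRASTS = ("EV", "no_dox", "no_biotin")


def enrich_contrast(matrix: LogIntensityMatrix, group_a, group_b) -> pd.DataFrame:
    """Two-sided pooled-variance Student t contrast of two sample groups.

    Returns a per-protein DataFrame with ``lfc`` (mean log2 A − mean log2 B),
    ``t``, ``p``, ``neg_log10_p``, ``n_a`` and ``n_b``. Degenerate rows with
    zero pooled variance give t=0, p=1 when the means agree and a p floored
    at 1e-300 when they differ.
    """
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    lfc = ma - mb
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = sp2 == 0
    equal = zero_var & (lfc == 0)
    unequal = zero_var & (lfc != 0)
    t[equal], p[equal] = 0.0, 1.0
    t[unequal] = np.sign(lfc[unequal]) * np.inf
    p[unequal] = P_FLOOR
    p = np.maximum(p, P_FLOOR)
    return pd.DataFrame({
        "lfc": lfc, "t": t, "p": p, "neg_log10_p": -np.log10(p),
        "n_a": na, "n_b": nb,
    }, index=matrix.values.index)


def _group_samples(design: pd.DataFrame, bait=None, treatment=None,
                   control_class="full_labeling"):
    sel = design["control_class"] == control_class
    if bait is not None:
        sel &= design["bait"] == bait
    if treatment is not None:
        sel &= design["treatment"] == treatment
    return design.loc[sel, "sample"].tolist()


def call_specific(matrix: LogIntensityMatrix, design: pd.DataFrame,
                  bait: str, treatment: str,
                  lfc_threshold: float = DEFAULT_LFC,
                  neg_log10_p_threshold: float = DEFAULT_NEG_LOG10_P,
                  controls=CONTROL_CONTRASTS) -> pd.DataFrame:
    """Call proteins specifically enriched with a bait versus all controls.

    For each negative-control class the bait/treatment group is contrasted
    against the control group of the same treatment; a protein is
    ``specific`` iff it passes the (inclusive) LFC and −log10 p thresholds
    in every contrast. Returns a per-protein DataFrame with the per-contrast
    statistics, pass flags and the ``specific`` verdict.
    """
    bait_samples = _group_samples(design, bait=bait, treatment=treatment)
    if not bait_samples:
        raise ValueError(f"no samples for bait {bait!r} / {treatment!r}")
    out, passed = {}, []
    for ctrl in controls:
        if ctrl == "EV":
            ctrl_samples = _group_samples(design, bait="EV",
                                          treatment=treatment)
        else:
            ctrl_samples = _group_samples(design, treatment=treatment,
                                          control_class=ctrl)
        if not ctrl_samples:
            raise ValueError(f"missing control class: {ctrl}")
        res = enrich_contrast(matrix, bait_samples, ctrl_samples)
        ok = (res["lfc"] >= lfc_threshold) & (
            res["neg_log10_p"] >= neg_log10_p_threshold)
        out[f"lfc_{ctrl}"] = res["lfc"]
        out[f"p_{ctrl}"] = res["p"]
        out[f"pass_{ctrl}"] = ok
        passed.append(ok)
    calls = pd.DataFrame(out)
    calls["specific"] = np.logical_and.reduce(passed)
    calls.insert(0, "bait", bait)
    calls.insert(1, "treatment", treatment)
    return calls


def specific_set(calls: pd.DataFrame) -> set:
    return set(calls.index[calls["specific"]])


@dataclass
class VennPartition:
    """Exhaustive region decomposition of named sets."""

    sets: dict
    regions: dict = field(init=False)  # frozenset of names -> member set

    def __post_init__(self):
        names = list(self.sets)
        if len(names) < 2:
            raise ValueError("need at least 2 sets")
        regions = {}
        universe = set().union(*self.sets.values())
        for x in universe:
            sig = frozenset(n for n in names if x in self.sets[n])
            regions.setdefault(sig, set()).add(x)
        self.regions = regions

    @property
    def counts(self) -> dict:
        return {sig: len(m) for sig, m in self.regions.items()}

    @property
    def union_size(self) -> int:
        return len(set().union(*self.sets.values()))

    def region(self, *names) -> set:
        return self.regions.get(frozenset(names), set())


def venn_partition(named_sets: dict) -> VennPartition:
    """Partition >=2 named sets into their exclusive Venn regions."""
    return VennPartition(sets={k: set(v) for k, v in named_sets.items()})


def overlap_from_counts(n_a: int, n_b: int, n_union: int) -> int:
    """Inclusion–exclusion: |A ∩ B| from |A|, |B| and |A ∪ B|."""
    n_int = n_a + n_b - n_union
    if not 0 <= n_int <= min(n_a, n_b):
        raise ValueError("inconsistent counts")
    return n_int


def classify_dependence(wt_set, ei_set, fldd_set) -> dict:
    """Partition interactors by bait-mutant dependence.

    wt ∩ E_I ∩ FL_DD → independent of both functions; lost only with the
    dimerization-deficient mutant → dimerization_dependent; lost only with
    the DNA-binding-deficient mutant → dna_binding_dependent; wt only →
    dimerization_and_dna_dependent; found only with a mutant → mutant_gained.
    """
    wt, ei, fldd = set(wt_set), set(ei_set), set(fldd_set)
    labels = {}
    for p in wt | ei | fldd:
        if p in wt:
            if p in ei and p in fldd:
                labels[p] = "independent"
            elif p in ei:
                labels[p] = "dimerization_dependent"
            elif p in fldd:
                labels[p] = "dna_binding_dependent"
            else:
                labels[p] = "dimerization_and_dna_dependent"
        else:
            labels[p] = "mutant_gained"
    return labels


def select_hci(calls, matrix: LogIntensityMatrix, design: pd.DataFrame,
               ppi_known=None, bait: str = "wt", bait_protein: str = None,
               ratio_threshold: float = 8.0, min_peptides: int = 2,
               allowlist=()) -> pd.DataFrame:
    """Select high-confidence interactors from the specific calls.

    Candidates are the union of specific interactors passed in ``calls``
    (a DataFrame from :func:`call_specific` or an iterable of them).
    Per biological replicate, the enrichment ratio versus the ligase-only
    control is 2^(mean bait log2 − mean EV log2) with technical replicates
    averaged on the log2 scale. A candidate is ``selected`` iff its ratio
    exceeds ``ratio_threshold`` in *both* biological replicates in at least
    one condition (untreated or stimulated), it was identified by at least
    ``min_peptides`` peptides (or sits on the explicit allowlist), and it
    has no documented edge to the bait in ``ppi_known``.
    """
    if isinstance(calls, pd.DataFrame):
        calls = [calls]
    candidates = sorted(set().union(*(specific_set(c) for c in calls)))

    agg = aggregate_bio_replicates(matrix, design)
    bio_reps = sorted(design["bio_rep"].unique())
    if len(bio_reps) < 2:
        raise ValueError("need at least 2 biological replicates")
    treatments = sorted(design["treatment"].unique())

    known = set()
    if ppi_known is not None and bait_protein is not None:
        if hasattr(ppi_known, "neighbors"):
            if bait_protein in ppi_known:
                known = set(ppi_known.neighbors(bait_protein))
        else:
            for a, b in ppi_known:
                if a == bait_protein:
                    known.add(b)
                elif b == bait_protein:
                    known.add(a)

    rows = []
    for prot in candidates:
        ratios = {}
        for tr in treatments:
            for b in bio_reps:
                bait_mean = agg.loc[prot, (bait, tr, "full_labeling", b)]
                ev_mean = agg.loc[prot, ("EV", tr, "full_labeling", b)]
                ratios[(tr, b)] = float(2.0 ** (bait_mean - ev_mean))
        ratio_ok = any(
            all(ratios[(tr, b)] > ratio_threshold for b in bio_reps)
            for tr in treatments)
        peptides = int(matrix.peptides.loc[prot])
        peptide_ok = peptides >= min_peptides or prot in set(allowlist)
        novel = prot not in known
        row = {"protein": prot, "peptides": peptides,
               "known_interactor": not novel,
               "selected": bool(ratio_ok and peptide_ok and novel)}
        for (tr, b), r in ratios.items():
            row[f"ratio_{tr}_b{b}"] = r
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein") if rows else pd.DataFrame(
        columns=["peptides", "known_interactor", "selected"])


def pairwise_overlaps(named_sets: dict) -> pd.DataFrame:
    """Pairwise intersection sizes between named sets (bookkeeping helper)."""
    names = list(named_sets)
    rows = []
    for a, b in combinations(names, 2):
        inter = len(set(named_sets[a]) & set(named_sets[b]))
        rows.append((a, b, len(set(named_sets[a])), len(set(named_sets[b])),
                     inter))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b",
                                       "n_intersection"])
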