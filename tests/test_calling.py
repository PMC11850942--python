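"""Interactor calling: pooled t, multi-control logic, set algebra, HCI."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxilogic.calling import (call_specific, classify_dependence,
                                enrich_contrast, overlap_from_counts,
                                select_hci, specific_set, venn_partition)
from proxilogic.proteomics import LogIntensityMatrix, log2_impute


def _matrix(rows: dict, samples=None):
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return LogIntensityMatrix(values=df, mask=df * 0 > 1, impute_value=9.0,
                              peptides=pd.Series(5, index=df.index))


def test_identical_groups_give_zero_lfc_p_one():
    m = _matrix({"p": [10, 11, 12, 10, 11, 12]})
    res = enrich_contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert res.loc["p", "lfc"] == 0
    assert res.loc["p", "p"] == pytest.approx(1.0)


def test_pooled_t_matches_closed_form_and_scipy():
    m = _matrix({"p": [14, 15, 16, 10, 11, 12]})
    res = enrich_contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert res.loc["p", "lfc"] == pytest.approx(4.0)
    assert res.loc["p", "t"] == pytest.approx(4.898979, abs=1e-6)
    assert res.loc["p", "p"] == pytest.approx(0.0080, abs=5e-5)
    # independent oracle: scipy's equal-variance two-sample t
    t_ref, p_ref = stats.ttest_ind([14, 15, 16], [10, 11, 12])
    assert res.loc["p", "t"] == pytest.approx(t_ref, abs=1e-9)
    assert res.loc["p", "p"] == pytest.approx(p_ref, abs=1e-9)


@pytest.mark.parametrize("a,b,t_exp,p_exp", [
    ((5, 5, 5), (5, 5, 5), 0.0, 1.0),            # zero variance, equal means
    ((7, 7, 7), (5, 5, 5), np.inf, 1e-300),      # zero variance, unequal
])
def test_degenerate_variance_handling(a, b, t_exp, p_exp):
    m = _matrix({"p": list(a) + list(b)})
    res = enrich_contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert res.loc["p", "t"] == t_exp
    assert res.loc["p", "p"] == p_exp


def test_small_group_rejected():
    m = _matrix({"p": [1, 2, 3]})
    with pytest.raises(ValueError):
        enrich_contrast(m, ["s0"], ["s1", "s2"])


def test_enrich_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.normal(10, 2, 4), rng.normal(9, 2, 5)
        m = _matrix({"p": list(a) + list(b)})
        res = enrich_contrast(m, [f"s{i}" for i in range(4)],
                              [f"s{i}" for i in range(4, 9)])
        na, nb = 4, 5
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.loc["p", "t"] == pytest.approx(t, abs=1e-9)
        assert res.loc["p", "p"] == pytest.approx(p, abs=1e-9)


def _three_control_design():
    rows = []
    for grp, bait, cc in [("wt", "wt", "full_labeling"),
                          ("EV", "EV", "full_labeling"),
                          ("nd", "wt", "no_dox"),
                          ("nb", "wt", "no_biotin")]:
        for i in range(3):
            rows.append((f"{grp}{i}", bait, "IL1", cc, 1, i + 1))
    return pd.DataFrame(rows, columns=["sample", "bait", "treatment",
                                       "control_class", "bio_rep",
                                       "tech_rep"])


def test_specific_requires_all_three_controls():
    design = _three_control_design()
    samples = design["sample"].tolist()
    # passes vs EV and no_dox but sits at control level vs no_biotin
    vals = {"p": [20, 20, 20, 14, 14, 14, 14, 14, 14, 20, 20, 20]}
    m = _matrix(vals, samples=samples)
    calls = call_specific(m, design, "wt", "IL1")
    assert bool(calls.loc["p", "pass_EV"])
    assert bool(calls.loc["p", "pass_no_dox"])
    assert not bool(calls.loc["p", "pass_no_biotin"])
    assert not bool(calls.loc["p", "specific"])


def test_missing_control_class_is_named():
    design = _three_control_design()
    design = design[design["control_class"] != "no_biotin"]
    m = _matrix({"p": list(range(9))}, samples=design["sample"].tolist())
    with pytest.raises(ValueError, match="no_biotin"):
        call_specific(m, design, "wt", "IL1")


def test_thresholds_are_inclusive_at_the_boundary():
    """A protein sitting exactly at LFC=2 and p=0.05 is still called."""
    design = _three_control_design()
    m = _matrix({"p": [16.0] * 3 + [14.0] * 9}, samples=design["sample"].tolist())
    res = enrich_contrast(m, ["wt0", "wt1", "wt2"], ["EV0", "EV1", "EV2"])
    assert res.loc["p", "lfc"] == 2.0 and res.loc["p", "p"] < 0.05
    calls = call_specific(m, design, "wt", "IL1",
                          lfc_threshold=2.0,
                          neg_log10_p_threshold=float(
                              res.loc["p", "neg_log10_p"]))
    assert bool(calls.loc["p", "specific"])


def test_calling_is_anti_monotone_in_thresholds(small_miniturbo):
    table, design, _ = small_miniturbo
    m = log2_impute(table)
    loose = specific_set(call_specific(m, design, "wt", "IL1", 2.0, 1.3))
    tight = specific_set(call_specific(m, design, "wt", "IL1", 3.0, 2.0))
    assert tight <= loose


def test_planted_interactors_all_called(small_miniturbo):
    table, design, truth = small_miniturbo
    m = log2_impute(table)
    called = specific_set(call_specific(m, design, "wt", "IL1"))
    assert "BAIT_RELA" in called
    planted = set(truth.planted_interactors)
    assert planted <= called  # every class is present in wt under IL1


def test_venn_partition_regions():
    v = venn_partition({"A": {"x", "y"}, "B": {"y", "z"}})
    assert v.region("A") == {"x"}
    assert v.region("B") == {"z"}
    assert v.region("A", "B") == {"y"}
    assert v.union_size == 3
    assert sum(v.counts.values()) == 3


def test_venn_identical_sets_collapse_to_one_region():
    v = venn_partition({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
    assert list(v.counts) == [frozenset({"A", "B", "C"})]


def test_inclusion_exclusion_on_reported_counts():
    """279 untreated + 310 stimulated interactors with a union of 366
    force an overlap of 223."""
    assert overlap_from_counts(279, 310, 366) == 223
    with pytest.raises(ValueError):
        overlap_from_counts(3, 3, 10)


@pytest.mark.parametrize("in_wt,in_ei,in_fldd,label", [
    (True, True, True, "independent"),
    (True, True, False, "dimerization_dependent"),
    (True, False, True, "dna_binding_dependent"),
    (True, False, False, "dimerization_and_dna_dependent"),
    (False, False, True, "mutant_gained"),
])
def test_dependence_classification(in_wt, in_ei, in_fldd, label):
    wt = {"P"} if in_wt else set()
    ei = {"P"} if in_ei else set()
    fldd = {"P"} if in_fldd else set()
    assert classify_dependence(wt, ei, fldd)["P"] == label


def test_dependence_recovery_on_planted_classes(small_miniturbo):
    table, design, truth = small_miniturbo
    m = log2_impute(table)
    sets = {bait: specific_set(call_specific(m, design, bait, "IL1"))
            for bait in ("wt", "E_I", "FL_DD")}
    labels = classify_dependence(sets["wt"], sets["E_I"], sets["FL_DD"])
    expected = {"independent": "independent",
                "dna_binding_dependent": "dna_binding_dependent",
                "dimerization_dependent": "dimerization_dependent",
                "both": "dimerization_and_dna_dependent",
                "condition_specific": "independent"}  # all baits under IL-1
    correct = sum(labels.get(p) == expected[c]
                  for p, c in truth.planted_interactors.items())
    assert correct / len(truth.planted_interactors) >= 0.95


def _hci_setup(ratios_by_rep, peptides=5):
    """Two bio reps x (wt, EV) x one treatment, one candidate protein."""
    rows, vals = [], []
    level = {("wt", b): 14.0 + np.log2(ratios_by_rep[b - 1])
             for b in (1, 2)}
    for bait in ("wt", "EV"):
        for b in (1, 2):
            for t in (1, 2, 3):
                rows.append((f"{bait}_b{b}_t{t}", bait, "untreated",
                             "full_labeling", b, t))
                vals.append(level.get((bait, b), 14.0))
    design = pd.DataFrame(rows, columns=["sample", "bait", "treatment",
                                         "control_class", "bio_rep",
                                         "tech_rep"])
    df = pd.DataFrame([vals], index=["cand"], columns=design["sample"])
    m = LogIntensityMatrix(values=df, mask=df * 0 > 1,
                           peptides=pd.Series({"cand": peptides}))
    calls = pd.DataFrame({"specific": [True]}, index=["cand"])
    return m, design, calls


@pytest.mark.parametrize("ratios,expected", [
    ((9, 10), True),   # above eightfold in both replicates
    ((9, 7), False),   # fails one replicate
    ((8, 9), False),   # threshold is strict '>'
])
def test_hci_ratio_rule(ratios, expected):
    m, design, calls = _hci_setup(ratios)
    sel = select_hci(calls, m, design)
    assert bool(sel.loc["cand", "selected"]) is expected


def test_hci_peptide_rule_and_allowlist():
    m, design, calls = _hci_setup((9, 10), peptides=1)
    assert not bool(select_hci(calls, m, design).loc["cand", "selected"])
    sel = select_hci(calls, m, design, allowlist=("cand",))
    assert bool(sel.loc["cand", "selected"])


def test_hci_excludes_known_interactors():
    import networkx as nx
    m, design, calls = _hci_setup((9, 10))
    known = nx.Graph([("BAIT", "cand")])
    sel = select_hci(calls, m, design, ppi_known=known, bait_protein="BAIT")
    assert bool(sel.loc["cand", "known_interactor"])
    assert not bool(sel.loc["cand", "selected"])


def test_hci_subset_of_specific_calls(small_miniturbo):
    table, design, truth = small_miniturbo
    m = log2_impute(table)
    wt_calls = [call_specific(m, design, "wt", tr)
                for tr in ("untreated", "IL1")]
    sel = select_hci(wt_calls, m, design)
    union = set().union(*(specific_set(c) for c in wt_calls))
    assert set(sel.index[sel["selected"]]) <= union
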