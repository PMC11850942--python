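"""NormExp, quantile normalization, probe collapse, moderated t, gene sets."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxilogic.transcriptome import (ExpressionMatrix,
                                      _normexp_conditional_mean,
                                      collapse_probes, correlate_effects,
                                      deg_pass, define_gene_sets,
                                      estimate_prior_variance,
                                      knockdown_ratios, moderated_t,
                                      normexp_correct, quantile_normalize,
                                      shift_test)

# ---------------------------------------------------------------------------
# NormExp
# ---------------------------------------------------------------------------


def test_normexp_vanishing_background_limit():
    # with sigma ~ 0 and mu = 0 the observation is (almost) pure signal
    out = _normexp_conditional_mean(np.array([50.0]), mu=0.0, sigma=0.001,
                                    alpha=100.0)
    assert out[0] == pytest.approx(50.0, abs=0.01)


def test_normexp_numeric_closed_form_example():
    out = _normexp_conditional_mean(np.array([100.0]), mu=50.0, sigma=10.0,
                                    alpha=100.0)
    # mu_sx = 100 - 50 - 100/100 = 49; the Mills-ratio correction at
    # z = 4.9 is ~2e-5
    assert out[0] == pytest.approx(49.0, abs=1e-3)
    assert out[0] > 49.0


def test_normexp_positive_far_below_background():
    out = _normexp_conditional_mean(np.array([-200.0, 0.0, 10.0]), mu=50.0,
                                    sigma=10.0, alpha=100.0)
    assert (out > 0).all()


def test_normexp_monotone_in_observation():
    x = np.linspace(-50, 300, 200)
    out = _normexp_conditional_mean(x, mu=50.0, sigma=10.0, alpha=100.0)
    assert (np.diff(out) > 0).all()


@pytest.mark.parametrize("mu,sigma,alpha,x", [
    (50.0, 10.0, 100.0, 100.0),
    (30.0, 5.0, 40.0, 32.0),
    (0.0, 20.0, 200.0, 10.0),
])
def test_normexp_matches_monte_carlo_conditional_expectation(mu, sigma,
                                                             alpha, x):
    """Importance-sampling estimate of E[signal | observed] as oracle."""
    rng = np.random.default_rng(12345)
    s = rng.exponential(alpha, size=4_000_000)
    w = stats.norm.pdf(x - s, loc=mu, scale=sigma)
    mc = float(np.sum(s * w) / np.sum(w))
    mine = float(_normexp_conditional_mean(np.array([x]), mu, sigma, alpha)[0])
    assert mine == pytest.approx(mc, abs=max(1e-3, 3e-3 * abs(mc)))


def test_normexp_correct_strictly_positive_and_param_estimation():
    rng = np.random.default_rng(0)
    n = 400
    neg = rng.normal(50, 10, size=(30, 2))
    sig = rng.normal(50, 10, size=(n, 2)) + rng.exponential(80, size=(n, 2))
    inten = np.clip(np.vstack([sig, neg]), 0, None)
    probes = [f"p{i}" for i in range(n)] + [f"neg{i}" for i in range(30)]
    em = ExpressionMatrix(
        intensities=pd.DataFrame(inten, index=probes, columns=["a", "b"]),
        probe_gene=pd.Series([f"g{i}" for i in range(n)] + [""] * 30,
                             index=probes),
        is_negative_control=pd.Series([False] * n + [True] * 30,
                                      index=probes))
    corrected, params = normexp_correct(em, offset=1.0)
    assert (corrected.to_numpy() > 0).all()
    assert params["a"].mu == pytest.approx(50, abs=5)
    assert params["a"].sigma == pytest.approx(10, abs=4)
    assert params["a"].alpha == pytest.approx(80, rel=0.3)


def test_normexp_requires_negative_controls():
    em = ExpressionMatrix(
        intensities=pd.DataFrame({"a": [1.0, 2.0]}, index=["p1", "p2"]),
        probe_gene=pd.Series({"p1": "g", "p2": "g"}),
        is_negative_control=pd.Series({"p1": False, "p2": False}))
    with pytest.raises(ValueError, match="negative-control"):
        normexp_correct(em)


# ---------------------------------------------------------------------------
# quantile normalization / probe collapse
# ---------------------------------------------------------------------------


def test_quantile_normalize_hand_example_and_idempotence():
    m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
    out = quantile_normalize(m)
    assert out["a"].tolist() == [1.5, 3.5]
    assert out["b"].tolist() == [1.5, 3.5]
    again = quantile_normalize(out)
    assert np.allclose(again.to_numpy(), out.to_numpy())


def test_quantile_normalize_equalizes_distributions_preserves_ranks():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.normal(size=(50, 4)) * [1, 2, 3, 4],
                     columns=list("abcd"))
    out = quantile_normalize(m)
    ref = np.sort(out["a"].to_numpy())
    for c in "bcd":
        assert np.allclose(np.sort(out[c].to_numpy()), ref)
        assert (stats.rankdata(m[c]) == stats.rankdata(out[c])).all()
    identical = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
    assert np.allclose(quantile_normalize(identical), identical)


def test_collapse_probes_max_mean_and_tie_break():
    m = pd.DataFrame({"s1": [5.0, 7.0, 3.0, 3.0], "s2": [5.0, 7.0, 3.0, 3.0]},
                     index=["pA", "pB", "pD", "pC"])
    gene = pd.Series({"pA": "g1", "pB": "g1", "pC": "g2", "pD": "g2"})
    out = collapse_probes(m, gene)
    assert out.loc["g1", "s1"] == 7.0           # max mean wins
    assert set(out.index) == {"g1", "g2"}
    # tie between pC and pD resolves to the lexicographically smaller id
    chosen = collapse_probes(m, gene)
    assert chosen.loc["g2"].equals(m.loc["pC"])


def test_collapse_drops_unmapped_probes():
    m = pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "neg"])
    out = collapse_probes(m, pd.Series({"p1": "g", "neg": ""}))
    assert list(out.index) == ["g"]


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _two_group_matrix(seed=0, n=200, shift_first=20):
    rng = np.random.default_rng(seed)
    x = rng.normal(8, 1, size=(n, 6))
    x[:shift_first, :3] += 2.0
    return pd.DataFrame(x, index=[f"g{i}" for i in range(n)],
                        columns=["a1", "a2", "a3", "b1", "b2", "b3"])


def test_d0_zero_reduces_to_ordinary_t():
    m = _two_group_matrix()
    mine = moderated_t(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                       d0_mode="none")
    t_ref, p_ref = stats.ttest_ind(m[["a1", "a2", "a3"]], m[["b1", "b2", "b3"]],
                                   axis=1)
    assert np.allclose(mine["t"], t_ref, atol=1e-9)
    assert np.allclose(mine["p"], p_ref, atol=1e-9)


def test_d0_infinite_pools_all_variances():
    m = _two_group_matrix()
    mine = moderated_t(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                       d0_mode="pooled")
    assert mine["s2_post"].nunique() == 1


def test_shrinkage_formula_example():
    # s_g²=4, s0²=1, d0=4, d_g=4 -> posterior variance 2.5
    s2_post = (4 * 1.0 + 4 * 4.0) / (4 + 4)
    assert s2_post == 2.5
    # heterogeneous true variances keep the prior df finite
    m = _two_group_matrix(shift_first=0)
    m.iloc[:50] *= 3.0
    res = moderated_t(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"], d0_mode="eb")
    d0, s02 = res["d0"].iloc[0], res["s02"].iloc[0]
    assert np.isfinite(d0)
    manual = (d0 * s02 + 4 * res["s2"]) / (d0 + 4)
    assert np.allclose(res["s2_post"], manual)


def test_moderated_t_matches_limma_ebayes(tmp_path):
    """Independent oracle: limma's lmFit + eBayes on the same matrix."""
    m = _two_group_matrix(seed=42)
    mat_path = tmp_path / "mat.tsv"
    m.to_csv(mat_path, sep="\t")
    r_code = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{mat_path}", row.names=1))
        design <- cbind(Intercept=1, A=c(1,1,1,0,0,0))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
    """)
    (tmp_path / "fit.R").write_text(r_code)
    subprocess.run(["Rscript", str(tmp_path / "fit.R")], check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    mine = moderated_t(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                       d0_mode="eb")
    assert mine["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-9)
    assert mine["s02"].iloc[0] == pytest.approx(ref["s02"].iloc[0], rel=1e-9)
    assert np.allclose(mine["t"], ref["t"], atol=1e-9)
    assert np.allclose(mine["p"], ref["p"], atol=1e-9)


def test_prior_estimate_detects_common_variance():
    rng = np.random.default_rng(1)
    dg = 4
    s2 = stats.chi2.rvs(dg, size=500, random_state=rng) / dg  # common var 1
    d0, s02 = estimate_prior_variance(s2, dg)
    assert d0 > 20 or np.isinf(d0)  # spread explained by sampling alone
    assert s02 == pytest.approx(1.0, rel=0.3)


def test_deg_pass_thresholds_inclusive():
    deg = pd.DataFrame({"lfc": [1.0, -1.0, 0.9], "neg_log10_p": [1.3, 5.0, 9.0]})
    assert deg_pass(deg).tolist() == [True, True, False]
    assert deg_pass(deg, direction="up").tolist() == [True, False, False]


# ---------------------------------------------------------------------------
# gene sets, shift test, correlation
# ---------------------------------------------------------------------------


def test_define_gene_sets_planted_recovery():
    genes = [f"g{i}" for i in range(8)]
    induced = pd.DataFrame({
        "lfc": [3, 3, 3, 3, 0, 0, 0, 0],
        "neg_log10_p": [5, 5, 5, 5, 0.1, 0.1, 0.1, 0.1]}, index=genes)
    ratios = {
        "RELA": pd.Series([3, 3, 0, 0, 3, 0, 0, 0], index=genes, dtype=float),
        "X": pd.Series([3, 0, 0, 0, 0, 3, 0, 0], index=genes, dtype=float),
    }
    sets = define_gene_sets(induced, ratios, bait="RELA")
    assert sets["stimulus_induced"] == {"g0", "g1", "g2", "g3"}
    # knockdown-affected sets live inside the stimulus-induced genes
    assert sets["affected_RELA"] == {"g0", "g1"}
    assert sets["affected_X"] == {"g0"}
    assert sets["jointly_regulated_X"] == {"g0"}


def test_empty_deg_list_gives_empty_sets():
    empty = pd.DataFrame(columns=["lfc", "neg_log10_p"], dtype=float)
    sets = define_gene_sets(empty, {"RELA": pd.Series(dtype=float)},
                            bait="RELA")
    assert sets["stimulus_induced"] == set()
    assert sets["affected_RELA"] == set()


def test_shift_test_exact_enumeration_and_symmetry():
    u, p = shift_test([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme
    _, p_swap = shift_test([4, 5, 6], [1, 2, 3])
    assert p_swap == pytest.approx(p)
    _, p_same = shift_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert p_same > 0.5


def test_shift_test_handles_ties_at_larger_n():
    a = [1, 1, 2, 2, 3, 3, 4, 4, 5]
    b = [3, 3, 4, 4, 5, 5, 6, 6, 7]
    _, p = shift_test(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic").pvalue
    assert p == pytest.approx(ref)


def test_correlate_effects_trivial_and_formula():
    genes = [f"g{i}" for i in range(10)]
    x = pd.Series(np.arange(10.0), index=genes)
    res = correlate_effects(x, 2 * x, {"all": genes})
    assert res.loc["all", "r"] == pytest.approx(1.0)
    assert res.loc["all", "r2"] == pytest.approx(1.0)
    res_neg = correlate_effects(x, -x + 3, {"all": genes})
    assert res_neg.loc["all", "r"] == pytest.approx(-1.0)
    rng = np.random.default_rng(0)
    y = pd.Series(rng.normal(size=10), index=genes)
    mine = correlate_effects(x, y, {"all": genes}).loc["all"]
    r_ref, p_ref = stats.pearsonr(x, y)
    assert mine["r"] == pytest.approx(r_ref)
    assert mine["p"] == pytest.approx(p_ref)
    tiny = correlate_effects(x, y, {"small": genes[:2]})
    assert np.isnan(tiny.loc["small", "r"])
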