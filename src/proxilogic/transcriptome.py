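"""Knockdown transcriptomics: normalization, moderated t, gene sets.

Single-channel probe-level expression data are background-corrected with
the NormExp convolution model estimated from negative-control spots
(observed intensity = exponential signal + normal background; the
corrected value is the conditional expectation of the signal given the
observation, plus a small offset), log2-transformed and
quantile-normalized. Probes addressing the same gene collapse to the probe
with the maximal average signal. Differential expression uses a moderated
t-statistic whose per-gene variance is shrunk toward an empirical-Bayes
prior (d0, s0²) estimated by moment matching on the log sample variances.
Gene sets (stimulus-induced, knockdown-affected, jointly regulated) are
derived from the differential calls and knockdown ratios, and distribution
shifts / co-regulation are quantified with Mann–Whitney tests and Pearson
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class ExpressionMatrix:
    """Probe × sample raw intensities with probe→gene map and control flags."""

    intensities: pd.DataFrame
    probe_gene: pd.Series          # "" for probes without a gene assignment
    is_negative_control: pd.Series
    sample_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("raw intensities must be >= 0")

    def to_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "gene", self.probe_gene)
        out.insert(1, "is_negative_control", self.is_negative_control)
        out.to_csv(path, sep="\t", index_label="probe")

    @classmethod
    def from_tsv(cls, path, sample_meta=None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe")
        gene = df.pop("gene").fillna("")
        neg = df.pop("is_negative_control").astype(bool)
        return cls(intensities=df, probe_gene=gene, is_negative_control=neg,
                   sample_meta=sample_meta)


@dataclass
class NormexpParams:
    mu: float      # background mean
    sigma: float   # background sd
    alpha: float   # signal (exponential) mean
    offset: float = 1.0


def _normexp_conditional_mean(x, mu, sigma, alpha):
    """E[signal | observed x] under x = Exp(alpha) + Normal(mu, sigma²)."""
    x = np.asarray(x, dtype=float)
    mu_sx = x - mu - sigma**2 / alpha
    z = mu_sx / sigma
    # sigma * phi(z)/Phi(z), computed in log space for stability far into
    # the left tail
    mills = sigma * np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return mu_sx + mills


def estimate_normexp_params(column: pd.Series, negatives: pd.Series,
                            offset: float = 1.0) -> NormexpParams:
    """Moment estimates of the NormExp parameters for one array.

    μ and σ come from the negative-control spots; α is the mean signal
    excess of all probes over the background mean (floored at a small
    positive value). A degenerate σ estimate of 0 falls back to 1 with a
    warning.
    """
    neg = column[negatives].to_numpy(dtype=float)
    if neg.size < 10:
        raise ValueError("need >= 10 negative-control probes per array")
    mu = float(neg.mean())
    sigma = float(neg.std(ddof=1))
    if sigma == 0:
        warnings.warn("zero background sd on an array; using sigma=1",
                      UserWarning)
        sigma = 1.0
    alpha = max(float(column.mean()) - mu, 1e-6)
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha, offset=offset)


def normexp_correct(matrix: ExpressionMatrix, offset: float = 1.0):
    """Background-correct each array with NormExp plus an offset.

    Returns (corrected DataFrame, dict of per-array NormexpParams). The
    corrected values are strictly positive, so logarithms are safe.
    """
    corrected = {}
    params = {}
    for col in matrix.intensities.columns:
        pars = estimate_normexp_params(matrix.intensities[col],
                                       matrix.is_negative_control, offset)
        vals = _normexp_conditional_mean(
            matrix.intensities[col].to_numpy(dtype=float),
            pars.mu, pars.sigma, pars.alpha) + offset
        corrected[col] = vals
        params[col] = pars
    out = pd.DataFrame(corrected, index=matrix.intensities.index)
    return out, params


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean of sorted) distribution.

    Rank order within each column is preserved; ties receive the average of
    the reference values they span. Idempotent.
    """
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    positions = np.arange(1, n + 1)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_gene: pd.Series) -> pd.DataFrame:
    """One row per gene: keep the probe with the maximal mean intensity.

    Probes without a gene assignment are dropped. Ties break toward the
    lexicographically smaller probe id, so the collapse is deterministic.
    """
    gene = probe_gene.reindex(matrix.index).fillna("")
    keep = gene != ""
    sub = matrix[keep]
    means = sub.mean(axis=1)
    choice = (
        pd.DataFrame({"gene": gene[keep], "mean": means,
                      "probe": sub.index})
        .sort_values(["gene", "mean", "probe"],
                     ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    out = sub.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration on 1/trigamma."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(-dif / x) < 1e-8:
            break
    return x


def estimate_prior_variance(s2: np.ndarray, df: float):
    """Moment-matching estimate of the variance prior (d0, s0²).

    Matches the mean and variance of log s² against the scaled-F model of
    the sample variances: a gene-level s² with df degrees of freedom around
    a prior s0² with d0 prior degrees of freedom. Returns (d0, s0²), with
    d0 = inf when the observed spread of log s² is no larger than expected
    under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0)
                           - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_t(matrix: pd.DataFrame, group_a, group_b,
                d0_mode: str = "eb") -> pd.DataFrame:
    """Two-group moderated t on log2 expression.

    Per gene: LFC = mean(A) − mean(B); the posterior variance shrinks the
    pooled sample variance toward the prior,
    s̃² = (d0·s0² + d_g·s²)/(d0 + d_g), and t̃ = LFC / (s̃·√(1/nA + 1/nB))
    is referred to a t distribution with d0 + d_g degrees of freedom.
    ``d0_mode``: "eb" estimates (d0, s0²) empirically; "none" sets d0 = 0
    (ordinary t); "pooled" sets d0 = ∞ (common variance, normal reference).
    """
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    dg = na + nb - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((na - 1) * a.var(axis=1, ddof=1)
          + (nb - 1) * b.var(axis=1, ddof=1)) / dg

    if d0_mode == "eb":
        d0, s02 = estimate_prior_variance(s2, dg)
    elif d0_mode == "none":
        d0, s02 = 0.0, 0.0
    elif d0_mode == "pooled":
        d0, s02 = np.inf, float(np.mean(s2))
    else:
        raise ValueError(f"unknown d0_mode: {d0_mode!r}")

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, np.maximum(p, 1e-300))
    return pd.DataFrame({
        "lfc": lfc, "t": t, "p": p, "neg_log10_p": -np.log10(p),
        "s2": s2, "s2_post": s2_post,
        "df": df_total if np.isscalar(df_total) else df_total,
        "d0": d0, "s02": s02,
    }, index=matrix.index)


def deg_pass(deg: pd.DataFrame, lfc_threshold: float = 1.0,
             neg_log10_p_threshold: float = 1.3,
             direction: str = "both") -> pd.Series:
    """Differential-expression verdict at |LFC| and −log10 p thresholds."""
    if direction == "up":
        lfc_ok = deg["lfc"] >= lfc_threshold
    elif direction == "down":
        lfc_ok = deg["lfc"] <= -lfc_threshold
    else:
        lfc_ok = deg["lfc"].abs() >= lfc_threshold
    return lfc_ok & (deg["neg_log10_p"] >= neg_log10_p_threshold)


# ---------------------------------------------------------------------------
# gene sets, shift tests, correlation
# ---------------------------------------------------------------------------

def knockdown_ratios(matrix: pd.DataFrame, control_samples,
                     knockdown_samples) -> pd.Series:
    """Per-gene log2(control siRNA / knockdown) from normalized log2 values."""
    return (matrix[list(control_samples)].mean(axis=1)
            - matrix[list(knockdown_samples)].mean(axis=1))


def define_gene_sets(induced_deg: pd.DataFrame, kd_log2_ratios: dict,
                     bait: str, lfc_threshold: float = 1.0,
                     neg_log10_p_threshold: float = 1.3,
                     kd_log2_threshold: float = 1.0) -> dict:
    """Derive the stimulus / knockdown gene sets from differential calls.

    ``induced_deg`` is the moderated-t result of stimulated vs unstimulated
    under the control siRNA; the stimulus-induced set requires LFC ≥ 1 and
    −log10 p ≥ 1.3 (up-regulation). ``kd_log2_ratios`` maps each siRNA
    target to per-gene log2(control/knockdown) values in stimulated
    samples; genes affected at least twofold in either direction among the
    stimulus-induced genes form the knockdown-affected set of that target.
    Jointly regulated sets intersect the bait-dependent set with each
    partner's.
    """
    induced = set(induced_deg.index[deg_pass(
        induced_deg, lfc_threshold, neg_log10_p_threshold, direction="up")])
    sets = {"stimulus_induced": induced}
    for target, ratios in kd_log2_ratios.items():
        affected = set(ratios.index[ratios.abs() >= kd_log2_threshold])
        sets[f"affected_{target}"] = affected & induced
    if bait in kd_log2_ratios:
        for target in kd_log2_ratios:
            if target == bait:
                continue
            sets[f"jointly_regulated_{target}"] = (
                sets[f"affected_{bait}"] & sets[f"affected_{target}"])
    return sets


def shift_test(values_a, values_b):
    """Two-sided Mann–Whitney U test of a distribution shift.

    Exact enumeration for small untied samples (n ≤ 8 each); otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U statistic, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    small = len(a) <= 8 and len(b) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def correlate_effects(ratios_x: pd.Series, ratios_y: pd.Series,
                      subsets: dict) -> pd.DataFrame:
    """Pearson r, p and r² of paired effect ratios, per gene subset."""
    rows = []
    for name, genes in subsets.items():
        idx = [g for g in genes if g in ratios_x.index and g in ratios_y.index]
        if len(idx) < 3:
            rows.append((name, len(idx), np.nan, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(ratios_x.loc[idx], ratios_y.loc[idx])
        rows.append((name, len(idx), r, p, r * r))
    return pd.DataFrame(rows, columns=["subset", "n", "r", "p", "r2"]
                        ).set_index("subset")
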