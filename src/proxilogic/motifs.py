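"""PWM scanning and motif co-occurrence under ChIP peak windows.

Position-weight matrices (JASPAR PFM text) are scanned over fixed windows
(default ±500 bp) around peak summits on both strands with log-odds
scores; the score threshold for a hit comes from the exact null score
distribution, computed by dynamic programming over positions with
background-weighted convolution at fixed score granularity. Motif
enrichment is tested against a genome-background hit rate with a binomial
tail. Peaks are classified into recruitment scenarios — a composite
element carries motifs for both the bait TF and a partner TF, a
partner-only peak suggests tethered (indirect, protein–protein) recruitment
of the bait — annotated to their nearest TSS, and motif content is
intersected with knockdown-derived gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: score-distribution granularity, in bits
SCORE_GRANULARITY = 1e-3


@dataclass
class PWM:
    """Position probability matrix with background and log-odds view."""

    name: str
    probs: np.ndarray                      # width x 4, rows sum to 1
    background: np.ndarray = None          # length 4

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p_i(b) / q(b)); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, name, counts, pseudocount: float = 0.25,
                    background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(name=name, probs=probs, background=background)


def read_jaspar(path, pseudocount: float = 0.25, background=None) -> list:
    """Read a JASPAR-format PFM file into pseudocount-smoothed PWMs."""
    try:
        with open(path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
        pwms = []
        for m in records:
            counts = np.array([[m.counts[b][i] for b in BASES]
                               for i in range(m.length)])
            name = m.matrix_id or m.name
            pwms.append(PWM.from_counts(name, counts, pseudocount, background))
    except Exception as exc:  # Biopython raises bare Exceptions on bad input
        raise ValueError(f"could not parse JASPAR PFM file {path}: {exc}")
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_jaspar(pwms, path, scale: int = 100) -> None:
    """Write PWMs as JASPAR-style integer count matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for bi, base in enumerate(BASES):
                row = " ".join(str(c) for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

def score_distribution(pwm: PWM, granularity: float = SCORE_GRANULARITY):
    """Exact null distribution of the log-odds score of a background word.

    Dynamic program over positions: integer-discretized per-position scores
    are convolved with background weights. -inf scores (zero probability
    positions) are tracked as a separate lost-mass term. Returns
    (scores array ascending, probabilities), summing to 1 with the lost
    mass assigned to -inf (prepended as scores[0] = -inf if present).
    """
    lo = pwm.log_odds
    finite = np.isfinite(lo)
    scaled = np.zeros(lo.shape, dtype=np.int64)
    scaled[finite] = np.round(lo[finite] / granularity).astype(np.int64)

    offset = 0
    dist = {0: 1.0}
    ninf_mass = 0.0
    for i in range(pwm.width):
        new = {}
        for b in range(4):
            q = pwm.background[b]
            if q == 0:
                continue
            if not finite[i, b]:
                ninf_mass += q * sum(dist.values())
                continue
            s = scaled[i, b]
            for tot, p in dist.items():
                new[tot + s] = new.get(tot + s, 0.0) + p * q
        dist = new
    keys = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[k] for k in keys])
    scores = keys * granularity
    if ninf_mass > 0:
        scores = np.concatenate([[-np.inf], scores])
        probs = np.concatenate([[ninf_mass], probs])
    return scores, probs


def _grid_tolerance(pwm: PWM, granularity: float = SCORE_GRANULARITY) -> float:
    # per-position rounding shifts a word's grid score by at most
    # granularity/2; this slack keeps float-score and grid-score
    # comparisons consistent
    return granularity * (pwm.width / 2.0 + 0.5)


def exact_score_pvalue(pwm: PWM, score: float,
                       granularity: float = SCORE_GRANULARITY) -> float:
    """P(score of a random background word >= score), exact via DP."""
    if np.isneginf(score):
        return 1.0
    scores, probs = score_distribution(pwm, granularity)
    tol = _grid_tolerance(pwm, granularity)
    return float(probs[scores >= score - tol].sum())


def score_threshold(pwm: PWM, pvalue_threshold: float = 1e-4,
                    granularity: float = SCORE_GRANULARITY) -> float:
    """Smallest score whose exact tail probability is <= the threshold.

    Returned on the float scale with the discretization slack subtracted,
    so any word at or above the grid threshold passes a float comparison.
    """
    scores, probs = score_distribution(pwm, granularity)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= pvalue_threshold
    if not ok.any():
        return np.inf  # no achievable score is that rare
    return float(scores[ok][0]) - _grid_tolerance(pwm, granularity)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PeakWindow:
    """Fixed-width window around a peak summit with its sequence."""

    peak_id: str
    chrom: str
    summit: int
    start: int
    end: int
    sequence: str
    truncated: bool = False


def peak_windows(peaks: pd.DataFrame, sequences: dict,
                 flank: int = 500) -> list:
    """[summit − flank, summit + flank) windows, truncated at contig ends.

    ``peaks`` needs columns chrom/start/end (0-based half-open BED) and
    optionally name and summit; without a summit column the interval
    midpoint is used.
    """
    windows = []
    for i, row in peaks.iterrows():
        chrom = row["chrom"]
        summit = int(row["summit"]) if "summit" in peaks.columns else int(
            (row["start"] + row["end"]) // 2)
        name = row["name"] if "name" in peaks.columns else f"peak{i}"
        seq = sequences[chrom]
        start, end = summit - flank, summit + flank
        truncated = start < 0 or end > len(seq)
        start_c, end_c = max(start, 0), min(end, len(seq))
        windows.append(PeakWindow(peak_id=name, chrom=chrom, summit=summit,
                                  start=start_c, end=end_c,
                                  sequence=seq[start_c:end_c],
                                  truncated=truncated))
    return windows


def scan_sequence(sequence: str, pwm: PWM, threshold_score: float) -> list:
    """Scan one sequence on both strands; return (offset, strand, score).

    Offsets are 0-based positions of the match start on the forward strand.
    Offsets covering an N are skipped. A hit requires score >= threshold.
    """
    enc = _encode(sequence)
    w = pwm.width
    L = len(enc)
    if L < w:
        return []
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]  # reverse-complement scoring matrix
    hits = []
    n_off = L - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    idx = np.arange(w)
    for strand, mat in (("+", lo), ("-", lo_rc)):
        scores = np.full(n_off, -np.inf)
        v = windows[valid]
        if len(v):
            scores[valid] = mat[idx, v].sum(axis=1)
        for off in np.flatnonzero(valid & (scores >= threshold_score)):
            hits.append((int(off), strand, float(scores[off])))
    return hits


def scan(windows, pwms, pvalue_threshold: float = 1e-4) -> pd.DataFrame:
    """Scan peak windows with a set of PWMs.

    Returns a hit table (peak_id, motif_id, offset, strand, score,
    pvalue) where ``offset`` is relative to the summit (negative =
    upstream on the forward strand) and ``pvalue`` is the exact null tail
    of the score.
    """
    if isinstance(windows, PeakWindow):
        windows = [windows]
    if isinstance(pwms, PWM):
        pwms = [pwms]
    rows = []
    for pwm in pwms:
        thr = score_threshold(pwm, pvalue_threshold)
        scores, probs = score_distribution(pwm)
        tail = np.cumsum(probs[::-1])[::-1]
        tol = _grid_tolerance(pwm)
        for win in windows:
            for off, strand, sc in scan_sequence(win.sequence, pwm, thr):
                p = float(tail[scores >= sc - tol][0]) \
                    if (scores >= sc - tol).any() else 0.0
                rows.append((win.peak_id, pwm.name,
                             win.start + off - win.summit, strand, sc, p))
    return pd.DataFrame(rows, columns=["peak_id", "motif_id", "offset",
                                       "strand", "score", "pvalue"])


def brute_force_scan(sequence: str, pwm: PWM) -> list:
    """All (offset, strand, score) by direct enumeration — test oracle."""
    out = []
    w = pwm.width
    lo = pwm.log_odds
    for off in range(len(sequence) - w + 1):
        word = sequence[off:off + w].upper()
        if any(c not in _BASE_INDEX for c in word):
            continue
        fwd = sum(lo[i, _BASE_INDEX[c]] for i, c in enumerate(word))
        rc = revcomp(word)
        rev = sum(lo[i, _BASE_INDEX[c]] for i, c in enumerate(rc))
        out.append((off, "+", float(fwd)))
        out.append((off, "-", float(rev)))
    return out


def enumerate_score_pvalue(pwm: PWM, score: float) -> float:
    """Exhaustive 4^w tail probability — test oracle for small widths."""
    lo = pwm.log_odds
    tol = _grid_tolerance(pwm)
    total = 0.0
    for word in product(range(4), repeat=pwm.width):
        s = sum(lo[i, b] for i, b in enumerate(word))
        if s >= score - tol:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


# ---------------------------------------------------------------------------
# enrichment and scenarios
# ---------------------------------------------------------------------------

def estimate_background_rate(sequences: dict, pwm: PWM,
                             window_size: int = 1000, n_windows: int = 10000,
                             pvalue_threshold: float = 1e-4,
                             seed: int = 0) -> float:
    """Fraction of uniformly sampled genome windows containing >= 1 hit."""
    rng = np.random.default_rng(seed)
    chroms = sorted(sequences)
    lengths = np.array([len(sequences[c]) - window_size for c in chroms])
    lengths = np.maximum(lengths, 0)
    weights = lengths / lengths.sum()
    thr = score_threshold(pwm, pvalue_threshold)
    hits = 0
    for _ in range(n_windows):
        c = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, len(sequences[c]) - window_size + 1))
        if scan_sequence(sequences[c][start:start + window_size], pwm, thr):
            hits += 1
    return hits / n_windows


def enrichment_vs_background(k: int, n: int, pi0: float):
    """Motif enrichment of k hit windows of n versus background rate pi0.

    Returns (fold, one-sided binomial p = P(Bin(n, pi0) >= k)).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    fold = (k / n) / pi0 if n > 0 and pi0 > 0 else np.nan
    p = float(stats.binom.sf(k - 1, n, pi0)) if k > 0 else 1.0
    return fold, p


def classify_scenarios(hits: pd.DataFrame, bait_motif_ids,
                       partner_motif_ids: dict, peak_ids=None):
    """Classify peaks into direct / composite / tethered recruitment.

    Motif presence per peak is the boolean union of hits over a family's
    PWMs. Per partner: both bait and partner motifs → "composite"; bait
    only → "bait_only" (direct binding); partner only → "partner_only"
    (tethered, indirect recruitment of the bait); neither → "none".
    Returns (per peak × partner DataFrame, aggregate fraction table).
    """
    bait_ids = set(bait_motif_ids)
    if peak_ids is None:
        peak_ids = sorted(hits["peak_id"].unique())
    by_peak = hits.groupby("peak_id")["motif_id"].agg(set).to_dict()
    rows = []
    for pid in peak_ids:
        present = by_peak.get(pid, set())
        has_bait = bool(present & bait_ids)
        for partner, ids in partner_motif_ids.items():
            has_partner = bool(present & set(ids))
            if has_bait and has_partner:
                scenario = "composite"
            elif has_bait:
                scenario = "bait_only"
            elif has_partner:
                scenario = "partner_only"
            else:
                scenario = "none"
            rows.append((pid, partner, has_bait, has_partner, scenario))
    calls = pd.DataFrame(rows, columns=["peak_id", "partner", "has_bait",
                                        "has_partner", "scenario"])
    frac = (calls.groupby(["partner", "scenario"]).size()
            / len(peak_ids)).unstack(fill_value=0.0)
    return calls, frac


def annotate_peaks_to_genes(peaks: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to its nearest TSS by summit distance (ties → all).

    Returns a long DataFrame (peak_id, gene, distance).
    """
    rows = []
    for _, row in peaks.iterrows():
        summit = int(row["summit"]) if "summit" in peaks.columns else int(
            (row["start"] + row["end"]) // 2)
        sub = tss[tss["chrom"] == row["chrom"]]
        if sub.empty:
            continue
        dist = (sub["tss"] - summit).abs()
        best = dist.min()
        for _, g in sub[dist == best].iterrows():
            rows.append((row.get("name", "peak"), g["gene"], int(best)))
    return pd.DataFrame(rows, columns=["peak_id", "gene", "distance"])


def gene_motif_table(hits: pd.DataFrame, peak_genes: pd.DataFrame,
                     motif_ids=None) -> pd.DataFrame:
    """Per gene, the union of motif presence over its assigned peaks."""
    if motif_ids is None:
        motif_ids = sorted(hits["motif_id"].unique())
    by_peak = hits.groupby("peak_id")["motif_id"].agg(set).to_dict()
    genes = sorted(peak_genes["gene"].unique())
    data = {m: [] for m in motif_ids}
    for g in genes:
        peaks_of_g = peak_genes.loc[peak_genes["gene"] == g, "peak_id"]
        present = set().union(*(by_peak.get(p, set()) for p in peaks_of_g))
        for m in motif_ids:
            data[m].append(m in present)
    return pd.DataFrame(data, index=genes)


def motif_combination_counts(gene_motifs: pd.DataFrame) -> pd.Series:
    """Power-set tally of motif combinations across genes."""
    combos = gene_motifs.apply(
        lambda r: "+".join(sorted(gene_motifs.columns[r])) or "(none)", axis=1)
    return combos.value_counts()


def intersect_with_genesets(gene_motifs: pd.DataFrame,
                            genesets: dict) -> pd.DataFrame:
    """Cross-tab: genes per (gene set × motif), plus set sizes with peaks."""
    rows = []
    for set_name, genes in genesets.items():
        with_peaks = [g for g in genes if g in gene_motifs.index]
        row = {"gene_set": set_name, "n_genes": len(set(genes)),
               "n_with_peak": len(with_peaks)}
        for m in gene_motifs.columns:
            row[f"n_{m}"] = int(gene_motifs.loc[with_peaks, m].sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_set")
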