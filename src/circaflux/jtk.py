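"""JTK_cycle rhythmicity testing and transcriptome summaries.

JTK_cycle detects rhythmic transcripts nonparametrically: for every
candidate (period, lag) a cosine reference waveform is evaluated at the
sample timepoints and ranked; the Jonckheere-Terpstra/Kendall statistic S
counts sign-concordant pairs between the data and the reference ordering;
the exact permutation null of S (which depends only on the reference's tie
structure) gives an exact p-value, Bonferroni-adjusted over the scanned
(period, lag) hypotheses.  The best hypothesis per gene supplies the
estimated period and lag (phase of peak), and a robust Hodges-Lehmann
estimate supplies the amplitude on the cpm scale.

Downstream summaries follow the standard rhythmic-transcriptome workflow:
cpm filtering, selection by adjusted p and amplitude, day/night phase
binning, Venn-region overlaps between condition gene sets, phase-ordered
[-1, 1]-scaled heatmap matrices, and an ANOVA + Tukey HSD rule for genes
whose mean temporal profile differs between conditions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidInputError

DEFAULT_PERIODS_H = (24.0,)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def cpm_filter(matrix: pd.DataFrame, min_cpm: float = 1.0,
               min_samples: int = 3) -> tuple[pd.DataFrame, dict]:
    """Keep genes with >= ``min_samples`` samples at >= ``min_cpm``.

    Returns the filtered matrix and a report with kept/dropped counts.
    """
    keep = (matrix >= min_cpm).sum(axis=1) >= min_samples
    report = {"kept": int(keep.sum()), "dropped": int((~keep).sum()),
              "min_cpm": min_cpm, "min_samples": min_samples}
    return matrix.loc[keep], report


# ---------------------------------------------------------------------------
# reference waveforms
# ---------------------------------------------------------------------------

@dataclass
class JTKReferences:
    """Ranked cosine references for one period over a grid of lags."""

    period_h: float
    lags_h: np.ndarray          # (n_lags,)
    ranks: np.ndarray           # (n_lags, n_samples), tie-aware average ranks
    timepoints_h: np.ndarray    # per-sample timepoint (replicates repeat)


def jtk_references(timepoints_h: np.ndarray, period_h: float = 24.0,
                   lag_step_h: float | None = None) -> JTKReferences:
    """Rank reference cosines cos(2*pi*(t - lag)/period) over a lag grid.

    Replicates share their timepoint's reference value, so the references
    carry ties; the default lag resolution is half the sampling interval,
    which lets estimated peak phases fall between sampled timepoints.
    """
    t = np.asarray(timepoints_h, dtype=float)
    if lag_step_h is None:
        uniq = np.unique(t)
        if uniq.size < 2:
            raise InvalidInputError("need at least two distinct timepoints")
        lag_step_h = float(np.diff(uniq).min()) / 2.0
    if lag_step_h <= 0:
        raise InvalidInputError("lag_step_h must be positive")
    lags = np.arange(0.0, period_h - 1e-9, lag_step_h)
    if lags.size == 0:
        raise InvalidInputError("empty lag grid")
    ref = np.cos(2 * np.pi * (t[None, :] - lags[:, None]) / period_h)
    ref = np.round(ref, 12)  # collapse numerically-equal cosines into ties
    ranks = np.vstack([stats.rankdata(row) for row in ref])
    return JTKReferences(period_h, lags, ranks, t)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra / Kendall statistic
# ---------------------------------------------------------------------------

def jt_statistic(values: np.ndarray, ref_ranks: np.ndarray) -> tuple[int, float]:
    """Concordance S and Kendall-style tau of data against a reference.

    S sums, over sample pairs comparable under the reference (distinct
    reference ranks), the sign concordance of the data ordering with the
    reference ordering; pairs tied in the data contribute zero.  tau is S
    over the number of reference-comparable pairs (the maximum attainable
    |S| for tie-free data).  With all data values tied tau is undefined and
    returned as NaN.
    """
    x = np.asarray(values, dtype=float)
    r = np.asarray(ref_ranks, dtype=float)
    if x.size != r.size:
        raise InvalidInputError("values and reference must have equal length")
    iu, ju = np.triu_indices(x.size, 1)
    rs = np.sign(r[ju] - r[iu])
    s = int(np.sum(np.sign(x[ju] - x[iu]) * rs))
    m = int(np.count_nonzero(rs))
    if np.all(x == x[0]) or m == 0:
        return s, math.nan
    return s, s / m


# ---------------------------------------------------------------------------
# exact null distribution (Harding-style convolution)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _gaussian_binomial(m: int, n: int) -> tuple[int, ...]:
    """Coefficients over u of the Gaussian binomial [m+n choose n]_q.

    Coefficient u counts the interleavings of a block of n items into a
    block of m items with exactly u cross-block inversions.  Computed with
    the q-Pascal recurrence in exact integer arithmetic.
    """
    prev: list[list[int]] = [[1]]  # row a=0
    for a in range(1, m + n + 1):
        cur: list[list[int]] = []
        for b in range(0, min(a, n) + 1):
            if b == 0 or b == a:
                cur.append([1])
                continue
            p1 = prev[b - 1]
            p2 = prev[b] if b < len(prev) else []
            out = [0] * max(len(p1), len(p2) + b)
            for i, v in enumerate(p1):
                out[i] += v
            for i, v in enumerate(p2):
                out[i + b] += v
            cur.append(out)
        prev = cur
    return tuple(prev[n])


@dataclass
class JTKNull:
    """Null distribution of S for one reference tie structure."""

    n: int
    max_s: int                      # number of reference-comparable pairs
    s_support: np.ndarray | None    # exact support (None => normal approx)
    pmf: np.ndarray | None
    sd: float
    exact: bool

    def p_two_sided(self, s: float) -> float:
        """P(|S'| >= |s|) under the null (exact or normal-approximate)."""
        if self.max_s == 0:
            return 1.0
        if self.exact:
            p = float(self.pmf[np.abs(self.s_support) >= abs(s) - 1e-9].sum())
            return min(max(p, 0.0), 1.0)
        if self.sd == 0:
            return 1.0
        # lattice step 2 => continuity correction of 1
        z = (abs(s) - 1.0) / self.sd
        return min(1.0, math.erfc(z / math.sqrt(2.0)))


def jtk_null(ref_ranks: np.ndarray, exact_limit: int = 50) -> JTKNull:
    """Exact permutation null of S for a reference's tie structure.

    Under the null the (tie-free) data values are exchangeable, so the
    concordant-pair count c against a reference with groups of tied ranks
    of sizes n_1..n_g is distributed as the Jonckheere-Terpstra statistic:
    its generating function factors into sequential Gaussian binomials,
    which are convolved group by group.  S = 2c - M where M is the number
    of comparable pairs.  Beyond ``exact_limit`` samples a normal
    approximation with continuity correction is used.
    """
    r = np.asarray(ref_ranks, dtype=float)
    n = r.size
    sizes = [int(c) for c in pd.Series(r).value_counts().sort_index()]
    max_s = (n * n - sum(k * k for k in sizes)) // 2
    var_jt = (n * n * (2 * n + 3) - sum(k * k * (2 * k + 3) for k in sizes)) / 72.0
    sd = 2.0 * math.sqrt(max(var_jt, 0.0))
    if n > exact_limit:
        return JTKNull(n, max_s, None, None, sd, exact=False)
    counts: list[int] = [1]
    m = 0
    for k in sizes:
        if m > 0:
            gb = _gaussian_binomial(m, k)
            new = [0] * (len(counts) + len(gb) - 1)
            for i, a in enumerate(counts):
                if a:
                    for j, b in enumerate(gb):
                        new[i + j] += a * b
            counts = new
        m += k
    total = sum(counts)
    pmf = np.array([c / total for c in counts], dtype=float)
    s_support = 2 * np.arange(len(counts)) - max_s
    return JTKNull(n, max_s, s_support, pmf, sd, exact=True)


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def _hl_amplitude(x: np.ndarray, t: np.ndarray, period: float, lag: float) -> float:
    # Hodges-Lehmann peak-to-trough: median of pairwise differences between
    # samples within a quarter period of the cosine peak (t = lag) and of
    # the trough (t = lag + period/2); amplitude is half of it.
    def circ_dist(a, b):
        d = np.abs((a - b) % period)
        return np.minimum(d, period - d)

    peak = circ_dist(t, lag) < period / 4.0
    trough = circ_dist(t, lag + period / 2.0) < period / 4.0
    if not peak.any() or not trough.any():
        return 0.0
    diffs = x[peak][:, None] - x[trough][None, :]
    return 0.5 * float(np.median(diffs))


def jtk_scan(matrix: pd.DataFrame, annot: pd.DataFrame,
             periods_h: tuple[float, ...] = DEFAULT_PERIODS_H,
             lag_step_h: float | None = None,
             exact_limit: int = 50) -> pd.DataFrame:
    """JTK_cycle over every gene: best (period, lag), exact p, amplitude.

    For each gene the (period, lag) hypothesis maximizing |tau| is chosen
    (ties prefer positive tau, then the earlier lag); the exact two-sided p
    comes from the permutation null of that reference's tie structure and
    is Bonferroni-adjusted by the number of hypotheses scanned.  Degenerate
    genes (all values tied) get p = 1, amplitude 0.  The default scan uses
    the single 24 h period: one sampled cycle at six timepoints cannot
    discriminate nearby periods (configurable for longer designs).

    Columns of ``matrix`` must match ``annot['sample']``; ``annot`` needs a
    ``timepoint_h`` column.
    """
    annot = annot.set_index("sample").loc[list(matrix.columns)].reset_index()
    t = annot["timepoint_h"].to_numpy(dtype=float)
    n = t.size

    hyps: list[tuple[float, float, np.ndarray]] = []
    for period in periods_h:
        refs = jtk_references(t, period, lag_step_h)
        for lag, ranks in zip(refs.lags_h, refs.ranks):
            hyps.append((period, float(lag), ranks))
    n_hyp = len(hyps)

    iu, ju = np.triu_indices(n, 1)
    x = matrix.to_numpy(dtype=float)
    d_sign = np.sign(x[:, ju] - x[:, iu]).astype(np.int8)

    ref_signs = np.empty((n_hyp, iu.size), dtype=np.int8)
    m_pairs = np.empty(n_hyp, dtype=np.int64)
    nulls: list[JTKNull] = []
    null_cache: dict[tuple[int, ...], JTKNull] = {}
    for h, (_, _, ranks) in enumerate(hyps):
        rs = np.sign(ranks[ju] - ranks[iu]).astype(np.int8)
        ref_signs[h] = rs
        m_pairs[h] = np.count_nonzero(rs)
        key = tuple(sorted(pd.Series(ranks).value_counts().to_list()))
        if key not in null_cache:
            null_cache[key] = jtk_null(ranks, exact_limit)
        nulls.append(null_cache[key])

    s_mat = d_sign.astype(np.int64) @ ref_signs.T.astype(np.int64)
    with np.errstate(invalid="ignore"):
        tau = s_mat / m_pairs[None, :]
    # best hypothesis: max |tau|, tie-break positive tau then earlier lag
    score = (np.abs(tau) + 1e-9 * (tau > 0)
             - 1e-12 * np.arange(n_hyp)[None, :])
    best = np.argmax(score, axis=1)

    genes = list(matrix.index)
    rows = []
    degenerate = np.all(d_sign == 0, axis=1)
    for g, gene in enumerate(genes):
        h = int(best[g])
        period, lag, _ = hyps[h]
        if degenerate[g]:
            rows.append((gene, period, math.nan, math.nan, 1.0, 1.0, 0.0))
            continue
        s = int(s_mat[g, h])
        p = nulls[h].p_two_sided(s)
        adj = min(1.0, p * n_hyp)
        amp = _hl_amplitude(x[g], t, period, lag)
        rows.append((gene, period, lag, float(tau[g, h]), p, adj, amp))
    return pd.DataFrame(rows, columns=["gene", "period_h", "lag_h", "tau",
                                       "p", "adj_p", "amplitude"]
                        ).set_index("gene")


def select_rhythmic(result: pd.DataFrame, p_max: float = 0.01,
                    amp_min: float = 10.0,
                    use_adjusted: bool = True) -> pd.Index:
    """Genes passing both the significance and amplitude criteria."""
    p = result["adj_p"] if use_adjusted else result["p"]
    return result.index[(p < p_max) & (result["amplitude"] > amp_min)]


# ---------------------------------------------------------------------------
# phase summaries and overlaps
# ---------------------------------------------------------------------------

@dataclass
class DayNightSummary:
    """Fraction of peak phases in the light ([0,12)) vs dark half-day."""

    day_fraction: float
    night_fraction: float
    bin_edges_h: np.ndarray
    bin_counts: np.ndarray
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def phase_day_night(lags_h: np.ndarray, bin_h: float = 2.0) -> DayNightSummary:
    """Day/night split and polar-bin histogram of peak phases (mod 24 h).

    The boundary value 12 h counts as night, matching the [0-12) / [12-24)
    interval convention.
    """
    lags = np.asarray(lags_h, dtype=float) % 24.0
    edges = np.arange(0.0, 24.0 + 1e-9, bin_h)
    if lags.size == 0:
        return DayNightSummary(math.nan, math.nan, edges,
                               np.zeros(edges.size - 1, dtype=int), 0)
    day = float(np.mean(lags < 12.0))
    counts, _ = np.histogram(lags, bins=edges)
    return DayNightSummary(day, 1.0 - day, edges, counts, int(lags.size))


def set_overlaps(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact Venn-region cardinalities for two or more labelled gene sets.

    Keys are tuples of the labels a region belongs to (exclusively); e.g.
    for sets A, B the key ``("A",)`` counts elements of A only and
    ``("A", "B")`` elements of both.
    """
    if len(sets) < 2:
        raise InvalidInputError("need at least two sets")
    labels = list(sets)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = set.intersection(*(set(sets[l]) for l in combo))
            for other in labels:
                if other not in combo:
                    inside -= set(sets[other])
            regions[combo] = len(inside)
    return regions


def heatmap_matrix(matrix: pd.DataFrame, annot: pd.DataFrame,
                   result: pd.DataFrame, genes) -> pd.DataFrame:
    """Phase-ordered, [-1, 1]-scaled mean temporal profiles for heatmaps.

    Each selected gene's replicate-averaged profile over timepoints is
    min-max scaled to [-1, 1] (a constant profile scales to all zeros) and
    rows are sorted by the gene's estimated lag, ascending.
    """
    genes = list(genes)
    if not genes:
        raise InvalidInputError("selected gene set is empty")
    annot = annot.set_index("sample").loc[list(matrix.columns)].reset_index()
    t = annot["timepoint_h"].to_numpy(dtype=float)
    tps = np.unique(t)
    prof = np.column_stack([matrix.loc[genes, matrix.columns[t == tp]]
                            .mean(axis=1) for tp in tps])
    lo = prof.min(axis=1, keepdims=True)
    hi = prof.max(axis=1, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 0, 2.0 * (prof - lo) / np.where(span > 0, span, 1.0) - 1.0, 0.0)
    df = pd.DataFrame(scaled, index=genes, columns=[f"t{tp:g}" for tp in tps])
    order = result.loc[genes, "lag_h"].sort_values(kind="stable").index
    return df.loc[order]


# ---------------------------------------------------------------------------
# differential mean-profile genes
# ---------------------------------------------------------------------------

@dataclass
class DEGResult:
    """ANOVA + Tukey HSD differential-expression call per gene."""

    anova_p: pd.Series                       # per-gene one-way ANOVA p
    degs_by_pair: dict[tuple[str, str], set]  # significant contrasts
    selected: set                            # genes significant in any pair


def deg_anova(matrices: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
              pairs: list[tuple[str, str]] | None = None,
              p_anova: float = 0.01, p_posthoc: float = 0.05) -> DEGResult:
    """Genes whose mean temporal profile differs between conditions.

    ``matrices`` maps condition label to its (matrix, annot) pair; shared
    genes are analyzed.  For each gene the replicate-averaged profile over
    timepoints is computed per condition; one-way ANOVA across conditions
    (P < ``p_anova``) is followed by Tukey's HSD (P < ``p_posthoc``) to
    assign the specific contrasts.
    """
    if len(matrices) < 2:
        raise InvalidInputError("need at least two conditions")
    labels = list(matrices)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    genes = set.intersection(*(set(m.index) for m, _ in matrices.values()))
    genes = sorted(genes)
    profiles = {}
    for label, (m, annot) in matrices.items():
        annot = annot.set_index("sample").loc[list(m.columns)].reset_index()
        t = annot["timepoint_h"].to_numpy(dtype=float)
        tps = np.unique(t)
        profiles[label] = np.column_stack(
            [m.loc[genes, m.columns[t == tp]].mean(axis=1) for tp in tps])

    anova_p = {}
    degs_by_pair: dict[tuple[str, str], set] = {p: set() for p in pairs}
    for g, gene in enumerate(genes):
        groups = [profiles[l][g] for l in labels]
        if np.ptp(np.concatenate(groups)) == 0:
            anova_p[gene] = 1.0
            continue
        try:
            p = float(stats.f_oneway(*groups).pvalue)
        except Exception:
            p = 1.0
        if math.isnan(p):
            p = 1.0
        anova_p[gene] = p
        if p >= p_anova:
            continue
        hsd = stats.tukey_hsd(*groups)
        for a, b in pairs:
            ia, ib = labels.index(a), labels.index(b)
            if hsd.pvalue[ia, ib] < p_posthoc:
                degs_by_pair[(a, b)].add(gene)
    selected = set().union(*degs_by_pair.values()) if degs_by_pair else set()
    return DEGResult(pd.Series(anova_p, name="anova_p"), degs_by_pair, selected)
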