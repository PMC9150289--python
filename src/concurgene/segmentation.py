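"""Per-sample copy-number segmentation and five-state CNV calling.

Marker-level log-intensity ratios (0 ~ diploid) are segmented chromosome by
chromosome with circular binary segmentation (CBS): the candidate change
points maximise a two-sample t statistic over all arcs of the chromosome
(treated as a circle) and are accepted when a within-segment permutation
test rejects equality of means.  Segment levels that remain statistically
indistinguishable genome-wide are collapsed (MergeLevels), and segments are
called AMP / GAIN / NEUTRAL / LOSS / HOMDEL against multiples of each
array's median absolute deviation (MAD).

Conventions
-----------
* Coordinates are 1-based and inclusive at both ends.
* A marker map is a :class:`pandas.DataFrame` with columns
  ``marker_id``, ``chromosome``, ``position`` (positions strictly
  increasing within a chromosome).
* A log-ratio matrix is a DataFrame indexed by ``marker_id`` with one
  column per sample; missing values are NaN, never silent zeros.
* Segment tables carry columns
  ``sample_id, chromosome, start_pos, end_pos, n_markers, seg_mean``
  (the SEG dialect written by :mod:`concurgene.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SEG_COLUMNS = ["sample_id", "chromosome", "start_pos", "end_pos", "n_markers", "seg_mean"]

#: Ordered CNV states, most deleted to most amplified.
CNV_STATES = ["HOMDEL", "LOSS", "NEUTRAL", "GAIN", "AMP"]


@dataclass(frozen=True)
class ArrayNoiseStat:
    """Per-array noise scale: the (unscaled) MAD of its log ratios."""

    sample_id: str
    mad: float


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check marker-map invariants; returns the frame untouched."""
    required = {"marker_id", "chromosome", "position"}
    missing = required - set(marker_map.columns)
    if missing:
        raise ValueError(f"marker map lacks columns: {sorted(missing)}")
    if marker_map["marker_id"].duplicated().any():
        raise ValueError("duplicated marker_id in marker map")
    for chrom, grp in marker_map.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
    return marker_map


def compute_mad(profile: np.ndarray | pd.Series, scaled: bool = False) -> float:
    """Median absolute deviation of one array's log ratios.

    Unscaled by default (no 1.4826 normal-consistency factor); pass
    ``scaled=True`` to apply it.  NaNs are ignored; an all-missing profile
    is an error.
    """
    x = np.asarray(profile, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("profile has no finite values")
    mad = float(np.median(np.abs(x - np.median(x))))
    return mad * 1.4826 if scaled else mad


def array_noise_stats(log_ratios: pd.DataFrame, scaled: bool = False) -> pd.Series:
    """MAD per sample column of a log-ratio matrix."""
    return pd.Series(
        {s: compute_mad(log_ratios[s], scaled=scaled) for s in log_ratios.columns},
        name="mad",
    )


# ---------------------------------------------------------------------------
# outlier smoothing
# ---------------------------------------------------------------------------

def smooth_outliers(
    profile: pd.Series,
    marker_map: pd.DataFrame,
    k: float = 4.0,
    shrink: float = 2.0,
    sd: float | None = None,
) -> pd.Series:
    """Shrink singleton outliers toward their nearer neighbour.

    A point is a singleton outlier when it deviates from *both* neighbours
    by more than ``k`` standard deviations in the same direction.  It is
    replaced by ``nearer neighbour + sign * shrink * SD``.  The SD is a
    robust per-profile estimate (1.4826 x MAD of first differences / sqrt 2)
    unless given explicitly.  Chromosomes with fewer than three markers are
    returned unchanged.
    """
    out = profile.copy()
    chroms = marker_map.set_index("marker_id").loc[profile.index, "chromosome"]
    for _, idx in profile.groupby(chroms, sort=False).groups.items():
        x = profile.loc[idx].to_numpy(dtype=float)
        n = x.size
        if n < 3:
            continue
        if sd is None:
            diffs = np.diff(x[np.isfinite(x)])
            est = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
        else:
            est = sd
        if est <= 0:
            continue
        y = x.copy()
        for i in range(1, n - 1):
            left, right = x[i - 1], x[i + 1]
            d_left, d_right = x[i] - left, x[i] - right
            if min(d_left, d_right) > k * est or max(d_left, d_right) < -k * est:
                neighbour = left if abs(d_left) <= abs(d_right) else right
                y[i] = neighbour + np.sign(x[i] - neighbour) * shrink * est
        out.loc[idx] = y
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

#: above this segment length the arc scan evaluates a coarse endpoint grid
#: first and then refines exactly around the best pair (quadratic cost cap)
_EXACT_SCAN_LIMIT = 300


def _arc_t_over(
    x_stats: tuple[np.ndarray, np.ndarray, float, float, int],
    i_cand: np.ndarray,
    j_cand: np.ndarray,
) -> tuple[float, int, int]:
    """Max |t| over arc endpoint pairs (i, j), i < j, from candidate sets."""
    s, q, tot_s, tot_q, n = x_stats
    i = i_cand[:, None]
    j = j_cand[None, :]
    k = j - i  # arc size
    valid = (k >= 1) & (k <= n - 1)
    k = np.where(valid, k, 1)
    m = n - k
    sum_in = s[j] - s[i]
    q_in = q[j] - q[i]
    mean_in = sum_in / k
    mean_out = (tot_s - sum_in) / m
    ss = (q_in - sum_in**2 / k) + ((tot_q - q_in) - (tot_s - sum_in) ** 2 / m)
    df = max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss / df * (1.0 / k + 1.0 / m))
        t = np.abs(mean_in - mean_out) / se
    diff = np.abs(mean_in - mean_out)
    t = np.where(se > 0, t, np.where(diff > 1e-12, np.inf, 0.0))
    t = np.where(valid, t, -np.inf)
    flat = int(np.argmax(t))
    bi, bj = divmod(flat, j_cand.size)
    return float(t.flat[flat]), int(i_cand[bi]), int(j_cand[bj])


def _max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal two-sample |t| over all arcs of ``x`` treated as a circle.

    Arcs are index ranges ``(i, j]`` with ``0 <= i < j <= n`` compared
    against their complement (the complement of an interior arc wraps
    around, which is what makes the scan circular).  Returns
    ``(t_max, i, j)``; degenerate pooled variance yields ``inf`` when the
    group means differ and 0 otherwise.  Long segments are scanned on a
    coarse endpoint grid first, then refined exactly around the best pair.
    """
    n = x.size
    s = np.concatenate(([0.0], np.cumsum(x)))
    q = np.concatenate(([0.0], np.cumsum(x * x)))
    stats = (s, q, s[-1], q[-1], n)
    full = np.arange(n + 1)
    if n <= _EXACT_SCAN_LIMIT:
        return _arc_t_over(stats, full, full)
    stride = int(np.ceil(n / 256))
    grid = np.unique(np.concatenate([full[::stride], [n]]))
    t_best, bi, bj = _arc_t_over(stats, grid, grid)
    lo_i = max(bi - stride, 0)
    hi_i = min(bi + stride, n)
    lo_j = max(bj - stride, 0)
    hi_j = min(bj + stride, n)
    t_ref, ri, rj = _arc_t_over(
        stats, np.arange(lo_i, hi_i + 1), np.arange(lo_j, hi_j + 1)
    )
    return (t_ref, ri, rj) if t_ref >= t_best else (t_best, bi, bj)


def _split_p_value(
    x: np.ndarray, t_obs: float, alpha: float, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p for the maximal arc statistic, with early stopping.

    Early exit once the add-one p is guaranteed above ``alpha`` (the split
    will be rejected regardless of the remaining permutations).
    """
    reject_count = int(np.floor(alpha * (1 + n_perm)))  # exceedances allowed
    exceed = 0
    for b in range(n_perm):
        t_b, _, _ = _max_arc_t(rng.permutation(x))
        if t_b >= t_obs:
            exceed += 1
            if 1 + exceed > reject_count:
                return (1 + exceed) / (2 + b)  # > alpha by construction
    return (1 + exceed) / (1 + n_perm)


def _cbs_recurse(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    breaks: list[int],
) -> None:
    n = x.size
    if n < 2:
        return
    t_obs, i, j = _max_arc_t(x)
    if t_obs <= 0:
        return
    p = _split_p_value(x, t_obs, alpha, n_perm, rng)
    if p > alpha:
        return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return
    for c in cuts:
        breaks.append(offset + c)
    edges = [0, *cuts, n]
    for a, b in zip(edges[:-1], edges[1:]):
        _cbs_recurse(x[a:b], offset + a, alpha, n_perm, rng, breaks)


def cbs_segment(
    profile: pd.Series,
    marker_map: pd.DataFrame,
    sample_id: str | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment one sample's profile into constant-copy-number regions.

    Parameters
    ----------
    profile
        Log ratios indexed by ``marker_id`` in marker-map order.
    alpha
        Significance level for accepting a change point (default 0.01).
    n_perm
        Permutations per candidate split (default 1000).

    Returns a SEG-dialect DataFrame; segments of each chromosome are
    contiguous, non-overlapping and cover all of its markers, and each
    ``seg_mean`` is the arithmetic mean of its member markers.
    """
    x_all = profile.to_numpy(dtype=float)
    if not np.all(np.isfinite(x_all)):
        raise ValueError("profile contains non-finite values; impute or drop first")
    if sample_id is None:
        sample_id = str(profile.name) if profile.name is not None else "sample"
    mm = marker_map.set_index("marker_id").loc[profile.index]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in mm.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        x = profile.loc[grp.index].to_numpy(dtype=float)
        breaks: list[int] = []
        _cbs_recurse(x, 0, alpha, n_perm, rng, breaks)
        edges = [0, *sorted(set(breaks)), x.size]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append(
                {
                    "sample_id": sample_id,
                    "chromosome": chrom,
                    "start_pos": int(pos[a]),
                    "end_pos": int(pos[b - 1]),
                    "n_markers": b - a,
                    "seg_mean": float(np.mean(x[a:b])),
                }
            )
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def segment_cohort(
    log_ratios: pd.DataFrame,
    marker_map: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    smooth: bool = True,
    merge: bool = True,
) -> pd.DataFrame:
    """CBS for every sample column, seeded per sample from the global seed."""
    validate_marker_map(marker_map)
    parts = []
    for idx, sample in enumerate(log_ratios.columns):
        prof = log_ratios[sample]
        if smooth:
            prof = smooth_outliers(prof, marker_map)
        segs = cbs_segment(
            prof,
            marker_map,
            sample_id=str(sample),
            alpha=alpha,
            n_perm=n_perm,
            seed=int(np.random.default_rng([seed, idx]).integers(2**31 - 1)),
        )
        if merge:
            segs = merge_levels(segs, prof, marker_map)
        parts.append(segs)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# MergeLevels
# ---------------------------------------------------------------------------

def merge_levels(
    segments: pd.DataFrame,
    profile: pd.Series,
    marker_map: pd.DataFrame,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Collapse genome-wide segment levels that are indistinguishable.

    Iteratively finds the pair of levels whose member-marker distributions
    have the largest Wilcoxon rank-sum p value and merges it while that p
    exceeds ``threshold``, recomputing each level's mean over all its
    member markers.  Adjacent same-level segments are fused, so the output
    still tiles each chromosome.
    """
    if len(segments) <= 1:
        return segments.copy()
    mm = marker_map.set_index("marker_id").loc[profile.index]
    member_values: list[np.ndarray] = []
    for seg in segments.itertuples():
        mask = (mm["chromosome"] == seg.chromosome) & (
            mm["position"].between(seg.start_pos, seg.end_pos)
        )
        member_values.append(profile.loc[mm.index[mask]].to_numpy(dtype=float))

    level_of = list(range(len(segments)))  # segment -> level id

    def level_members(lev: int) -> np.ndarray:
        vals = [member_values[s] for s, l in enumerate(level_of) if l == lev]
        return np.concatenate(vals)

    while True:
        levels = sorted(set(level_of))
        if len(levels) == 1:
            break
        best_p, best_pair = -1.0, None
        for a_i, a in enumerate(levels):
            xa = level_members(a)
            for b in levels[a_i + 1 :]:
                xb = level_members(b)
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
                if p > best_p:
                    best_p, best_pair = p, (a, b)
        if best_p <= threshold or best_pair is None:
            break
        a, b = best_pair
        level_of = [a if l == b else l for l in level_of]

    level_mean = {
        lev: float(np.mean(level_members(lev))) for lev in sorted(set(level_of))
    }
    # fuse adjacent same-level segments within each chromosome
    rows = []
    for chrom in segments["chromosome"].unique():
        sub = segments[segments["chromosome"] == chrom].sort_values("start_pos")
        run = None
        for pos_i, seg in zip(sub.index, sub.itertuples()):
            lev = level_of[segments.index.get_loc(pos_i)]
            if run is not None and run["level"] == lev:
                run["end_pos"] = seg.end_pos
                run["n_markers"] += seg.n_markers
            else:
                if run is not None:
                    rows.append(run)
                run = {
                    "sample_id": seg.sample_id,
                    "chromosome": chrom,
                    "start_pos": seg.start_pos,
                    "end_pos": seg.end_pos,
                    "n_markers": seg.n_markers,
                    "level": lev,
                }
        if run is not None:
            rows.append(run)
    out = pd.DataFrame(rows)
    out["seg_mean"] = out["level"].map(level_mean)
    return out[SEG_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CNV calling
# ---------------------------------------------------------------------------

def call_cnv(
    segments: pd.DataFrame,
    mads: pd.Series | float,
    high_mult: float = 1.0,
    low_mult: float = 0.5,
) -> pd.DataFrame:
    """Five-state CNV calls against per-array MAD multiples.

    AMP when ``seg_mean > high_mult * MAD``; HOMDEL when
    ``seg_mean < -high_mult * MAD``; otherwise GAIN / LOSS when beyond
    ``+/- low_mult * MAD``; NEUTRAL in between.  All comparisons strict,
    so a mean exactly at a threshold takes the milder state.
    """
    out = segments.copy()
    if np.isscalar(mads):
        mad_per_row = pd.Series(float(mads), index=out.index)
    else:
        mad_per_row = out["sample_id"].map(mads)
        if mad_per_row.isna().any():
            missing = out.loc[mad_per_row.isna(), "sample_id"].unique()
            raise KeyError(f"no MAD for samples: {list(missing)}")
    if (mad_per_row == 0).any():
        warnings.warn(
            "MAD of 0 for at least one array: every nonzero segment becomes a "
            "high-level call",
            stacklevel=2,
        )
    mean = out["seg_mean"].to_numpy(dtype=float)
    mad = mad_per_row.to_numpy(dtype=float)
    state = np.full(len(out), "NEUTRAL", dtype=object)
    state[mean > low_mult * mad] = "GAIN"
    state[mean < -low_mult * mad] = "LOSS"
    state[mean > high_mult * mad] = "AMP"
    state[mean < -high_mult * mad] = "HOMDEL"
    out["state"] = state
    return out


# ---------------------------------------------------------------------------
# gene-centric summaries and frequency profile
# ---------------------------------------------------------------------------

def gene_centric_table(
    log_ratios: pd.DataFrame,
    marker_map: pd.DataFrame,
    genes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Average log ratio of the markers inside each gene, per sample.

    ``genes`` needs columns ``gene, chromosome, start, end`` (1-based
    inclusive; a zero-length gene covers markers at exactly its position).
    Genes covering no marker — including genes on chromosomes absent from
    the map — are NaN rows, never zero-filled.  Returns the genes x
    samples matrix and the per-gene covered-marker count.
    """
    mm = marker_map.set_index("marker_id").loc[log_ratios.index]
    values = np.full((len(genes), log_ratios.shape[1]), np.nan)
    counts = np.zeros(len(genes), dtype=int)
    by_chrom = {
        chrom: (grp["position"].to_numpy(), log_ratios.loc[grp.index].to_numpy())
        for chrom, grp in mm.groupby("chromosome", sort=False)
    }
    for g_i, gene in enumerate(genes.itertuples()):
        hit = by_chrom.get(gene.chromosome)
        if hit is None:
            continue
        pos, mat = hit
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="right")
        if hi > lo:
            values[g_i] = mat[lo:hi].mean(axis=0)
            counts[g_i] = hi - lo
    table = pd.DataFrame(values, index=genes["gene"].to_numpy(), columns=log_ratios.columns)
    table.index.name = "gene"
    return table, pd.Series(counts, index=table.index, name="n_markers")


def frequency_profile(calls: pd.DataFrame, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Per-marker fraction of samples gained (GAIN/AMP) and lost (LOSS/HOMDEL)."""
    samples = calls["sample_id"].unique()
    gain = np.zeros(len(marker_map))
    loss = np.zeros(len(marker_map))
    pos_index = marker_map.reset_index(drop=True)
    for chrom, grp in pos_index.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        rows = grp.index.to_numpy()
        sub = calls[calls["chromosome"] == chrom]
        for seg in sub.itertuples():
            lo = np.searchsorted(pos, seg.start_pos, side="left")
            hi = np.searchsorted(pos, seg.end_pos, side="right")
            if seg.state in ("GAIN", "AMP"):
                gain[rows[lo:hi]] += 1
            elif seg.state in ("LOSS", "HOMDEL"):
                loss[rows[lo:hi]] += 1
    out = marker_map[["marker_id", "chromosome", "position"]].copy()
    out["gain_freq"] = gain / len(samples)
    out["loss_freq"] = loss / len(samples)
    return out
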