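"""Recurrent copy-number aberrations across samples (G-score scan).

A marker's G score aggregates aberration amplitude over samples:
``G_gain(m) = sum_s max(x_sm - theta_gain, 0)`` and symmetrically for
losses, an amplitude-weighted frequency.  Significance comes from a
resampled null in which each sample's marker values are independently
permuted across the genome; per-marker p values are read off the pooled
null G distribution, adjusted by Benjamini-Hochberg, and significant
regions are maximal runs of markers below the q cutoff.

Gene-set enrichment inside gain/loss regions is scored by random sampling
of equal-sized gene sets from the coordinate universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class GScoreProfile:
    """Per-marker G scores with optional p/q values and significant regions."""

    scores: pd.DataFrame  # marker_id, chromosome, position, g_gain, g_loss
    pvalues: pd.DataFrame | None = None  # p_gain, p_loss, q_gain, q_loss
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)


def g_scores(
    seg_values: pd.DataFrame,
    marker_map: pd.DataFrame,
    theta_gain: float = 0.1,
    theta_loss: float = -0.1,
) -> GScoreProfile:
    """Amplitude-over-threshold G scores per marker.

    ``seg_values`` is the markers x samples matrix of segmented log ratios
    aligned to the marker map.
    """
    x = seg_values.to_numpy(dtype=float)
    out = marker_map[["marker_id", "chromosome", "position"]].copy()
    out["g_gain"] = np.maximum(x - theta_gain, 0.0).sum(axis=1)
    out["g_loss"] = np.maximum(theta_loss - x, 0.0).sum(axis=1)
    return GScoreProfile(scores=out)


def _null_pool(x: np.ndarray, theta: float, sign: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Pooled null G values from per-sample genome-wide marker permutation."""
    pool = np.empty(n_perm * x.shape[0])
    for b in range(n_perm):
        xp = rng.permuted(x, axis=0)  # each sample column shuffled independently
        if sign > 0:
            g = np.maximum(xp - theta, 0.0).sum(axis=1)
        else:
            g = np.maximum(theta - xp, 0.0).sum(axis=1)
        pool[b * x.shape[0] : (b + 1) * x.shape[0]] = g
    pool.sort()
    return pool


def _pool_p(pool: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Add-one empirical p: fraction of the pooled null >= observed."""
    n_ge = pool.size - np.searchsorted(pool, observed, side="left")
    return (1.0 + n_ge) / (1.0 + pool.size)


def _runs_to_regions(
    marker_map: pd.DataFrame, significant: np.ndarray, direction: str, q: np.ndarray
) -> list[dict]:
    rows = []
    chroms = marker_map["chromosome"].to_numpy()
    pos = marker_map["position"].to_numpy()
    n = len(marker_map)
    i = 0
    while i < n:
        if significant[i]:
            j = i
            while j + 1 < n and significant[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            rows.append(
                {
                    "chromosome": chroms[i],
                    "start": int(pos[i]),
                    "end": int(pos[j]),
                    "direction": direction,
                    "q_min": float(np.min(q[i : j + 1])),
                }
            )
            i = j + 1
        else:
            i += 1
    return rows


def gistic_null(
    seg_values: pd.DataFrame,
    marker_map: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    theta_gain: float = 0.1,
    theta_loss: float = -0.1,
    q_threshold: float = 0.25,
) -> GScoreProfile:
    """G-score significance against a marker-permutation null.

    Each of ``n_perm`` resamples independently permutes every sample's
    marker values across the genome; the null G values of all markers are
    pooled (markers are exchangeable under this null), giving per-marker
    empirical p values, BH q values, and significant regions as maximal
    runs with ``q < q_threshold`` per direction.
    """
    if seg_values.shape[1] < 2:
        raise ValueError("need at least two samples")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable null tail", stacklevel=2)
    profile = g_scores(seg_values, marker_map, theta_gain, theta_loss)
    x = seg_values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    p_gain = _pool_p(
        _null_pool(x, theta_gain, +1, n_perm, rng), profile.scores["g_gain"].to_numpy()
    )
    p_loss = _pool_p(
        _null_pool(x, theta_loss, -1, n_perm, rng), profile.scores["g_loss"].to_numpy()
    )
    q_gain = multipletests(p_gain, method="fdr_bh")[1]
    q_loss = multipletests(p_loss, method="fdr_bh")[1]
    profile.pvalues = profile.scores[["marker_id", "chromosome", "position"]].copy()
    profile.pvalues["p_gain"] = p_gain
    profile.pvalues["q_gain"] = q_gain
    profile.pvalues["p_loss"] = p_loss
    profile.pvalues["q_loss"] = q_loss
    regions = _runs_to_regions(marker_map, q_gain < q_threshold, "gain", q_gain)
    regions += _runs_to_regions(marker_map, q_loss < q_threshold, "loss", q_loss)
    profile.regions = pd.DataFrame(
        regions, columns=["chromosome", "start", "end", "direction", "q_min"]
    )
    return profile


def region_enrichment(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical enrichment of gene sets inside aberrant regions.

    The observed statistic is the number of set members whose interval
    overlaps any region; the null redraws equal-sized sets uniformly from
    the gene universe (all genes with coordinates).  Add-one empirical p.
    Sets with no genes in the universe get a NaN p and a flag.
    """
    rng = np.random.default_rng(seed)
    universe = genes["gene"].to_numpy()

    in_region = np.zeros(len(genes), dtype=bool)
    for reg in regions.itertuples():
        hit = (
            (genes["chromosome"] == reg.chromosome)
            & (genes["start"] <= reg.end)
            & (genes["end"] >= reg.start)
        )
        in_region |= hit.to_numpy()
    hit_of = dict(zip(universe, in_region))

    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in hit_of]
        if not present:
            rows.append(
                {"set": name, "size": 0, "overlap": 0, "p": np.nan, "note": "no genes in universe"}
            )
            continue
        observed = sum(hit_of[g] for g in present)
        k = len(present)
        null_ge = 0
        for _ in range(n_perm):
            draw = rng.choice(len(universe), size=k, replace=False)
            if int(in_region[draw].sum()) >= observed:
                null_ge += 1
        p = (1.0 + null_ge) / (1.0 + n_perm)
        rows.append({"set": name, "size": k, "overlap": int(observed), "p": p, "note": ""})
    return pd.DataFrame(rows)
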