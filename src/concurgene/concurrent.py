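"""Concurrent-gene scoring: CNV/expression correlation and Fisher-z meta-combination.

A gene is "concurrent" when its gene-centric copy-number value (mean log
ratio of markers inside the gene) and its expression move together across
samples, assessed by the Spearman rank correlation.  Correlations from two
discovery cohorts of unequal size are combined on the Fisher z scale,

    z = arctanh(r),            V(z) = 1 / (n - 3),
    z_bar = ((n1-3) z1 + (n2-3) z2) / (n1 + n2 - 6),
    r_bar = tanh(z_bar),       V(z_bar) = 1 / (n1 + n2 - 6),

with a two-sided normal p value on z_bar / sqrt(V(z_bar)).  The universal
concurrent set is the genes whose combined p clears a preset alpha
(0.001 by default; 0.05 and 0.01 are the per-cohort screening levels).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "reduce_probes",
    "median_center",
    "spearman_per_gene",
    "fisher_z",
    "combine_cohorts",
    "combine_stats",
    "filter_concurrent",
]


def reduce_probes(expr: pd.DataFrame, probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """One row per gene: the probe with the largest IQR across samples.

    Unmapped probes are dropped (count logged); IQR ties are broken by the
    lexicographically smallest probe id so reduction is deterministic.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene map")
    mapped = expr.index.intersection(mapping.index)
    n_dropped = len(expr.index) - len(mapped)
    if n_dropped:
        logger.info("reduce_probes: dropped %d unmapped probes", n_dropped)
    sub = expr.loc[mapped]
    q75, q25 = np.nanpercentile(sub.to_numpy(dtype=float), [75, 25], axis=1)
    info = pd.DataFrame(
        {"gene": mapping.loc[mapped].to_numpy(), "iqr": q75 - q25, "probe": mapped}
    )
    # max IQR, then smallest probe id on ties
    info = info.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    keep = info.drop_duplicates("gene", keep="first")
    out = sub.loc[keep["probe"]]
    out.index = pd.Index(keep["gene"].to_numpy(), name="gene")
    return out.sort_index()


def median_center(expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across samples (idempotent)."""
    return expr.sub(expr.median(axis=1), axis=0)


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise midrank Spearman correlation of two equal-shape matrices."""
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan  # constant input: correlation undefined
    return r


def spearman_per_gene(
    gene_cnv: pd.DataFrame, gene_expr: pd.DataFrame, min_samples: int = 4
) -> pd.DataFrame:
    """Per-gene Spearman r of copy number vs expression over shared samples.

    Midrank ties; two-sided p from the t approximation with n-2 degrees of
    freedom.  Genes with fewer than ``min_samples`` complete pairs or with
    constant input are flagged undefined (NaN r/p) and excluded by
    downstream filters.
    """
    genes = gene_cnv.index.intersection(gene_expr.index)
    samples = gene_cnv.columns.intersection(gene_expr.columns)
    if len(samples) == 0:
        raise ValueError("no shared samples between CNV and expression")
    x = gene_cnv.loc[genes, samples].to_numpy(dtype=float)
    y = gene_expr.loc[genes, samples].to_numpy(dtype=float)

    complete = np.isfinite(x) & np.isfinite(y)
    n_per_gene = complete.sum(axis=1)
    r = np.full(len(genes), np.nan)
    all_complete = complete.all(axis=1)
    if all_complete.any():
        r[all_complete] = _spearman_rows(x[all_complete], y[all_complete])
    for g_i in np.flatnonzero(~all_complete):
        ok = complete[g_i]
        if ok.sum() >= min_samples:
            r[g_i] = _spearman_rows(x[g_i : g_i + 1, ok], y[g_i : g_i + 1, ok])[0]
    r[n_per_gene < min_samples] = np.nan

    n = n_per_gene.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[~np.isfinite(r)] = np.nan
    return pd.DataFrame(
        {"r": r, "n": n_per_gene, "p": p}, index=pd.Index(genes, name="gene")
    )


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = arctanh(r) = 1/2 log((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def combine_cohorts(r1, n1, r2, n2) -> dict:
    """Weighted Fisher-z combination of two cohort correlations.

    Weights are n-3 (the inverse z variances); returns z_bar, r_bar,
    var_zbar = 1/(n1+n2-6), and the two-sided normal p.  Accepts scalars
    or aligned arrays; requires n >= 4 in both cohorts.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 4) or np.any(n2 < 4):
        raise ValueError("both cohorts need n >= 4 for a positive z weight")
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    zbar = ((n1 - 3.0) * z1 + (n2 - 3.0) * z2) / (n1 + n2 - 6.0)
    var = 1.0 / (n1 + n2 - 6.0)
    p = 2.0 * stats.norm.sf(np.abs(zbar) / np.sqrt(var))
    out = {"z_bar": zbar, "r_bar": np.tanh(zbar), "var_zbar": var, "p_combined": p}
    if np.ndim(r1) == 0 and np.ndim(r2) == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def combine_stats(stats1: pd.DataFrame, stats2: pd.DataFrame) -> pd.DataFrame:
    """Gene-aligned cohort combination table.

    Inputs are `spearman_per_gene` outputs; genes undefined in either
    cohort (NaN r, or n < 4) stay in the table with NaN combined fields.
    Columns follow the on-disk results dialect:
    gene, r1, n1, p1, r2, n2, p2, z1, z2, z_bar, r_bar, var_zbar, p_combined.
    """
    genes = stats1.index.union(stats2.index)
    s1 = stats1.reindex(genes)
    s2 = stats2.reindex(genes)
    out = pd.DataFrame(index=genes)
    out["r1"], out["n1"], out["p1"] = s1["r"], s1["n"], s1["p"]
    out["r2"], out["n2"], out["p2"] = s2["r"], s2["n"], s2["p"]
    ok = (
        out[["r1", "r2"]].notna().all(axis=1)
        & (out["n1"] >= 4)
        & (out["n2"] >= 4)
        & (out[["r1", "r2"]].abs() < 1).all(axis=1)
    )
    for col in ("z1", "z2", "z_bar", "r_bar", "var_zbar", "p_combined"):
        out[col] = np.nan
    if ok.any():
        combined = combine_cohorts(
            out.loc[ok, "r1"].to_numpy(),
            out.loc[ok, "n1"].to_numpy(),
            out.loc[ok, "r2"].to_numpy(),
            out.loc[ok, "n2"].to_numpy(),
        )
        out.loc[ok, "z1"] = np.arctanh(out.loc[ok, "r1"].to_numpy())
        out.loc[ok, "z2"] = np.arctanh(out.loc[ok, "r2"].to_numpy())
        out.loc[ok, "z_bar"] = combined["z_bar"]
        out.loc[ok, "r_bar"] = combined["r_bar"]
        out.loc[ok, "var_zbar"] = combined["var_zbar"]
        out.loc[ok, "p_combined"] = combined["p_combined"]
    out.index.name = "gene"
    return out


def filter_concurrent(
    stats_table: pd.DataFrame, alpha: float = 0.001, p_col: str = "p_combined"
) -> list[str]:
    """Genes with p below alpha, in input order; NaN p never passes."""
    mask = stats_table[p_col] < alpha
    return stats_table.index[mask.fillna(False)].tolist()
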