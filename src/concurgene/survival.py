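"""Supervised principal-component survival modelling.

The prognostic model follows the supervised principal-component recipe:
genes are screened one at a time with a univariate Cox proportional-
hazards test at a stringent alpha (0.001 by default), the screened
submatrix is standardized and its first principal component — the
"supergene" — supplies per-gene loadings.  Each sample's prognostic index
is the loading-weighted sum of its standardized expression, oriented so
that a larger index means a larger estimated hazard, and high/low risk
groups are cut at a percentile (50th, or 75th for sensitivity analyses) of
the training indices.  Evaluation is by nested leave-one-out
cross-validation (screening, loadings, orientation and threshold all
refit per fold), the two-group log-rank test, and a landmark
time-dependent ROC AUC with inverse-probability-of-censoring weights.

Outcome tables are DataFrames with columns ``sample_id, time, event``
(time > 0, event 1 = observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "cox_univariate",
    "cox_screen",
    "fit_risk_model",
    "predict_risk",
    "loocv_risk_groups",
    "logrank_test",
    "time_dependent_auc",
    "consensus_filter",
]


# ---------------------------------------------------------------------------
# univariate Cox screening (score test, Efron ties)
# ---------------------------------------------------------------------------

def _cox_score_components(
    x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score U and information V at beta=0 for each gene (row of ``x``.T).

    ``x`` is samples x genes.  Efron handling of tied event times: for the
    l-th of d tied deaths the risk-set mean removes an l/d fraction of the
    tied deaths' contribution.  At beta = 0 all relative risks are 1, so
    risk-set sums reduce to suffix sums over the time-ordered samples.
    """
    order = np.argsort(time, kind="stable")
    xs = x[order]
    ts = time[order]
    es = event[order]
    n, g = xs.shape

    # suffix sums: risk set at t_k = samples k..n-1 (ties share the set)
    suffix_x = np.cumsum(xs[::-1], axis=0)[::-1]
    suffix_q = np.cumsum((xs**2)[::-1], axis=0)[::-1]

    U = np.zeros(g)
    V = np.zeros(g)
    k = 0
    while k < n:
        j = k
        while j + 1 < n and ts[j + 1] == ts[k]:
            j += 1
        deaths = np.flatnonzero(es[k : j + 1] == 1) + k
        d = deaths.size
        if d > 0:
            n_risk = n - k
            s_risk = suffix_x[k]
            q_risk = suffix_q[k]
            s_dead = xs[deaths].sum(axis=0)
            q_dead = (xs[deaths] ** 2).sum(axis=0)
            U += s_dead
            for l in range(d):
                frac = l / d
                denom = n_risk - l
                m1 = (s_risk - frac * s_dead) / denom
                m2 = (q_risk - frac * q_dead) / denom
                U -= m1
                V += m2 - m1**2
        k = j + 1
    return U, V


def cox_screen(expr: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox score test for every gene (genes x samples input).

    Returns a per-gene frame with the signed score ``u``, the chi-square
    ``statistic`` (U^2/V, 1 df) and two-sided ``p``.  Genes with no
    variance in the risk sets are flagged undefined (NaN).
    """
    samples = [s for s in expr.columns if s in set(outcome["sample_id"])]
    out_idx = outcome.set_index("sample_id").loc[samples]
    time = out_idx["time"].to_numpy(dtype=float)
    event = out_idx["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least two events for Cox screening")
    x = expr[samples].to_numpy(dtype=float).T  # samples x genes
    if not np.all(np.isfinite(x)):
        raise ValueError("expression matrix contains non-finite values")
    U, V = _cox_score_components(x, time, event)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = U**2 / V
    undefined = V <= 1e-12
    chi2[undefined] = np.nan
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame(
        {"u": U, "statistic": chi2, "p": p}, index=expr.index.copy()
    )


def cox_univariate(
    gene_values: pd.Series | np.ndarray, outcome: pd.DataFrame
) -> tuple[float, float]:
    """Score-test (statistic, p) for one continuous covariate."""
    if isinstance(gene_values, pd.Series):
        expr = gene_values.to_frame().T
        expr.index = ["gene"]
    else:
        expr = pd.DataFrame(
            np.asarray(gene_values, dtype=float)[None, :],
            index=["gene"],
            columns=outcome["sample_id"].to_numpy(),
        )
    res = cox_screen(expr, outcome)
    return float(res["statistic"].iloc[0]), float(res["p"].iloc[0])


# ---------------------------------------------------------------------------
# supervised principal component model
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """Cox-screened PC1 prognostic model ("supergene")."""

    genes: list[str]
    cox_stats: pd.DataFrame
    means: pd.Series  # training per-gene mean
    sds: pd.Series  # training per-gene SD
    loadings: pd.Series  # unit Euclidean norm
    orientation_sign: int  # +1/-1 so larger index => larger hazard
    train_index: pd.Series
    percentile: float
    threshold: float


def _standardize(expr: pd.DataFrame, means: pd.Series, sds: pd.Series) -> np.ndarray:
    x = expr.to_numpy(dtype=float)
    return (x - means.to_numpy()[:, None]) / sds.to_numpy()[:, None]


def fit_risk_model(
    expr: pd.DataFrame,
    outcome: pd.DataFrame,
    alpha: float = 0.001,
    percentile: float = 50.0,
) -> RiskModel:
    """Cox filter -> standardize -> PC1 loadings -> oriented index -> threshold.

    ``expr`` is genes x samples.  Raises when no gene clears the filter.
    The PC sign is arbitrary, so loadings are flipped if the training
    index's Cox score runs opposite to hazard.
    """
    screen = cox_screen(expr, outcome)
    selected = screen.index[(screen["p"] < alpha).fillna(False)].tolist()
    if not selected:
        raise ValueError(f"no gene passes the Cox filter at alpha={alpha}")
    sub = expr.loc[selected]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    xs = _standardize(sub, means, sds)  # genes x samples
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = u[:, 0]
    index = loadings @ xs  # = s[0] * vt[0]
    idx_outcome = outcome.set_index("sample_id").loc[list(sub.columns)]
    u_score, _ = _cox_score_components(
        index[:, None],
        idx_outcome["time"].to_numpy(dtype=float),
        idx_outcome["event"].to_numpy(dtype=int),
    )
    sign = -1 if u_score[0] < 0 else 1
    loadings = sign * loadings
    index = sign * index
    train_index = pd.Series(index, index=sub.columns, name="prognostic_index")
    threshold = float(np.percentile(index, percentile))
    return RiskModel(
        genes=selected,
        cox_stats=screen.loc[selected],
        means=means,
        sds=sds,
        loadings=pd.Series(loadings, index=selected, name="loading"),
        orientation_sign=sign,
        train_index=train_index,
        percentile=percentile,
        threshold=threshold,
    )


def predict_risk(model: RiskModel, expr_new: pd.DataFrame) -> pd.DataFrame:
    """Prognostic index and high/low label for new samples.

    Missing model genes are imputed at the training mean (zero after
    standardization, count logged); more than half missing is refused.
    High risk = index strictly above the threshold; ties go to low risk.
    """
    present = [g for g in model.genes if g in expr_new.index]
    n_missing = len(model.genes) - len(present)
    if n_missing * 2 > len(model.genes):
        raise ValueError(
            f"{n_missing}/{len(model.genes)} model genes missing from input"
        )
    if n_missing:
        logger.info("predict_risk: %d model genes imputed at training mean", n_missing)
    sub = expr_new.reindex(model.genes)
    sub = sub.apply(lambda row: row.fillna(model.means[row.name]), axis=1)
    xs = _standardize(sub, model.means, model.sds)
    index = model.loadings.to_numpy() @ xs
    return pd.DataFrame(
        {
            "sample_id": list(expr_new.columns),
            "prognostic_index": index,
            "risk_label": np.where(index > model.threshold, "high", "low"),
        }
    )


def loocv_risk_groups(
    expr: pd.DataFrame,
    outcome: pd.DataFrame,
    alpha: float = 0.001,
    percentile: float = 50.0,
) -> pd.DataFrame:
    """Nested leave-one-out risk grouping.

    For each sample the entire pipeline (Cox filter, PC1, orientation,
    percentile threshold) is refit on the other n-1 samples; the held-out
    sample is then scored and labelled.  When a fold selects no genes, its
    sample falls back to an unweighted index over all genes thresholded at
    the fold's own percentile (logged).
    """
    samples = list(expr.columns)
    if len(samples) < 10:
        raise ValueError("LOOCV risk grouping needs n >= 10")
    rows = []
    for fold, held in enumerate(samples):
        train = [s for s in samples if s != held]
        train_out = outcome[outcome["sample_id"].isin(train)]
        try:
            model = fit_risk_model(expr[train], train_out, alpha=alpha, percentile=percentile)
            pred = predict_risk(model, expr[[held]])
            idx, label = float(pred["prognostic_index"].iloc[0]), pred["risk_label"].iloc[0]
        except ValueError:
            logger.info("loocv_risk_groups: fold %d empty selection, fallback index", fold)
            means = expr[train].mean(axis=1)
            sds = expr[train].std(axis=1, ddof=0).replace(0.0, 1.0)
            proxy_train = ((expr[train].sub(means, axis=0)).div(sds, axis=0)).mean(axis=0)
            thr = float(np.percentile(proxy_train, percentile))
            idx = float(((expr[held] - means) / sds).mean())
            label = "high" if idx > thr else "low"
        rows.append(
            {"sample_id": held, "prognostic_index": idx, "risk_label": label, "fold_id": fold}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def logrank_test(outcome: pd.DataFrame, labels: pd.Series) -> tuple[float, float]:
    """Two-group log-rank (chi-square 1 df, p)."""
    lab = labels.reindex(outcome["sample_id"]).to_numpy()
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {list(groups)}")
    mask = lab == groups[0]
    res = _ll_logrank(
        outcome["time"].to_numpy()[mask],
        outcome["time"].to_numpy()[~mask],
        event_observed_A=outcome["event"].to_numpy()[mask],
        event_observed_B=outcome["event"].to_numpy()[~mask],
    )
    return float(res.test_statistic), float(res.p_value)


def _km_censoring(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t), with left limits.

    Returns a function ``G(t, left=False)``; the left limit is what IPCW
    weights need at observed event times.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    cens_sorted = 1 - event[order]
    uniq = np.unique(t_sorted)
    surv = []
    s = 1.0
    n = time.size
    at_risk = n
    for t in uniq:
        here = t_sorted == t
        d_cens = int(cens_sorted[here].sum())
        if at_risk > 0 and d_cens > 0:
            s *= 1.0 - d_cens / at_risk
        surv.append(s)
        at_risk -= int(here.sum())
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def G(t: float, left: bool = False) -> float:
        side = "left" if left else "right"
        i = np.searchsorted(uniq, t, side=side) - 1
        return 1.0 if i < 0 else float(surv[i])

    return G


def time_dependent_auc(
    indices: pd.Series, outcome: pd.DataFrame, landmark_time: float
) -> float:
    """Cumulative-case / dynamic-control AUC at a landmark, IPCW-weighted.

    Cases are samples with an observed event by the landmark, controls are
    samples still event-free past it; weights are inverse Kaplan-Meier
    censoring-survival probabilities (left limit at each case's event
    time).  Ties in the index count half.  Returns NaN when no comparable
    case-control pair exists.
    """
    out = outcome.set_index("sample_id").loc[indices.index]
    time = out["time"].to_numpy(dtype=float)
    event = out["event"].to_numpy(dtype=int)
    if not (time.min() <= landmark_time <= time.max()):
        raise ValueError("landmark outside the observed time range")
    score = indices.to_numpy(dtype=float)
    G = _km_censoring(time, event)
    case = (time <= landmark_time) & (event == 1)
    control = time > landmark_time
    if case.sum() == 0 or control.sum() == 0:
        return float("nan")
    w_case = np.array([1.0 / max(G(t, left=True), 1e-12) for t in time[case]])
    # the (uniform) control weight 1/G(landmark) cancels between num. and denom.
    sc = score[case][:, None]
    st = score[control][None, :]
    conc = (sc > st) + 0.5 * (sc == st)
    return float((conc * w_case[:, None]).sum() / (w_case.sum() * control.sum()))


def consensus_filter(flags: pd.DataFrame) -> tuple[pd.Series, dict[int, list[str]]]:
    """Agreement counting across datasets.

    ``flags`` is genes x datasets boolean (prognostic in that dataset).
    Returns, for each k = 1..K, the number and the list of genes flagged
    in at least k datasets; counts are non-increasing in k.
    """
    n_hit = flags.fillna(False).astype(bool).sum(axis=1)
    k_max = flags.shape[1]
    gene_lists = {
        k: flags.index[n_hit >= k].tolist() for k in range(1, k_max + 1)
    }
    counts = pd.Series({k: len(v) for k, v in gene_lists.items()}, name="n_genes")
    counts.index.name = "min_datasets"
    return counts, gene_lists
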