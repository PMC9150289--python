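"""Dichotomous-outcome class prediction with leave-one-out cross-validation.

Mirrors the classical microarray class-prediction toolbox: a univariate
pooled-variance t filter (alpha 0.001), a global multivariate permutation
test on the count of filter-passing genes, and six classifiers —

* compound covariate predictor (CCP): score = sum_g t_g x_g, decision at
  the midpoint of the class mean scores;
* diagonal linear discriminant analysis (DLDA): Gaussian classes with a
  shared (pooled) per-gene variance;
* k-nearest neighbours (k = 1 and 3) and nearest centroid, both on
  training-standardized genes with Euclidean distance;
* linear soft-margin SVM (cost 1);
* Bayesian compound covariate (BCCP): Gaussian class-conditional densities
  of the compound score, pooled variance and equal priors, reporting the
  class-1 posterior.

All supervised steps — the gene filter included — are refit inside every
cross-validation fold, and permutation p values rerun the entire LOOCV per
label shuffle with the add-one correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "ClassifierResult",
    "CLASSIFIER_METHODS",
    "t_test_filter",
    "global_multivariate_permutation_test",
    "train_classifier",
    "predict",
    "loocv_classify",
    "permutation_pvalue",
    "cv_auc_bccp",
]

CLASSIFIER_METHODS = ["ccp", "dlda", "1nn", "3nn", "centroid", "svm", "bccp"]


@dataclass
class ClassifierResult:
    method: str
    predictions: pd.Series
    misclassification: float
    permutation_p: float | None = None
    posteriors: pd.Series | None = None
    cv_auc: float | None = None
    n_folds: int = 0
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sample t and two-sided p.

    ``x`` is genes x samples; ``y`` is the 0/1 label vector.  Genes with
    zero pooled variance are NaN (undefined) unless the class means also
    differ, in which case t is +/-inf with p = 0.
    """
    g0 = x[:, y == 0]
    g1 = x[:, y == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least two samples for the t filter")
    m0, m1 = g0.mean(axis=1), g1.mean(axis=1)
    ss = ((g0 - m0[:, None]) ** 2).sum(axis=1) + ((g1 - m1[:, None]) ** 2).sum(axis=1)
    df = n0 + n1 - 2
    sp2 = ss / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    zero_var = sp2 <= 0
    diff = np.abs(m1 - m0) > 1e-12
    t[zero_var & diff] = np.sign((m1 - m0)[zero_var & diff]) * np.inf
    t[zero_var & ~diff] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p[np.isinf(t)] = 0.0
    return t, p


def t_test_filter(
    expr: pd.DataFrame, labels: pd.Series, alpha: float = 0.001
) -> pd.DataFrame:
    """Per-gene pooled t statistics with a pass flag at ``alpha``.

    Degenerate genes (identical class means with zero variance) are
    flagged undefined and never pass.
    """
    y = labels.reindex(expr.columns).to_numpy(dtype=int)
    t, p = _pooled_t(expr.to_numpy(dtype=float), y)
    out = pd.DataFrame({"t": t, "p": p}, index=expr.index.copy())
    out["pass"] = (out["p"] < alpha).fillna(False)
    return out


def global_multivariate_permutation_test(
    expr: pd.DataFrame,
    labels: pd.Series,
    gene_alpha: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for the count of genes passing the univariate filter."""
    y = labels.reindex(expr.columns).to_numpy(dtype=int)
    n0 = int((y == 0).sum())
    if comb(y.size, n0) < 20:
        raise ValueError("fewer than 20 distinct label permutations")
    x = expr.to_numpy(dtype=float)
    _, p = _pooled_t(x, y)
    observed = int(np.nansum(p < gene_alpha))
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    null_ge = 0
    for _ in range(n_perm):
        _, pp = _pooled_t(x, rng.permutation(y))
        if int(np.nansum(pp < gene_alpha)) >= observed:
            null_ge += 1
    return (1.0 + null_ge) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _standardizer(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return mu, sd


@dataclass
class _Fitted:
    method: str
    params: dict


def train_classifier(method: str, x_train: np.ndarray, y_train: np.ndarray) -> _Fitted:
    """Fit one method on (samples x genes, labels); genes are pre-filtered."""
    if x_train.shape[1] == 0:
        raise ValueError("empty gene set")
    y_train = np.asarray(y_train, dtype=int)
    if method in ("ccp", "bccp"):
        t, _ = _pooled_t(x_train.T, y_train)
        t = np.nan_to_num(t, nan=0.0, posinf=1e6, neginf=-1e6)
        scores = x_train @ t
        m0, m1 = scores[y_train == 0].mean(), scores[y_train == 1].mean()
        s0 = scores[y_train == 0]
        s1 = scores[y_train == 1]
        pooled_var = (
            ((s0 - m0) ** 2).sum() + ((s1 - m1) ** 2).sum()
        ) / max(len(scores) - 2, 1)
        return _Fitted(method, {"t": t, "m0": m0, "m1": m1, "var": max(pooled_var, 1e-12)})
    if method == "dlda":
        mu0 = x_train[y_train == 0].mean(axis=0)
        mu1 = x_train[y_train == 1].mean(axis=0)
        ss = ((x_train[y_train == 0] - mu0) ** 2).sum(axis=0) + (
            (x_train[y_train == 1] - mu1) ** 2
        ).sum(axis=0)
        var = ss / max(x_train.shape[0] - 2, 1)
        var[var <= 0] = 1e-12
        return _Fitted(method, {"mu0": mu0, "mu1": mu1, "var": var})
    if method in ("1nn", "3nn"):
        k = 1 if method == "1nn" else 3
        if k > x_train.shape[0]:
            raise ValueError(f"k={k} exceeds training size {x_train.shape[0]}")
        mu, sd = _standardizer(x_train)
        return _Fitted(method, {"k": k, "x": (x_train - mu) / sd, "y": y_train, "mu": mu, "sd": sd})
    if method == "centroid":
        mu, sd = _standardizer(x_train)
        xs = (x_train - mu) / sd
        return _Fitted(
            method,
            {
                "c0": xs[y_train == 0].mean(axis=0),
                "c1": xs[y_train == 1].mean(axis=0),
                "mu": mu,
                "sd": sd,
            },
        )
    if method == "svm":
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(x_train, y_train)
        return _Fitted(method, {"clf": clf})
    raise ValueError(f"unknown method {method!r}; choose from {CLASSIFIER_METHODS}")


def predict(state: _Fitted, x: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Predict labels (and class-1 posteriors for BCCP) for samples x genes."""
    x = np.atleast_2d(x)
    p = state.params
    if state.method == "ccp":
        scores = x @ p["t"]
        cut = 0.5 * (p["m0"] + p["m1"])
        side = 1 if p["m1"] >= p["m0"] else 0
        label = np.where(scores > cut, side, 1 - side)
        return label, None
    if state.method == "bccp":
        scores = x @ p["t"]
        d0 = stats.norm.logpdf(scores, loc=p["m0"], scale=np.sqrt(p["var"]))
        d1 = stats.norm.logpdf(scores, loc=p["m1"], scale=np.sqrt(p["var"]))
        with np.errstate(over="ignore"):
            post1 = 1.0 / (1.0 + np.exp(np.clip(d0 - d1, -700, 700)))  # equal priors
        return (post1 > 0.5).astype(int), post1
    if state.method == "dlda":
        d0 = (((x - p["mu0"]) ** 2) / p["var"]).sum(axis=1)
        d1 = (((x - p["mu1"]) ** 2) / p["var"]).sum(axis=1)
        return (d1 < d0).astype(int), None
    if state.method in ("1nn", "3nn"):
        xs = (x - p["mu"]) / p["sd"]
        d = ((xs[:, None, :] - p["x"][None, :, :]) ** 2).sum(axis=2)
        nn = np.argsort(d, axis=1, kind="stable")[:, : p["k"]]
        votes = p["y"][nn].mean(axis=1)
        return (votes > 0.5).astype(int), None
    if state.method == "centroid":
        xs = (x - p["mu"]) / p["sd"]
        d0 = ((xs - p["c0"]) ** 2).sum(axis=1)
        d1 = ((xs - p["c1"]) ** 2).sum(axis=1)
        return (d1 < d0).astype(int), None
    if state.method == "svm":
        return p["clf"].predict(x).astype(int), None
    raise ValueError(f"unknown method {state.method!r}")


# ---------------------------------------------------------------------------
# LOOCV and permutation inference
# ---------------------------------------------------------------------------

def _loocv_predictions(
    x: np.ndarray, y: np.ndarray, method: str, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated labels (and posteriors) with per-fold refiltering."""
    n = y.size
    preds = np.empty(n, dtype=int)
    posts = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.min() == y_tr.max():
            raise ValueError("a fold has an empty class")
        _, p = _pooled_t(x[:, mask], y_tr)
        keep = np.flatnonzero(np.nan_to_num(p, nan=1.0) < alpha)
        if keep.size == 0:  # fall back to the single best-separating gene
            keep = np.array([int(np.nanargmin(p))])
        state = train_classifier(method, x[keep][:, mask].T, y_tr)
        label, post = predict(state, x[keep, i][None, :])
        preds[i] = int(label[0])
        if post is not None:
            posts[i] = float(post[0])
    return preds, posts


def loocv_classify(
    expr: pd.DataFrame, labels: pd.Series, method: str, alpha: float = 0.001
) -> ClassifierResult:
    """Leave-one-out misclassification with the gene filter inside the loop."""
    y = labels.reindex(expr.columns).to_numpy(dtype=int)
    if y.size < 6:
        raise ValueError("LOOCV classification needs n >= 6")
    x = expr.to_numpy(dtype=float)
    preds, posts = _loocv_predictions(x, y, method, alpha)
    result = ClassifierResult(
        method=method,
        predictions=pd.Series(preds, index=expr.columns, name="prediction"),
        misclassification=float(np.mean(preds != y)),
        n_folds=int(y.size),
    )
    if method == "bccp":
        result.posteriors = pd.Series(posts, index=expr.columns, name="posterior")
        result.cv_auc = cv_auc_bccp(result.posteriors, labels)
    return result


def permutation_pvalue(
    expr: pd.DataFrame,
    labels: pd.Series,
    method: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.001,
) -> float:
    """Fraction of label permutations whose full-LOOCV error is <= observed.

    Reruns the entire cross-validation (filter included) per permutation;
    add-one corrected so p is never zero.  Fewer than 1000 permutations
    triggers a warning but still runs.
    """
    if n_perm < 1000:
        warnings.warn(
            f"n_perm={n_perm} is below the conventional minimum of 1000", stacklevel=2
        )
    y = labels.reindex(expr.columns).to_numpy(dtype=int)
    x = expr.to_numpy(dtype=float)
    obs_preds, _ = _loocv_predictions(x, y, method, alpha)
    observed = float(np.mean(obs_preds != y))
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        preds, _ = _loocv_predictions(x, yp, method, alpha)
        if float(np.mean(preds != yp)) <= observed:
            n_le += 1
    return (1.0 + n_le) / (1.0 + n_perm)


def cv_auc_bccp(posteriors: pd.Series, labels: pd.Series) -> float:
    """ROC AUC of cross-validated posteriors vs true labels (ties half)."""
    y = labels.reindex(posteriors.index).to_numpy(dtype=int)
    s = posteriors.to_numpy(dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)
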