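"""End-to-end pipeline: simulate -> segment -> call -> recurrence ->
concurrency -> combine -> survival model -> classification -> report.

`run_pipeline` chains every stage on two simulated discovery cohorts and
writes all artifacts plus a JSON report that records the gene-count funnel
at every filter, so synthetic runs can be audited against the generating
truth.  All randomness flows from the single seed in the configuration;
a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import concurrent as cg
from . import io as cio
from . import recurrent as rc
from . import segmentation as seg
from . import survival as sv
from .synthetic import SimulationConfig, simulate_multi_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed.

    Defaults mirror the analysis conventions the pipeline implements:
    CBS at alpha 0.01, per-cohort concurrency screening at 0.01, the
    combined Fisher-z filter at 0.001, Cox/t filters at 0.001, risk
    percentile 50, G-score q cutoff 0.25.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    cohort_sizes: tuple[int, ...] = (31, 345)
    probes_per_gene: int = 1
    simulation: dict = field(default_factory=dict)
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    mad_high_mult: float = 1.0
    mad_low_mult: float = 0.5
    gistic_n_perm: int = 10000
    gistic_theta: float = 0.1
    gistic_q: float = 0.25
    cohort_alpha: float = 0.01
    combined_alpha: float = 0.001
    cox_alpha: float = 0.001
    t_alpha: float = 0.001
    risk_percentile: float = 50.0
    classify_methods: tuple[str, ...] = ("ccp", "dlda", "3nn", "centroid", "svm", "bccp")
    classify_n_perm: int = 0  # 0 disables the (costly) permutation p stage
    landmark_time: float | None = None

    def validate(self) -> None:
        if not 0 < self.cbs_alpha < 1:
            raise ValueError("cbs_alpha must lie in (0, 1)")
        for name in ("cohort_alpha", "combined_alpha", "cox_alpha", "t_alpha"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 < self.risk_percentile < 100:
            raise ValueError("risk_percentile must lie in (0, 100)")
        if self.cbs_n_perm < 1 or self.gistic_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")
        if len(self.cohort_sizes) < 2:
            raise ValueError("need at least two cohorts")
        unknown = set(self.classify_methods) - set(cl.CLASSIFIER_METHODS)
        if unknown:
            raise ValueError(f"unknown classifier methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.cohort_sizes, list):
            cfg.cohort_sizes = tuple(cfg.cohort_sizes)
        if isinstance(cfg.classify_methods, list):
            cfg.classify_methods = tuple(cfg.classify_methods)
        return cfg


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write artifacts + JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        # --- simulate -----------------------------------------------------
        info = stage("simulate")
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        cohorts = simulate_multi_cohort(
            sim, cohort_sizes=config.cohort_sizes, probes_per_gene=config.probes_per_gene
        )
        cio.write_marker_map(cohorts[0].marker_map, out / "marker_map.tsv")
        cio.write_bed_genes(cohorts[0].genes, out / "genes.tsv")
        for c in cohorts:
            cio.write_matrix(c.log_ratios, out / f"{c.name}_log_ratios.tsv")
            cio.write_matrix(c.expression, out / f"{c.name}_expression.tsv")
            cio.write_outcomes(c.survival, out / f"{c.name}_survival.tsv")
            truth = c.truth.concurrent_genes.copy()
            cio._write_tsv(truth, out / f"{c.name}_truth_concurrent.tsv")
        info["n_cohorts"] = len(cohorts)
        info["n_genes"] = len(cohorts[0].genes)
        info["cohort_sizes"] = [c.log_ratios.shape[1] for c in cohorts]

        # --- segment + call (first cohort carries the CNV analyses) -------
        info = stage("segment")
        first = cohorts[0]
        segments = seg.segment_cohort(
            first.log_ratios,
            first.marker_map,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            seed=config.seed,
        )
        mads = seg.array_noise_stats(first.log_ratios)
        calls = seg.call_cnv(
            segments, mads, high_mult=config.mad_high_mult, low_mult=config.mad_low_mult
        )
        cio.write_seg(calls, out / f"{first.name}_calls.seg")
        freq = seg.frequency_profile(calls, first.marker_map)
        cio._write_tsv(freq, out / f"{first.name}_frequency.tsv")
        info["n_segments"] = int(len(segments))
        info["state_counts"] = calls["state"].value_counts().to_dict()

        # --- recurrent CNV -------------------------------------------------
        info = stage("gistic")
        seg_matrix = _segments_to_marker_matrix(calls, first.marker_map)
        profile = rc.gistic_null(
            seg_matrix,
            first.marker_map,
            n_perm=config.gistic_n_perm,
            seed=config.seed,
            theta_gain=config.gistic_theta,
            theta_loss=-config.gistic_theta,
            q_threshold=config.gistic_q,
        )
        cio._write_tsv(profile.regions, out / "recurrent_regions.tsv")
        info["n_regions"] = int(len(profile.regions))

        # --- concurrency per cohort + combination --------------------------
        info = stage("concurrent")
        per_cohort = []
        for c in cohorts[:2]:
            gene_cnv, _ = seg.gene_centric_table(c.log_ratios, c.marker_map, c.genes)
            expr_gene = cg.reduce_probes(c.expression, c.probe_to_gene)
            expr_gene = cg.median_center(expr_gene)
            stats_c = cg.spearman_per_gene(gene_cnv, expr_gene)
            per_cohort.append(stats_c)
            info[f"{c.name}_pass_{config.cohort_alpha}"] = int(
                (stats_c["p"] < config.cohort_alpha).sum()
            )
        combined = cg.combine_stats(per_cohort[0], per_cohort[1])
        universal = cg.filter_concurrent(combined, alpha=config.combined_alpha)
        table = combined.reset_index()
        table["pass_flag"] = table["gene"].isin(universal).astype(int)
        cio._write_tsv(table, out / "concurrent_genes.tsv")
        info["n_genes_tested"] = int(len(combined))
        info["n_universal"] = len(universal)

        # --- survival model on the larger cohort ---------------------------
        info = stage("survival")
        big = cohorts[1]
        expr_gene = cg.median_center(cg.reduce_probes(big.expression, big.probe_to_gene))
        expr_sel = expr_gene.loc[[g for g in universal if g in expr_gene.index]]
        cv = sv.loocv_risk_groups(
            expr_sel,
            big.survival,
            alpha=config.cox_alpha,
            percentile=config.risk_percentile,
        )
        cio._write_tsv(cv, out / f"{big.name}_risk_groups.tsv")
        labels = cv.set_index("sample_id")["risk_label"]
        chi2, p = sv.logrank_test(big.survival, labels)
        landmark = config.landmark_time
        if landmark is None:
            censored = big.survival.loc[big.survival["event"] == 0, "time"]
            landmark = float(censored.median() if len(censored) else big.survival["time"].median())
        auc = sv.time_dependent_auc(
            cv.set_index("sample_id")["prognostic_index"], big.survival, landmark
        )
        info.update(
            {
                "n_candidate_genes": int(expr_sel.shape[0]),
                "n_high": int((labels == "high").sum()),
                "n_low": int((labels == "low").sum()),
                "logrank_chi2": chi2,
                "logrank_p": p,
                "landmark_time": landmark,
                "auc": auc,
            }
        )

        # --- class prediction on the smaller cohort's binary labels --------
        info = stage("classify")
        small = cohorts[0]
        expr_small = cg.median_center(
            cg.reduce_probes(small.expression, small.probe_to_gene)
        )
        expr_small = expr_small.loc[[g for g in universal if g in expr_small.index]]
        rows = []
        for method in config.classify_methods:
            res = cl.loocv_classify(
                expr_small, small.binary_labels, method, alpha=config.t_alpha
            )
            if config.classify_n_perm > 0:
                res.permutation_p = cl.permutation_pvalue(
                    expr_small,
                    small.binary_labels,
                    method,
                    n_perm=config.classify_n_perm,
                    seed=config.seed,
                    alpha=config.t_alpha,
                )
            rows.append(
                {
                    "method": method,
                    "n_folds": res.n_folds,
                    "misclassification": res.misclassification,
                    "permutation_p": res.permutation_p if res.permutation_p is not None else "",
                    "cv_auc": res.cv_auc if res.cv_auc is not None else "",
                }
            )
        cio._write_tsv(pd.DataFrame(rows), out / "classification.tsv")
        info["methods"] = {r["method"]: r["misclassification"] for r in rows}
    except Exception as exc:  # surface the failing stage
        failed = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _segments_to_marker_matrix(
    segments: pd.DataFrame, marker_map: pd.DataFrame
) -> pd.DataFrame:
    """Expand per-sample segments back to a markers x samples seg-mean matrix."""
    samples = list(dict.fromkeys(segments["sample_id"]))
    values = np.zeros((len(marker_map), len(samples)))
    mm = marker_map.reset_index(drop=True)
    col_of = {s: i for i, s in enumerate(samples)}
    for chrom, grp in mm.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        rows = grp.index.to_numpy()
        for s in segments[segments["chromosome"] == chrom].itertuples():
            lo = np.searchsorted(pos, s.start_pos, side="left")
            hi = np.searchsorted(pos, s.end_pos, side="right")
            values[rows[lo:hi], col_of[s.sample_id]] = s.seg_mean
    out = pd.DataFrame(values, index=mm["marker_id"].to_numpy(), columns=samples)
    out.index.name = "marker_id"
    return out
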