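"""Synthetic paired CNV/expression cohorts with known ground truth.

Emulates the paired design the pipeline targets: marker-level SNP-array
log ratios with segmental gains/losses and per-array noise, a gene
expression matrix in which a subset of genes ("concurrent" genes) responds
linearly to its own copy number, survival times whose hazard follows a
signature supergene, dichotomous adverse-event labels through a logistic
link, and multiple cohorts of very unequal size sharing one ground truth.

Every quantity that downstream stages estimate (segment boundaries and
states, the concurrent gene set and its dosage slopes, the signature genes
and the per-sample linear predictor) is returned as explicit ground truth,
so each stage has a parameter-recovery test without external data.

All randomness flows from one integer seed; operations draw from
deterministic substreams of it, so identical seeds give bit-identical
cohorts even when stages are re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortDataset",
    "simulate_genome",
    "simulate_cnv_profiles",
    "simulate_expression",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_multi_cohort",
]

_STATE_SHIFT_KEYS = {
    "AMP": ("amp_magnitude", +1.0),
    "GAIN": ("gain_magnitude", +1.0),
    "LOSS": ("loss_magnitude", -1.0),
    "HOMDEL": ("del_magnitude", -1.0),
}

# relative frequency of simulated event types: low-level events dominate
_STATE_PROBS = {"GAIN": 0.35, "LOSS": 0.35, "AMP": 0.15, "HOMDEL": 0.15}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one paired cohort.

    Magnitudes are absolute log-ratio shifts (signs applied by state);
    ``seg_event_rate`` is the expected number of CNV events per sample per
    chromosome; ``censoring_rate`` is the target fraction of censored
    samples, matched by solving for the upper bound of an independent
    uniform censoring time.
    """

    n_chromosomes: int = 3
    markers_per_chromosome: int = 1000
    n_genes: int = 600
    n_samples: int = 50
    seg_event_rate: float = 4.5
    mean_segment_markers: float = 110.0
    amp_magnitude: float = 1.0
    del_magnitude: float = 1.0
    gain_magnitude: float = 0.3
    loss_magnitude: float = 0.3
    marker_noise_sd: float = 0.15
    concurrent_fraction: float = 1.0 / 6.0
    dosage_beta: float = 2.5
    expr_noise_sd: float = 0.35
    signature_size: int = 20
    signature_factor_sd: float = 0.0
    log_hazard_coef: float = 1.0
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.7
    logistic_intercept: float = 0.0
    logistic_slope: float = 1.0
    probe_noise_sd: float = 0.25
    marker_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "n_samples": self.n_samples,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("seg_event_rate", "concurrent_fraction", "censoring_rate"):
            value = getattr(self, name)
            if name != "seg_event_rate" and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not self.gain_magnitude < self.amp_magnitude:
            raise ValueError("gain_magnitude must be < amp_magnitude")
        if not self.loss_magnitude < self.del_magnitude:
            raise ValueError("loss_magnitude must be < del_magnitude")
        for name in ("marker_noise_sd", "expr_noise_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic substream generator for one operation."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    concurrent_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    signature_genes: list[str] = field(default_factory=list)
    linear_predictor: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class CohortDataset:
    """One simulated cohort: inputs plus its share of the ground truth."""

    name: str
    marker_map: pd.DataFrame
    genes: pd.DataFrame
    log_ratios: pd.DataFrame
    expression: pd.DataFrame  # probe-level (rows = probes)
    probe_to_gene: pd.Series
    survival: pd.DataFrame  # sample_id, time, event
    binary_labels: pd.Series
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evenly spaced marker map plus non-overlapping gene intervals.

    Genes are laid out deterministically: each chromosome receives an equal
    share of genes, each occupying the first half (at least one marker) of
    its own marker block, so intervals are disjoint and each covers >= 1
    marker.
    """
    n_chrom = config.n_chromosomes
    n_mark = config.markers_per_chromosome
    spacing = config.marker_spacing
    rows = []
    for c in range(1, n_chrom + 1):
        for m in range(n_mark):
            rows.append(
                {
                    "marker_id": f"m_{c}_{m + 1}",
                    "chromosome": str(c),
                    "position": (m + 1) * spacing,
                }
            )
    marker_map = pd.DataFrame(rows)

    n_genes = config.n_genes
    if n_genes == 0:
        genes = pd.DataFrame(columns=["gene", "chromosome", "start", "end"])
        return marker_map, genes
    if n_genes > n_chrom * n_mark:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping genes on "
            f"{n_chrom * n_mark} markers"
        )
    per_chrom = [n_genes // n_chrom] * n_chrom
    for c in range(n_genes % n_chrom):
        per_chrom[c] += 1
    gene_rows = []
    g = 0
    for c in range(1, n_chrom + 1):
        k = per_chrom[c - 1]
        if k == 0:
            continue
        block = n_mark // k
        if block < 1:
            raise ValueError(f"too many genes ({k}) for chromosome of {n_mark} markers")
        for b in range(k):
            first = b * block  # 0-based marker offset
            width = max(1, block // 2)
            gene_rows.append(
                {
                    "gene": f"G{g + 1:04d}",
                    "chromosome": str(c),
                    "start": (first + 1) * spacing,
                    "end": (first + width) * spacing,
                }
            )
            g += 1
    genes = pd.DataFrame(gene_rows)
    return marker_map, genes


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def simulate_cnv_profiles(
    marker_map: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Piecewise-constant true copy-number means plus Gaussian marker noise.

    Event counts per sample-chromosome are Poisson(``seg_event_rate``);
    segment lengths are geometric in marker units with the configured mean;
    overlapping events are resolved later-event-wins.  Ground truth lists
    every maximal non-neutral run with its state, and the noiseless mean
    matrix is kept for gene-centric truth downstream.
    """
    rng = config.rng(1)
    chroms = marker_map["chromosome"].to_numpy()
    chrom_labels = list(dict.fromkeys(chroms))
    positions = marker_map["position"].to_numpy()
    n_markers = len(marker_map)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    states = list(_STATE_PROBS)
    probs = np.array([_STATE_PROBS[s] for s in states])
    geo_p = min(1.0, 1.0 / max(config.mean_segment_markers, 1.0))

    means = np.zeros((n_markers, config.n_samples))
    state_grid = np.full((n_markers, config.n_samples), "NEUTRAL", dtype=object)
    for s_i in range(config.n_samples):
        for chrom in chrom_labels:
            idx = np.flatnonzero(chroms == chrom)
            n_events = rng.poisson(config.seg_event_rate)
            for _ in range(n_events):
                start = rng.integers(0, idx.size)
                length = rng.geometric(geo_p)
                state = states[rng.choice(len(states), p=probs)]
                key, sign = _STATE_SHIFT_KEYS[state]
                shift = sign * getattr(config, key)
                span = idx[start : min(start + length, idx.size)]
                means[span, s_i] = shift
                state_grid[span, s_i] = state

    noise = rng.normal(0.0, config.marker_noise_sd, size=means.shape)
    log_ratios = pd.DataFrame(
        means + noise, index=marker_map["marker_id"].to_numpy(), columns=samples
    )
    log_ratios.index.name = "marker_id"
    true_means = pd.DataFrame(
        means, index=log_ratios.index.copy(), columns=samples
    )

    seg_rows = []
    for s_i, sample in enumerate(samples):
        for chrom in chrom_labels:
            idx = np.flatnonzero(chroms == chrom)
            run_start = 0
            col = state_grid[idx, s_i]
            for k in range(1, idx.size + 1):
                if k == idx.size or col[k] != col[run_start]:
                    if col[run_start] != "NEUTRAL":
                        seg_rows.append(
                            {
                                "sample_id": sample,
                                "chromosome": chrom,
                                "start_pos": int(positions[idx[run_start]]),
                                "end_pos": int(positions[idx[k - 1]]),
                                "n_markers": k - run_start,
                                "state": col[run_start],
                            }
                        )
                    run_start = k
    truth = GroundTruth(segments=pd.DataFrame(seg_rows), true_means=true_means)
    return log_ratios, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def pick_concurrent_genes(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw the shared concurrent set (gene, dosage_beta) from its substream."""
    rng = config.rng(2)
    n_conc = int(round(config.concurrent_fraction * len(genes)))
    chosen = rng.choice(genes["gene"].to_numpy(), size=n_conc, replace=False)
    return pd.DataFrame({"gene": np.sort(chosen), "dosage_beta": config.dosage_beta})


def simulate_expression(
    gene_cn_truth: pd.DataFrame,
    genes: pd.DataFrame,
    config: SimulationConfig,
    concurrent: pd.DataFrame | None = None,
    signature_genes: list[str] | None = None,
    stream: int = 3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene-level expression: dosage response for concurrent genes only.

    ``gene_cn_truth`` is the genes x samples matrix of *true* copy-number
    values (mean of true marker means inside each gene).  Concurrent genes
    get ``baseline + dosage_beta * cn + noise``; all others get
    ``baseline + noise`` with no dependence on copy number.

    When ``signature_factor_sd > 0`` the signature genes additionally share
    a per-sample latent factor with that SD, emulating the co-expression of
    a prognostic programme (without it the signature genes would be mutually
    independent, which no first-principal-component summary can exploit).
    """
    if concurrent is None:
        concurrent = pick_concurrent_genes(genes, config)
    missing = set(concurrent["gene"]) - set(gene_cn_truth.index)
    if missing:
        raise ValueError(f"concurrent genes absent from copy-number truth: {missing}")
    rng = config.rng(stream)
    gene_ids = gene_cn_truth.index.to_numpy()
    baseline = rng.normal(0.0, 1.0, size=len(gene_ids))
    noise = rng.normal(0.0, config.expr_noise_sd, size=gene_cn_truth.shape)
    values = baseline[:, None] + noise
    beta_by_gene = dict(zip(concurrent["gene"], concurrent["dosage_beta"]))
    cn = np.nan_to_num(gene_cn_truth.to_numpy(), nan=0.0)
    for g_i, gene in enumerate(gene_ids):
        beta = beta_by_gene.get(gene)
        if beta is not None:
            values[g_i] += beta * cn[g_i]
    if config.signature_factor_sd > 0 and signature_genes:
        factor = rng.normal(0.0, 1.0, size=gene_cn_truth.shape[1])
        sig_idx = [i for i, g in enumerate(gene_ids) if g in set(signature_genes)]
        values[sig_idx] += config.signature_factor_sd * factor[None, :]
    expr = pd.DataFrame(values, index=gene_cn_truth.index.copy(), columns=gene_cn_truth.columns)
    expr.index.name = "gene"
    return expr, GroundTruth(concurrent_genes=concurrent)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _signature_score(expr: pd.DataFrame, signature_genes: list[str]) -> pd.Series:
    score = expr.loc[signature_genes].mean(axis=0)
    sd = score.std(ddof=0)
    if sd == 0:
        return score - score.mean()
    return (score - score.mean()) / sd


def _solve_censoring_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target rate.

    For exponential event times with rate lambda, P(censored) =
    (1 - exp(-lambda c)) / (lambda c); averaged over samples and solved
    by bisection (monotone decreasing in c).
    """

    def censored_fraction(c: float) -> float:
        lc = rates * c
        return float(np.mean(np.where(lc > 0, -np.expm1(-lc) / np.maximum(lc, 1e-300), 1.0)))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda c: censored_fraction(c) - target, lo, hi))


def simulate_outcomes(
    expr: pd.DataFrame,
    signature_genes: list[str],
    config: SimulationConfig,
    stream: int = 4,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Survival table and dichotomous labels driven by the signature score.

    Event times are exponential with log hazard
    ``log_hazard_coef * standardized mean signature expression``; censoring
    is an independent Uniform(0, c) with c solved for the target censoring
    rate.  Binary labels are Bernoulli under a logistic link on the same
    score.  Returns (survival table, labels, true linear predictor).
    """
    missing = set(signature_genes) - set(expr.index)
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing}")
    if not signature_genes and config.log_hazard_coef != 0:
        raise ValueError("empty signature with nonzero log_hazard_coef")
    rng = config.rng(stream)
    if signature_genes:
        score = _signature_score(expr, list(signature_genes))
    else:
        score = pd.Series(0.0, index=expr.columns)
    lin_pred = config.log_hazard_coef * score
    rates = config.baseline_hazard * np.exp(lin_pred.to_numpy())
    times = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        c = _solve_censoring_bound(rates, config.censoring_rate)
        cens = rng.uniform(0.0, c, size=times.size)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(times.size, dtype=int)
        obs = times
    obs = np.maximum(obs, 1e-9)  # strictly positive
    survival = pd.DataFrame(
        {"sample_id": expr.columns, "time": obs, "event": event}
    )
    p1 = 1.0 / (1.0 + np.exp(-(config.logistic_intercept + config.logistic_slope * score)))
    labels = pd.Series(rng.binomial(1, p1), index=expr.columns, name="label")
    return survival, labels, lin_pred.rename("linear_predictor")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _expand_probes(
    expr: pd.DataFrame, probes_per_gene: int, rng: np.random.Generator, probe_noise_sd: float
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate each gene row into redundant probes with probe-level noise."""
    if probes_per_gene <= 1:
        probe_ids = [f"{g}_p1" for g in expr.index]
        probes = expr.copy()
        probes.index = pd.Index(probe_ids, name="probe")
        return probes, pd.Series(expr.index.to_numpy(), index=probes.index, name="gene")
    blocks, ids, gene_of = [], [], []
    for g in expr.index:
        base = expr.loc[g].to_numpy()
        for p in range(probes_per_gene):
            blocks.append(base + rng.normal(0.0, probe_noise_sd, size=base.size))
            ids.append(f"{g}_p{p + 1}")
            gene_of.append(g)
    probes = pd.DataFrame(np.vstack(blocks), index=pd.Index(ids, name="probe"), columns=expr.columns)
    return probes, pd.Series(gene_of, index=probes.index, name="gene")


def simulate_cohort(
    config: SimulationConfig,
    marker_map: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    concurrent: pd.DataFrame | None = None,
    signature_genes: list[str] | None = None,
    name: str = "cohort",
    probes_per_gene: int = 1,
) -> CohortDataset:
    """One full paired cohort; shared truth may be injected for multi-cohort runs."""
    from .segmentation import gene_centric_table

    if marker_map is None or genes is None:
        marker_map, genes = simulate_genome(config)
    if concurrent is None:
        concurrent = pick_concurrent_genes(genes, config)
    if signature_genes is None:
        rng = config.rng(5)
        pool = concurrent["gene"].to_numpy()
        size = min(config.signature_size, pool.size)
        signature_genes = sorted(rng.choice(pool, size=size, replace=False))

    log_ratios, truth = simulate_cnv_profiles(marker_map, config)
    gene_cn_truth, _ = gene_centric_table(truth.true_means, marker_map, genes)
    expr, expr_truth = simulate_expression(
        gene_cn_truth, genes, config, concurrent=concurrent,
        signature_genes=list(signature_genes),
    )
    survival, labels, lin_pred = simulate_outcomes(expr, signature_genes, config)
    rng_probe = config.rng(6)
    probes, probe_map = _expand_probes(expr, probes_per_gene, rng_probe, config.probe_noise_sd)

    truth.concurrent_genes = expr_truth.concurrent_genes
    truth.signature_genes = list(signature_genes)
    truth.linear_predictor = lin_pred
    return CohortDataset(
        name=name,
        marker_map=marker_map,
        genes=genes,
        log_ratios=log_ratios,
        expression=probes,
        probe_to_gene=probe_map,
        survival=survival,
        binary_labels=labels,
        truth=truth,
    )


def simulate_multi_cohort(
    config: SimulationConfig,
    cohort_sizes: tuple[int, ...] = (31, 345),
    probes_per_gene: int | tuple[int, ...] = 1,
) -> list[CohortDataset]:
    """Cohorts of unequal size sharing one genome and one ground truth.

    The gene universe, the concurrent set (with its dosage slopes) and the
    signature are drawn once; each cohort then gets independent CNV,
    expression and outcome noise through its own substream.
    """
    if len(cohort_sizes) < 2:
        raise ValueError("need at least two cohort sizes")
    marker_map, genes = simulate_genome(config)
    concurrent = pick_concurrent_genes(genes, config)
    rng = config.rng(5)
    pool = concurrent["gene"].to_numpy()
    size = min(config.signature_size, pool.size)
    signature = sorted(rng.choice(pool, size=size, replace=False))
    if isinstance(probes_per_gene, int):
        probes_per_gene = tuple([probes_per_gene] * len(cohort_sizes))
    cohorts = []
    for c_i, (n, ppg) in enumerate(zip(cohort_sizes, probes_per_gene)):
        sub = replace(config, n_samples=n, seed=int(np.random.default_rng([config.seed, 100 + c_i]).integers(2**31 - 1)))
        cohorts.append(
            simulate_cohort(
                sub,
                marker_map=marker_map,
                genes=genes,
                concurrent=concurrent,
                signature_genes=signature,
                name=f"cohort{c_i + 1}",
                probes_per_gene=ppg,
            )
        )
    return cohorts
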