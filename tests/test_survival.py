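"""Cox screening, the supervised-PC risk model, LOOCV, log-rank and IPCW AUC."""

import numpy as np
import pandas as pd
import pytest

from concurgene.survival import (
    consensus_filter,
    cox_screen,
    cox_univariate,
    fit_risk_model,
    logrank_test,
    loocv_risk_groups,
    predict_risk,
    time_dependent_auc,
)
from concurgene.synthetic import SimulationConfig, simulate_cohort


def _gene_level(cohort):
    expr = cohort.expression.copy()
    expr.index = [p.rsplit("_p", 1)[0] for p in expr.index]
    return expr


@pytest.fixture(scope="module")
def planted_cohort():
    """Signature-driven survival, decoupled from copy number."""
    cfg = SimulationConfig(
        n_chromosomes=1, markers_per_chromosome=300, n_genes=100, n_samples=120,
        dosage_beta=0.0, signature_size=10, signature_factor_sd=0.35,
        log_hazard_coef=2.0, censoring_rate=0.5, seed=21,
    )
    c = simulate_cohort(cfg)
    return _gene_level(c), c.survival, c.truth


class TestCoxScreen:
    def test_matches_r_survival_score_test(self):
        # fixture regenerated deterministically; oracle values computed with
        # R survival::coxph (Efron ties), summary()$sctest
        rng = np.random.default_rng(42)
        n = 30
        x1 = rng.normal(size=n).round(4)
        x2 = rng.normal(size=n).round(4)
        t = np.round(rng.exponential(10, n), 3)
        t[5] = t[7] = t[9]
        e = rng.integers(0, 2, n)
        e[:4] = 1
        out = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "time": t, "event": e})
        expr = pd.DataFrame([x1, x2], index=["x1", "x2"], columns=out["sample_id"])
        res = cox_screen(expr, out)
        assert res.loc["x1", "statistic"] == pytest.approx(0.3380820393, abs=1e-8)
        assert res.loc["x1", "p"] == pytest.approx(0.5609384028, abs=1e-8)
        assert res.loc["x2", "statistic"] == pytest.approx(2.7007934789, abs=1e-8)
        assert res.loc["x2", "p"] == pytest.approx(0.100298318, abs=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        n, g = 80, 1000
        t = rng.exponential(20, n)
        cens = rng.uniform(0, 40, n)
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "time": np.minimum(t, cens),
                "event": (t <= cens).astype(int),
            }
        )
        expr = pd.DataFrame(
            rng.normal(size=(g, n)), index=[f"g{i}" for i in range(g)],
            columns=out["sample_id"],
        )
        res = cox_screen(expr, out)
        from scipy.stats import kstest

        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_power_on_true_score(self, planted_cohort):
        expr, outcome, truth = planted_cohort
        score = truth.linear_predictor.reindex(outcome["sample_id"])
        stat, p = cox_univariate(score, outcome)
        assert p < 1e-4

    def test_constant_covariate_flagged(self):
        out = pd.DataFrame(
            {"sample_id": list("abcdef"), "time": [1, 2, 3, 4, 5, 6.0], "event": 1}
        )
        expr = pd.DataFrame([[2.0] * 6], index=["g"], columns=out["sample_id"])
        res = cox_screen(expr, out)
        assert np.isnan(res.loc["g", "statistic"])

    def test_requires_two_events(self):
        out = pd.DataFrame(
            {"sample_id": list("abcd"), "time": [1, 2, 3, 4.0], "event": [1, 0, 0, 0]}
        )
        expr = pd.DataFrame([[1, 2, 3, 4.0]], index=["g"], columns=out["sample_id"])
        with pytest.raises(ValueError):
            cox_screen(expr, out)


class TestRiskModel:
    def test_rank_one_expression_recovers_latent_factor(self):
        rng = np.random.default_rng(3)
        n = 60
        factor = rng.normal(size=n)
        load = rng.normal(size=20)
        expr = pd.DataFrame(
            np.outer(load, factor), index=[f"g{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(n)],
        )
        t = np.exp(-factor) * rng.exponential(1.0, n) + 0.01
        out = pd.DataFrame({"sample_id": expr.columns, "time": t, "event": 1})
        model = fit_risk_model(expr, out, alpha=0.05)
        rho = np.corrcoef(model.train_index, factor)[0, 1]
        assert abs(rho) > 0.999
        assert rho > 0  # oriented so larger index = larger hazard

    def test_loadings_unit_norm_and_half_split(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        model = fit_risk_model(expr, outcome, alpha=0.01, percentile=50)
        assert np.linalg.norm(model.loadings) == pytest.approx(1.0)
        n_high = (model.train_index > model.threshold).sum()
        assert n_high in (len(model.train_index) // 2, (len(model.train_index) + 1) // 2)

    def test_selected_genes_are_mostly_signature(self, planted_cohort):
        expr, outcome, truth = planted_cohort
        model = fit_risk_model(expr, outcome, alpha=0.001)
        frac = np.mean([g in set(truth.signature_genes) for g in model.genes])
        assert frac >= 0.8

    def test_no_passing_gene_raises(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(10, 30)), index=[f"g{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(30)],
        )
        out = pd.DataFrame(
            {"sample_id": expr.columns, "time": rng.exponential(5, 30), "event": 1}
        )
        with pytest.raises(ValueError, match="no gene passes"):
            fit_risk_model(expr, out, alpha=1e-12)


class TestPredictRisk:
    def test_training_matrix_reproduces_training_indices(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        model = fit_risk_model(expr, outcome, alpha=0.01)
        pred = predict_risk(model, expr)
        assert np.allclose(
            pred.set_index("sample_id")["prognostic_index"], model.train_index
        )

    def test_index_shift_is_loading_weighted(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        model = fit_risk_model(expr, outcome, alpha=0.01)
        shifted = expr.copy()
        shifted.iloc[:, 0] = shifted.iloc[:, 0] + 1.0
        base = predict_risk(model, expr).iloc[0]["prognostic_index"]
        new = predict_risk(model, shifted).iloc[0]["prognostic_index"]
        expected = (model.loadings / model.sds.loc[model.genes]).sum()
        assert new - base == pytest.approx(expected, rel=1e-9)

    def test_missing_genes_imputed_then_refused(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        model = fit_risk_model(expr, outcome, alpha=0.01)
        if len(model.genes) > 1:
            partial = expr.drop(index=model.genes[:1])
            pred = predict_risk(model, partial)
            assert len(pred) == expr.shape[1]
        with pytest.raises(ValueError):
            predict_risk(model, expr.drop(index=model.genes))


class TestLoocv:
    def test_strong_signal_gives_significant_logrank(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        cv = loocv_risk_groups(expr, outcome)
        labels = cv.set_index("sample_id")["risk_label"]
        chi2, p = logrank_test(outcome, labels)
        assert p < 0.01

    def test_deterministic_rerun(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        sub = expr.iloc[:, :30]
        out_sub = outcome[outcome["sample_id"].isin(sub.columns)]
        a = loocv_risk_groups(sub, out_sub, alpha=0.01)
        b = loocv_risk_groups(sub, out_sub, alpha=0.01)
        pd.testing.assert_frame_equal(a, b)

    def test_heldout_outcome_never_influences_its_label(self, planted_cohort):
        """Leakage check: flipping the held-out sample's outcome leaves its
        cross-validated label unchanged."""
        expr, outcome, _ = planted_cohort
        sub = expr.iloc[:, :30]
        out_sub = outcome[outcome["sample_id"].isin(sub.columns)].reset_index(drop=True)
        base = loocv_risk_groups(sub, out_sub, alpha=0.01)
        for sample in sub.columns[:3]:
            mutated = out_sub.copy()
            row = mutated["sample_id"] == sample
            mutated.loc[row, "event"] = 1 - mutated.loc[row, "event"]
            mutated.loc[row, "time"] = mutated.loc[row, "time"] * 7 + 1
            cv = loocv_risk_groups(sub, mutated, alpha=0.01)
            assert (
                cv.set_index("sample_id").loc[sample, "risk_label"]
                == base.set_index("sample_id").loc[sample, "risk_label"]
            )

    def test_small_n_rejected(self, planted_cohort):
        expr, outcome, _ = planted_cohort
        with pytest.raises(ValueError):
            loocv_risk_groups(expr.iloc[:, :5], outcome.head(5))


class TestLogrank:
    def test_identical_groups_give_zero(self):
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(8)],
                "time": [1, 2, 3, 4, 1, 2, 3, 4.0],
                "event": 1,
            }
        )
        labels = pd.Series(
            ["a"] * 4 + ["b"] * 4, index=out["sample_id"]
        )
        chi2, p = logrank_test(out, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_risk_set_tabulation(self):
        # A = {1,2,3}, B = {4,5,6}, all events.
        # O_A = 3; E_A = 3/6 + 2/5 + 1/4 = 1.15
        # V = 9/36 + 6/25 + 3/16 = 0.6775; chi2 = (3-1.15)^2/0.6775
        out = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "time": [1, 2, 3, 4, 5, 6.0],
                "event": 1,
            }
        )
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=out["sample_id"])
        chi2, p = logrank_test(out, labels)
        assert chi2 == pytest.approx(1.85**2 / 0.6775, rel=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(40)],
                "time": rng.exponential(10, 40),
                "event": rng.integers(0, 2, 40),
            }
        )
        labels = pd.Series(
            np.where(rng.random(40) < 0.5, "x", "y"), index=out["sample_id"]
        )
        swapped = labels.map({"x": "y", "y": "x"})
        assert logrank_test(out, labels)[0] == pytest.approx(logrank_test(out, swapped)[0])

    def test_single_group_rejected(self):
        out = pd.DataFrame(
            {"sample_id": list("abc"), "time": [1, 2, 3.0], "event": 1}
        )
        with pytest.raises(ValueError):
            logrank_test(out, pd.Series(["a"] * 3, index=out["sample_id"]))


class TestTimeDependentAuc:
    def test_perfect_separation_no_censoring(self):
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(10)],
                "time": [1, 2, 3, 4, 5, 20, 21, 22, 23, 24.0],
                "event": 1,
            }
        )
        idx = pd.Series(
            [9, 8, 7, 6, 5, 1, 2, 3, 0.5, 0.2], index=out["sample_id"]
        )
        assert time_dependent_auc(idx, out, 10.0) == 1.0

    def test_equals_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(6)
        n = 60
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "time": rng.exponential(10, n),
                "event": 1,
            }
        )
        idx = pd.Series(rng.normal(size=n), index=out["sample_id"])
        landmark = float(np.median(out["time"]))
        status = (out["time"] <= landmark).to_numpy()
        from scipy.stats import rankdata

        ranks = rankdata(idx.to_numpy())
        n1, n0 = status.sum(), (~status).sum()
        mw = (ranks[status].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert time_dependent_auc(idx, out, landmark) == pytest.approx(mw)

    def test_random_indices_near_half(self):
        rng = np.random.default_rng(7)
        n = 600
        t = rng.exponential(10, n)
        cens = rng.uniform(0, 30, n)
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "time": np.minimum(t, cens),
                "event": (t <= cens).astype(int),
            }
        )
        idx = pd.Series(rng.normal(size=n), index=out["sample_id"])
        auc = time_dependent_auc(idx, out, 8.0)
        assert abs(auc - 0.5) < 0.05

    def test_close_to_independent_ipcw_implementation(self):
        """Cross-check against scikit-survival's IPCW cumulative/dynamic AUC."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(8)
        n = 200
        risk = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-risk), n)
        cens = rng.uniform(0, 25, n)
        out = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "time": np.maximum(np.minimum(t, cens), 1e-6),
                "event": (t <= cens).astype(int),
            }
        )
        idx = pd.Series(risk, index=out["sample_id"])
        y = Surv.from_arrays(out["event"].astype(bool), out["time"])
        ref = cumulative_dynamic_auc(y, y, risk, [8.0])[0][0]
        ours = time_dependent_auc(idx, out, 8.0)
        assert ours == pytest.approx(ref, abs=0.03)

    def test_landmark_outside_range_rejected(self):
        out = pd.DataFrame(
            {"sample_id": list("abc"), "time": [1, 2, 3.0], "event": 1}
        )
        idx = pd.Series([1.0, 2.0, 3.0], index=out["sample_id"])
        with pytest.raises(ValueError):
            time_dependent_auc(idx, out, 99.0)


class TestConsensusFilter:
    def test_gene_in_three_of_five(self):
        flags = pd.DataFrame(
            False, index=["g1", "g2"], columns=[f"d{i}" for i in range(5)]
        )
        flags.loc["g1", ["d0", "d1", "d2"]] = True
        counts, lists = consensus_filter(flags)
        assert "g1" in lists[1] and "g1" in lists[3]
        assert "g1" not in lists[4]

    def test_counts_non_increasing(self):
        rng = np.random.default_rng(9)
        flags = pd.DataFrame(
            rng.random((50, 6)) < 0.3,
            index=[f"g{i}" for i in range(50)],
            columns=[f"d{i}" for i in range(6)],
        )
        counts, _ = consensus_filter(flags)
        assert (np.diff(counts.to_numpy()) <= 0).all()

    def test_disjoint_flags_have_no_level_two(self):
        flags = pd.DataFrame(
            [[True, False], [False, True]], index=["g1", "g2"], columns=["d1", "d2"]
        )
        counts, lists = consensus_filter(flags)
        assert counts[2] == 0 and counts[1] == 2
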