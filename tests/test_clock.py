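"""Elastic-net clock: solver correctness against an independent
coordinate-descent oracle, prediction semantics, evaluation metrics and
the cohort deceleration readout."""

import numpy as np
import pandas as pd
import pytest

import passclock as pc
from passclock.clock import elastic_net_fit, elastic_net_objective, lambda_max
from passclock.exceptions import ConfigError, DesignError, MissingProbeError

from oracles import enet_coordinate_descent, enet_kkt_residuals


def _gaussian_instance(n=20, p=10, seed=123):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.zeros(p)
    w[:3] = [1.5, -2.0, 0.5]
    y = 12.0 + X @ w + rng.normal(0, 0.5, n)
    return X, y


class TestElasticNetCore:
    def test_null_model_beyond_lambda_max(self):
        X, y = _gaussian_instance()
        lmax = lambda_max(X, y, 0.5)
        for lam in (lmax, 1.5 * lmax):
            w0, w = elastic_net_fit(X, y, 0.5, lam)
            assert np.all(w == 0.0)
            assert w0 == y.mean()

    def test_unpenalised_limit_is_ols(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 1))
        y = 3.0 + 2.0 * x[:, 0] + rng.normal(0, 0.1, 30)
        w0, w = elastic_net_fit(x, y, 0.5, 1e-10)
        b = np.polyfit(x[:, 0], y, 1)[0]
        assert w[0] == pytest.approx(b, abs=1e-6)

    @pytest.mark.parametrize("lam_frac", [0.5, 0.1, 0.01])
    def test_agrees_with_coordinate_descent_oracle(self, lam_frac):
        X, y = _gaussian_instance()
        lam = lam_frac * lambda_max(X, y, 0.5)
        w0, w = elastic_net_fit(X, y, 0.5, lam, tol=1e-12)
        ob, ow = enet_coordinate_descent(X, y, 0.5, lam, tol=1e-13)
        ours = elastic_net_objective(X, y, w0, w, 0.5, lam)
        theirs = elastic_net_objective(X, y, ob, ow, 0.5, lam)
        assert ours == pytest.approx(theirs, abs=1e-8)
        kkt, kkt_b = enet_kkt_residuals(X, y, w0, w, 0.5, lam)
        assert kkt.max() < 1e-6 and kkt_b < 1e-6

    def test_local_optimality_under_perturbation(self):
        """The returned fit beats every point of a random perturbation
        cloud around it."""
        X, y = _gaussian_instance()
        lam = 0.05 * lambda_max(X, y, 0.5)
        w0, w = elastic_net_fit(X, y, 0.5, lam, tol=1e-12)
        base = elastic_net_objective(X, y, w0, w, 0.5, lam)
        rng = np.random.default_rng(99)
        for scale in (1e-3, 1e-2, 1e-1):
            pert_w = w + rng.normal(0, scale, (1000 // 3 + 1, w.size))
            pert_b = w0 + rng.normal(0, scale, pert_w.shape[0])
            objs = [elastic_net_objective(X, y, b_, w_, 0.5, lam)
                    for b_, w_ in zip(pert_b, pert_w)]
            assert base <= min(objs) + 1e-12


class TestFitClock:
    def test_deterministic_given_seed(self, small_cohort):
        beta, sheet, _ = small_cohort
        train = [s for s in beta.sample_ids if s.startswith("train")]
        bt = beta.select_samples(train)
        probes = [r.probe_id for r in
                  pc.screen_dmps(bt, sheet, pc.ScreenConfig(threshold=1e-11))]
        m1 = pc.fit_clock(bt.select_probes(probes), sheet, cv=pc.CvSpec(seed=3))
        m2 = pc.fit_clock(bt.select_probes(probes), sheet, cv=pc.CvSpec(seed=3))
        assert m1 == m2

    def test_coefficient_signs_match_drift_direction(self, small_cohort, small_clock):
        beta, sheet, truth = small_cohort
        model, _ = small_clock
        slopes = dict(zip(truth.drifters["probe_id"], truth.drifters["slope"]))
        selected_truth = [p for p in model.weights if p in slopes]
        assert selected_truth, "clock selected no truth CpGs"
        agree = sum(np.sign(model.weights[p]) == np.sign(slopes[p])
                    for p in selected_truth)
        assert agree >= 0.9 * len(selected_truth)

    def test_constant_columns_dropped(self, toy_sheet):
        rng = np.random.default_rng(4)
        n = 12
        sheet = pc.SampleSheet(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "passage": np.repeat([10, 12, 14, 16], 3)}))
        vals = rng.random((3, n))
        vals[1] = 0.5  # constant probe
        beta = pc.BetaMatrix(("cgA", "cgB", "cgC"),
                             tuple(f"S{i}" for i in range(n)), vals)
        model = pc.fit_clock(beta, sheet, cv=pc.CvSpec(n_folds=3, seed=0))
        assert "cgB" not in model.weights

    def test_too_few_samples_for_folds(self, toy_beta, toy_sheet):
        with pytest.raises(ConfigError):
            pc.fit_clock(toy_beta, toy_sheet, cv=pc.CvSpec(n_folds=10))


class TestPredict:
    def test_intercept_only_model_predicts_constant(self, toy_beta):
        model = pc.ClockModel(intercept=15.0, weights={})
        preds = pc.predict_passage(model, toy_beta)
        assert [p.predicted_passage for p in preds] == [15.0, 15.0]

    def test_single_probe_affine_form(self, toy_beta):
        model = pc.ClockModel(intercept=15.0, weights={"cgA": 1.0})
        preds = pc.predict_passage(model, toy_beta)
        assert [p.predicted_passage for p in preds] == \
            pytest.approx([15.0 + 0.1, 15.0 + 0.2])

    def test_extra_probes_do_not_change_predictions(self, small_cohort, small_clock):
        beta, sheet, _ = small_cohort
        model, probes = small_clock
        sub = beta.select_probes(list(model.weights))
        full = beta  # contains hundreds of probes not in the model
        a = pc.predict_passage(model, sub, sheet)
        b = pc.predict_passage(model, full, sheet)
        assert [p.predicted_passage for p in a] == \
               [p.predicted_passage for p in b]

    def test_prediction_is_affine_in_beta(self, small_clock, small_cohort):
        beta, _, _ = small_cohort
        model, _ = small_clock
        sub = beta.select_probes(list(model.weights))
        half = pc.BetaMatrix(sub.probe_ids, sub.sample_ids, 0.5 * sub.values)
        full_p = np.array([p.predicted_passage
                           for p in pc.predict_passage(model, sub)])
        half_p = np.array([p.predicted_passage
                           for p in pc.predict_passage(model, half)])
        w0 = model.intercept
        assert np.allclose(half_p - w0, 0.5 * (full_p - w0), atol=1e-9)

    def test_missing_probe_is_hard_error(self, small_clock, small_cohort):
        beta, _, _ = small_cohort
        model, _ = small_clock
        some_probe = next(iter(model.weights))
        pruned = beta.drop_probes([some_probe])
        with pytest.raises(MissingProbeError, match=some_probe):
            pc.predict_passage(model, pruned)

    def test_missing_value_in_clock_probe_is_hard_error(self, small_clock, small_cohort):
        beta, _, _ = small_cohort
        model, _ = small_clock
        sub = beta.select_probes(list(model.weights))
        vals = sub.values.copy()
        vals[0, 0] = np.nan
        with pytest.raises(MissingProbeError):
            pc.predict_passage(model, pc.BetaMatrix(sub.probe_ids,
                                                    sub.sample_ids, vals))


class TestEvaluate:
    def test_perfect_prediction(self):
        preds = [pc.PredictionResult(f"S{i}", float(p), p)
                 for i, p in enumerate((10, 12, 14, 16))]
        m = pc.evaluate(preds)
        assert m.rmse == 0.0 and m.spearman_rho == 1.0

    def test_hand_example(self):
        preds = [pc.PredictionResult("a", 10.0, 11),
                 pc.PredictionResult("b", 12.0, 12),
                 pc.PredictionResult("c", 14.0, 13)]
        m = pc.evaluate(preds)
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        assert m.spearman_rho == pytest.approx(1.0)
        assert 0 < m.spearman_p <= 1

    def test_constant_predictions_flagged(self):
        preds = [pc.PredictionResult(f"S{i}", 5.0, p)
                 for i, p in enumerate((10, 12, 14))]
        m = pc.evaluate(preds)
        assert not m.spearman_defined
        assert m.rmse > 0

    def test_too_few_samples(self):
        with pytest.raises(DesignError):
            pc.evaluate([pc.PredictionResult("a", 1.0, 1)])


class TestAcceleration:
    @staticmethod
    def _cohorts(effect_by_passage, seed=0, n=8):
        """Two cohorts with prescribed per-passage delta shifts."""
        rng = np.random.default_rng(seed)
        rows, preds = [], []
        for p, shift in effect_by_passage.items():
            for cohort, s in (("vehicle", 0.0), ("drug", shift)):
                for k in range(n):
                    sid = f"{cohort}_{p}_{k}"
                    rows.append({"sample_id": sid, "passage": p,
                                 "treatment": cohort,
                                 "cumulative_pd": 2.5 * (p - 8)})
                    preds.append(pc.PredictionResult(
                        sid, p + s + rng.normal(0, 0.1), p))
        return preds, pc.SampleSheet(pd.DataFrame(rows))

    def test_null_comparison_within_noise(self):
        preds, sheet = self._cohorts({16: 0.0, 18: 0.0, 20: 0.0}, seed=1)
        comp = pc.compute_acceleration(preds, sheet, "drug", "vehicle")
        assert abs(comp.overall_effect) < 2 * comp.overall_se

    def test_deceleration_pattern_and_monotonicity(self):
        preds, sheet = self._cohorts({16: -2.1, 18: -2.7, 20: -3.3}, seed=2)
        comp = pc.compute_acceleration(preds, sheet, "drug", "vehicle")
        effects = list(comp.table["effect"])
        assert all(e < 0 for e in effects)
        assert effects[0] > effects[1] > effects[2]
        weaker, _ = self._cohorts({16: -1.0, 18: -1.3, 20: -1.6}, seed=2)
        comp2 = pc.compute_acceleration(weaker, sheet, "drug", "vehicle")
        assert comp2.overall_effect > comp.overall_effect

    def test_cumulative_pd_axis(self):
        preds, sheet = self._cohorts({16: -2.0, 18: -2.5, 20: -3.0}, seed=3)
        comp = pc.compute_acceleration(preds, sheet, "drug", "vehicle",
                                       x_axis="cumulative_pd", n_bins=3)
        assert comp.x_axis == "cumulative_pd"
        assert (comp.table["effect"] < 0).all()

    def test_absent_label_is_an_error(self):
        preds, sheet = self._cohorts({16: 0.0})
        with pytest.raises(pc.exceptions.LabelError):
            pc.compute_acceleration(preds, sheet, "nosuchdrug", "vehicle")
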