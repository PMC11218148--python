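"""Simulator contracts: determinism, drift calibration, trajectory
transforms (deceleration, immortalisation) and marginal statistics."""

import io

import numpy as np
import pytest

import passclock as pc
from passclock.exceptions import ConfigError
from passclock.simulate import CohortSpec
from conftest import SMALL


def _cohort_means(beta, sheet, label, passage, probes):
    ids = [s for s, t, p in zip(sheet.frame["sample_id"], sheet.frame["treatment"],
                                sheet.frame["passage"])
           if t == label and p == passage]
    return beta.select_probes(probes).select_samples(ids).values.mean(axis=1)


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg = pc.default_config(**SMALL)
        b1, s1, t1 = pc.generate_cohort(cfg)
        b2, s2, t2 = pc.generate_cohort(cfg)
        assert b1 == b2 and s1 == s2
        assert t1.drifters.equals(t2.drifters)

    def test_written_tsv_bytes_identical(self, tmp_path):
        cfg = pc.default_config(**SMALL)
        texts = []
        for run in ("a", "b"):
            beta, sheet, _ = pc.generate_cohort(cfg)
            path = tmp_path / f"{run}.tsv"
            pc.write_beta_matrix(beta, path)
            texts.append(path.read_bytes())
        assert texts[0] == texts[1]

    def test_different_seed_differs(self):
        b1, _, _ = pc.generate_cohort(pc.default_config(**{**SMALL, "seed": 1}))
        b2, _, _ = pc.generate_cohort(pc.default_config(**{**SMALL, "seed": 2}))
        assert not np.array_equal(b1.values, b2.values)


class TestStructure:
    def test_default_design_counts(self, small_cohort):
        beta, sheet, truth = small_cohort
        frame = sheet.frame
        assert (frame["treatment"] == "train").sum() == 39
        assert (frame["treatment"] == "test").sum() == 26
        assert beta.n_samples == 65
        assert len(truth.drifting_probe_ids) == SMALL["n_hypo"] + \
            SMALL["n_hyper"] + SMALL["n_extra_drifters"]

    def test_directions_split(self, small_cohort):
        _, _, truth = small_cohort
        d = truth.drifters
        assert ((d["slope"] < 0) == (d["direction"] == "hypo")).all()
        assert (d["direction"] == "hypo").sum() >= SMALL["n_hypo"]
        assert (d["direction"] == "hyper").sum() >= SMALL["n_hyper"]

    def test_values_inside_unit_interval(self, small_cohort):
        beta, _, _ = small_cohort
        assert ((beta.values > 0) & (beta.values < 1)).all()

    def test_background_means_near_drawn_baselines(self):
        """Per-probe sample means of static probes sit within 3 SE of a
        bimodal-mixture baseline (all well inside (0.02, 0.98))."""
        beta, sheet, truth = pc.generate_cohort(
            pc.default_config(n_probes=300, n_hypo=0, n_hyper=0,
                              n_extra_drifters=0, seed=9))
        means = beta.values.mean(axis=1)
        # SE of the mean of 65 beta draws at kappa=200 is < 0.005
        assert ((means > 0.005) & (means < 0.995)).all()
        # bimodality: almost nothing in the middle
        assert np.mean((means > 0.3) & (means < 0.7)) < 0.1


class TestDriftCalibration:
    def test_mean_absolute_change_matches_target(self):
        beta, sheet, truth = pc.generate_cohort(pc.default_config(
            n_probes=2000, n_hypo=20, n_hyper=20, n_extra_drifters=20, seed=21))
        probes = list(truth.drifting_probe_ids)
        m10 = _cohort_means(beta, sheet, "train", 10, probes)
        m20 = _cohort_means(beta, sheet, "train", 20, probes)
        assert np.abs(m20 - m10).mean() == pytest.approx(0.2, abs=0.02)

    def test_zero_drift_yields_no_screen_hits(self):
        beta, sheet, _ = pc.generate_cohort(pc.default_config(
            n_probes=2000, drift_total=0.0, seed=13))
        train = [s for s in beta.sample_ids if s.startswith("train")]
        res = pc.screen_dmps(beta.select_samples(train), sheet,
                             pc.ScreenConfig(threshold=1e-11))
        assert res == []


class TestEffectivePassage:
    def test_control_is_identity(self):
        spec = CohortSpec("c")
        assert spec.effective_passage(16) == 16.0

    def test_deceleration_formula(self):
        spec = CohortSpec("d", deceleration=0.3, onset_passage=9)
        assert spec.effective_passage(16) == pytest.approx(9 + 7 * 0.7)
        assert spec.effective_passage(9) == 9.0

    def test_full_deceleration_freezes_trajectory(self):
        """d=1 from P9: every passage >= 9 has the P9 mean trajectory."""
        cohorts = (CohortSpec("frozen", ((10, 2), (15, 2), (20, 2)),
                              deceleration=1.0, onset_passage=9),)
        beta, sheet, truth = pc.generate_cohort(pc.default_config(
            **{**SMALL, "cohorts": cohorts}))
        probes = list(truth.drifting_probe_ids)
        m = [_cohort_means(beta, sheet, "frozen", p, probes).mean()
             for p in (10, 15, 20)]
        # only sampling noise (SE ~0.006 per cohort mean), vs the ~0.2
        # spread a control trajectory would accumulate over P10-P20
        assert np.ptp(m) < 0.03

    def test_immortalisation_residual_formula(self):
        spec = CohortSpec("i", ((10, 1), (20, 1)), immortalisation_passage=12,
                          residual_drift=0.4)
        assert spec.effective_passage(11) == 11.0
        assert spec.effective_passage(20) == pytest.approx(12 + 8 * 0.4)

    def test_residual_one_matches_control(self):
        cfg = pc.default_config(**SMALL)
        base, _, _ = pc.generate_cohort(cfg)
        full, sheet, _ = pc.generate_immortalised(cfg, residual_drift=1.0)
        # the added arm follows the control trajectory law exactly
        spec = CohortSpec("x", immortalisation_passage=12, residual_drift=1.0,
                          schedule=((10, 1), (20, 1)))
        assert spec.effective_passage(17) == 17.0
        assert full.n_samples == base.n_samples + 18

    def test_residual_zero_plateaus_predictions(self):
        cfg = pc.immortalised_config(residual_drift=0.0,
                                     immortalisation_passage=12,
                                     **{**SMALL, "seed": 23})
        beta, sheet, truth = pc.generate_cohort(cfg)
        train = [s for s in beta.sample_ids if s.startswith("train")]
        bt = beta.select_samples(train)
        dmps = pc.screen_dmps(bt, sheet, pc.ScreenConfig(threshold=1e-11))
        model = pc.fit_clock(bt.select_probes([r.probe_id for r in dmps]),
                             sheet, cv=pc.CvSpec(seed=1))
        imm = [s for s in beta.sample_ids if s.startswith("immortalised")]
        preds = pc.predict_passage(model, beta.select_samples(imm), sheet)
        late = [p.predicted_passage for p in preds if p.actual_passage >= 14]
        # frozen drift: predictions hover at the clock's estimate of
        # P12 instead of spanning the 8-passage range P14-P20
        assert np.ptp(late) < 2.0
        assert np.mean(late) == pytest.approx(12.0, abs=1.0)


class TestConfigValidation:
    def test_too_many_drifters_rejected(self):
        with pytest.raises(ConfigError):
            pc.default_config(n_probes=10, n_hypo=20)

    def test_duplicate_cohort_labels_rejected(self):
        with pytest.raises(ConfigError):
            pc.SyntheticConfig(cohorts=(CohortSpec("a"), CohortSpec("a")))

    def test_invalid_deceleration_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec("x", deceleration=1.5)
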