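"""Metric definitions, aggregation, and experiment bookkeeping."""

import inspect

import numpy as np
import pandas as pd
import pytest

from shuntscope.evaluate import (DEFAULT_SWEEP_CONCENTRATIONS,
                                 DEFAULT_SWEEP_OPEN_BEAM,
                                 DEFAULT_SWEEP_VOLUMES, aggregate,
                                 default_threshold_grid, run_fixed_experiment,
                                 run_sweep_experiment, score_frame)


class TestScoreFrame:
    def test_perfect_prediction(self):
        truth = np.zeros((8, 8), bool)
        truth[2:5, 2:5] = True
        s = score_frame(truth.astype(float), truth, 0.5)
        assert (s.sensitivity, s.precision, s.dsc) == (1.0, 1.0, 1.0)

    def test_disjoint_prediction(self):
        truth = np.zeros((8, 8), bool)
        truth[:2] = True
        pred = np.zeros((8, 8))
        pred[6:] = 1.0
        s = score_frame(pred, truth, 0.5)
        assert s.sensitivity == 0.0 and s.dsc == 0.0

    def test_dsc_harmonic_formula(self):
        """sens 0.7, prec 0.9 -> DSC = 2*0.63/1.6 = 0.7875 exactly."""
        # 7 of 10 truth pixels hit; 7 detected pixels of which 7*?; build
        # counts giving sens=0.7, prec=0.9: tp=63, fn=27, fp=7
        prob = np.zeros((10, 10))
        truth = np.zeros((10, 10), bool)
        truth.ravel()[:90] = True
        prob.ravel()[:63] = 1.0       # 63 true positives
        prob.ravel()[90:97] = 1.0     # 7 false positives
        s = score_frame(prob, truth, 0.5)
        assert s.sensitivity == pytest.approx(0.7)
        assert s.precision == pytest.approx(0.9)
        assert s.dsc == pytest.approx(0.7875)

    def test_counts_match_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            prob = rng.random((16, 16))
            truth = rng.random((16, 16)) > 0.8
            thr = rng.uniform(0.2, 0.8)
            s = score_frame(prob, truth, thr)
            tp = fp = fn = 0
            for i in range(16):
                for j in range(16):
                    pred = prob[i, j] >= thr
                    if pred and truth[i, j]:
                        tp += 1
                    elif pred:
                        fp += 1
                    elif truth[i, j]:
                        fn += 1
            assert (s.tp, s.fp, s.fn) == (tp, fp, fn)

    def test_degenerate_obstructed_frame_flagged(self):
        truth = np.zeros((4, 4), bool)
        truth[0, 0] = True
        s = score_frame(np.zeros((4, 4)), truth, 0.5)
        assert s.degenerate and s.dsc == 0.0 and s.precision == 0.0

    def test_dsc_between_sensitivity_and_precision(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            prob = rng.random((12, 12))
            truth = rng.random((12, 12)) > 0.7
            s = score_frame(prob, truth, 0.5)
            if s.tp + s.fp and s.tp + s.fn:
                lo, hi = sorted([s.sensitivity, s.precision])
                assert lo - 1e-12 <= s.dsc <= hi + 1e-12


class TestAggregate:
    def _random_maps(self, n, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random((n, 16, 16))
        truths = rng.random((n, 16, 16)) > 0.85
        return probs, truths

    def test_threshold_grid_contains_operating_point(self):
        grid = default_threshold_grid()
        assert 0.5 in np.round(grid, 2)
        assert grid.min() == pytest.approx(0.05)
        assert grid.max() == pytest.approx(0.95)

    def test_fpr_definitions(self):
        probs, truths = self._random_maps(4, 0)
        zeros = np.zeros((5, 16, 16))
        rep = aggregate(probs, truths, zeros)
        assert np.all(rep.curves["fpr"] == 0.0)
        ones = np.ones((5, 16, 16))
        rep = aggregate(probs, truths, ones)
        assert np.all(rep.curves["fpr"] == 1.0)

    def test_fpr_matches_recount_oracle(self):
        probs, truths = self._random_maps(6, 1)
        clean = np.random.default_rng(2).random((9, 16, 16)) ** 4
        rep = aggregate(probs, truths, clean)
        for _, row in rep.curves.iterrows():
            recount = sum(1 for p in clean if (p >= row["threshold"]).sum() >= 1)
            assert row["fpr"] == pytest.approx(recount / len(clean))

    def test_sensitivity_and_fpr_monotone_in_threshold(self):
        probs, truths = self._random_maps(8, 3)
        clean = np.random.default_rng(4).random((8, 16, 16))
        rep = aggregate(probs, truths, clean)
        assert np.all(np.diff(rep.curves["mean_sensitivity"]) <= 1e-12)
        assert np.all(np.diff(rep.curves["fpr"]) <= 1e-12)

    def test_perfect_oracle_maps(self):
        """Truth masks used as probabilities: everything is perfect at any
        threshold in (0, 1]."""
        rng = np.random.default_rng(5)
        truths = rng.random((5, 16, 16)) > 0.8
        clean = np.zeros((5, 16, 16))
        rep = aggregate(truths.astype(float), truths, clean,
                        thresholds=[0.1, 0.5, 1.0])
        for _, row in rep.curves.iterrows():
            assert row["mean_sensitivity"] == 1.0
            assert row["mean_precision"] == 1.0
            assert row["median_dsc"] == 1.0
            assert row["fpr"] == 0.0

    def test_rejects_empty_groups(self):
        probs, truths = self._random_maps(2, 6)
        with pytest.raises(ValueError):
            aggregate(probs, truths, np.zeros((0, 16, 16)))
        with pytest.raises(ValueError):
            aggregate(np.zeros((0, 16, 16)), np.zeros((0, 16, 16), bool),
                      probs)


class TestExperimentBookkeeping:
    def test_sweep_grid_is_5x5x5_with_10_per_cell(self):
        """The default sweep requests 5*5*5 cells x 10 = 1250 projections
        for training and the same for testing."""
        assert len(DEFAULT_SWEEP_VOLUMES) == 5
        assert len(DEFAULT_SWEEP_CONCENTRATIONS) == 5
        assert len(DEFAULT_SWEEP_OPEN_BEAM) == 5
        sig = inspect.signature(run_sweep_experiment)
        assert sig.parameters["n_per_cell"].default == 10
        n_cells = (len(DEFAULT_SWEEP_VOLUMES)
                   * len(DEFAULT_SWEEP_CONCENTRATIONS)
                   * len(DEFAULT_SWEEP_OPEN_BEAM))
        assert n_cells * sig.parameters["n_per_cell"].default == 1250

    def test_fixed_experiment_defaults_are_reference_scale(self):
        """2500 training frames, 2500 + 2500 test frames by default."""
        sig = inspect.signature(run_fixed_experiment)
        assert sig.parameters["n_train"].default == 2500
        assert sig.parameters["n_test_obstructed"].default == 2500
        assert sig.parameters["n_test_clean"].default == 2500
        assert sig.parameters["n0"].default == 400
        assert sig.parameters["concentration"].default == 2.0
        assert sig.parameters["volume_range"].default[1] == pytest.approx(0.9)

    def test_fixed_experiment_rejects_empty_groups(self, fixture_volume):
        with pytest.raises(ValueError):
            run_fixed_experiment(fixture_volume, n_train=0,
                                 n_test_obstructed=1, n_test_clean=1)


@pytest.fixture(scope="module")
def micro_fixed(fixture_volume, attenuation, small_geometry):
    from shuntscope.detector import DetectorConfig

    cfg = DetectorConfig(matrix=64, pyramid_depth=1, features=(8, 16, 32),
                         batch_size=8, max_epochs=10, patience=10, seed=0)
    return run_fixed_experiment(
        fixture_volume, attenuation, small_geometry, n_train=24,
        n_test_obstructed=10, n_test_clean=10, detector_config=cfg,
        n_angles=24, seed=3)


class TestMicroExperiments:
    """Desk-scale end-to-end runs of both experiment harnesses."""

    def test_emits_full_threshold_curves(self, micro_fixed):
        curves = micro_fixed.report.curves
        assert len(curves) == len(default_threshold_grid())
        assert set(curves.columns) >= {"threshold", "mean_sensitivity",
                                       "mean_precision", "mean_dsc",
                                       "median_dsc", "fpr"}

    def test_per_volume_breakdown_covers_all_obstructed_frames(self,
                                                               micro_fixed):
        assert len(micro_fixed.per_volume) == 10
        assert (micro_fixed.per_volume["volume_mm3"] > 0).all()

    def test_monotone_curves_on_real_run(self, micro_fixed):
        curves = micro_fixed.report.curves
        assert np.all(np.diff(curves["mean_sensitivity"]) <= 1e-12)
        assert np.all(np.diff(curves["fpr"]) <= 1e-12)

    def test_sweep_micro_grid_bookkeeping(self, fixture_volume, attenuation,
                                          small_geometry):
        from shuntscope.detector import DetectorConfig

        cfg = DetectorConfig(matrix=64, pyramid_depth=1, features=(8, 16),
                             batch_size=8, max_epochs=4, patience=4, seed=0)
        res = run_sweep_experiment(
            fixture_volume, attenuation, small_geometry,
            volumes=(0.1, 0.9), concentrations=(0.5, 2.0), open_beam=(100, 400),
            n_per_cell=2, detector_config=cfg, n_angles=24, seed=1)
        assert res.n_train_frames == 16
        assert res.n_test_frames == 16
        assert len(res.table) == 8
        assert (res.table["n_frames"] == 2).all()
        cell = res.cell(0.9, 2.0, 400)
        assert 0.0 <= cell["median_dsc"] <= 1.0
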