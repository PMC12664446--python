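"""Segmentation metrics and the two simulation experiments.

Metrics follow the reference definitions, computed per obstructed frame
after thresholding the detector's probability map:

* sensitivity  = TP / (TP + FN)   (correct obstruction pixels / true ones)
* precision    = TP / (TP + FP)   (correct obstruction pixels / detected;
  called "specificity" in the reference wording)
* DSC          = 2 * sens * prec / (sens + prec)
* frame false-positive rate = fraction of obstruction-free frames with at
  least one suprathreshold pixel.

Two experiments are provided: a parameter sweep over obstruction size x
contrast concentration x open-beam counts with a detector trained on the
mixed-parameter training half, and a fixed-parameter experiment with
threshold-dependency curves and a per-volume DSC breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import DetectorConfig, build_model, predict_batch, train
from .materials import AttenuationTable
from .phantom import MaterialVolume
from .projector import FrameSimulator, ProjectionGeometry
from .scene import OBSTRUCTION_VOLUME_RANGE

__all__ = ["FrameScore", "MetricsReport", "score_frame", "aggregate",
           "default_threshold_grid", "run_fixed_experiment",
           "run_sweep_experiment", "FixedExperimentResult", "SweepResult",
           "desk_detector_schedule", "DEFAULT_SWEEP_VOLUMES",
           "DEFAULT_SWEEP_CONCENTRATIONS", "DEFAULT_SWEEP_OPEN_BEAM"]

# default 5-value grids for the parameter sweep, spanning the studied ranges
DEFAULT_SWEEP_VOLUMES = (0.05, 0.1, 0.2, 0.45, 0.9)          # mm^3
DEFAULT_SWEEP_CONCENTRATIONS = (0.25, 0.5, 1.0, 2.0, 4.0)    # mmol/ml
DEFAULT_SWEEP_OPEN_BEAM = (50, 100, 200, 400, 800)           # counts


def desk_detector_schedule(seed: int = 0,
                           width: int = 16,
                           epochs_a: int = 120,
                           epochs_b: int = 18) -> tuple[DetectorConfig, ...]:
    """Two-phase CPU training schedule for the single-scale detector.

    Phase A learns the representation on 32-px obstruction-biased crops;
    phase B recalibrates the detection prior on 64-px crops with a
    near-natural positive fraction at a reduced Adam rate.  See
    docs/methods.md for the sizing rationale.
    """
    features = (width, width, 2 * width, 2 * width, 4 * width)
    common = dict(pyramid_depth=1, features=features, patience=10 ** 6,
                  seed=seed)
    return (DetectorConfig(crop_size=32, crop_positive_frac=0.5,
                           max_epochs=epochs_a, **common),
            DetectorConfig(crop_size=64, crop_positive_frac=0.2,
                           max_epochs=epochs_b, lr=2.5e-4, **common))


@dataclass(frozen=True)
class FrameScore:
    """Pixel confusion counts and derived metrics for one frame."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    dsc: float
    threshold: float
    obstruction_volume_mm3: float = float("nan")
    degenerate: bool = False


def score_frame(prob: np.ndarray, truth: np.ndarray, threshold: float,
                obstruction_volume_mm3: float = float("nan")) -> FrameScore:
    """Binarize ``prob`` at >= threshold and score against the truth mask.

    On an obstructed frame with no detected pixel (TP + FP = 0) the
    precision is undefined; the frame is flagged degenerate and scored
    conservatively with precision = DSC = 0.
    """
    if prob.shape != truth.shape:
        raise ValueError("probability map and truth mask shapes differ")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    pred = prob >= threshold
    t = truth.astype(bool)
    tp = int(np.count_nonzero(pred & t))
    fp = int(np.count_nonzero(pred & ~t))
    fn = int(np.count_nonzero(~pred & t))
    sens = tp / (tp + fn) if tp + fn else 0.0
    degenerate = (tp + fp == 0) and bool(t.any())
    prec = tp / (tp + fp) if tp + fp else 0.0
    dsc = 2 * sens * prec / (sens + prec) if sens + prec else 0.0
    return FrameScore(tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec,
                      dsc=dsc, threshold=threshold,
                      obstruction_volume_mm3=obstruction_volume_mm3,
                      degenerate=degenerate)


def default_threshold_grid() -> np.ndarray:
    """0.05 to 0.95 in steps of 0.05 (always contains 0.5)."""
    return np.round(np.arange(1, 20) * 0.05, 2)


@dataclass
class MetricsReport:
    """Per-threshold aggregates plus per-frame detail.

    ``curves`` has one row per threshold with columns mean/median
    sensitivity, precision and DSC over obstructed frames and the
    frame-level false-positive rate over clean frames.  ``frames`` holds
    the per-frame scores of the obstructed group at every threshold.
    """

    curves: pd.DataFrame
    frames: pd.DataFrame
    n_obstructed: int
    n_clean: int

    def at_threshold(self, threshold: float) -> pd.Series:
        idx = (self.curves["threshold"] - threshold).abs().idxmin()
        row = self.curves.loc[idx]
        if abs(row["threshold"] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not in the grid")
        return row

    def save(self, curves_csv, frames_csv=None, aggregates_json=None) -> None:
        self.curves.to_csv(curves_csv, index=False)
        if frames_csv is not None:
            self.frames.to_csv(frames_csv, index=False)
        if aggregates_json is not None:
            import json
            from pathlib import Path

            payload = {
                "n_obstructed": self.n_obstructed,
                "n_clean": self.n_clean,
                "thresholds": self.curves.to_dict(orient="records"),
            }
            Path(aggregates_json).write_text(json.dumps(payload, indent=2))


def aggregate(obstructed_probs: np.ndarray, truth_masks: np.ndarray,
              clean_probs: np.ndarray,
              thresholds: np.ndarray | None = None,
              obstruction_volumes: np.ndarray | None = None) -> MetricsReport:
    """Score both test groups over a threshold grid.

    ``obstructed_probs``/``truth_masks``: (n, H, W) detector outputs and
    ground-truth masks for obstructed frames; ``clean_probs``: (m, H, W)
    outputs on obstruction-free frames.
    """
    if len(obstructed_probs) == 0 or len(clean_probs) == 0:
        raise ValueError("need at least one frame in each test group")
    thresholds = default_threshold_grid() if thresholds is None \
        else np.asarray(thresholds, dtype=float)
    if obstruction_volumes is None:
        obstruction_volumes = np.full(len(obstructed_probs), np.nan)

    frame_rows = []
    curve_rows = []
    clean_max = np.asarray([p.max() for p in clean_probs])
    for thr in thresholds:
        scores = [score_frame(p, m, thr, v) for p, m, v in
                  zip(obstructed_probs, truth_masks, obstruction_volumes)]
        for i, s in enumerate(scores):
            frame_rows.append({"frame": i, "threshold": thr, "tp": s.tp,
                               "fp": s.fp, "fn": s.fn,
                               "sensitivity": s.sensitivity,
                               "precision": s.precision, "dsc": s.dsc,
                               "volume_mm3": s.obstruction_volume_mm3,
                               "degenerate": s.degenerate})
        sens = np.array([s.sensitivity for s in scores])
        dsc = np.array([s.dsc for s in scores])
        # precision (TP / detected) is a 0/0 form on frames without any
        # detection, so those frames cannot contribute to its average;
        # sensitivity and DSC still count them (as 0) on every frame
        prec_def = np.array([s.precision for s in scores if not s.degenerate])
        fpr = float(np.mean(clean_max >= thr))
        curve_rows.append({
            "threshold": thr,
            "mean_sensitivity": sens.mean(),
            "median_sensitivity": float(np.median(sens)),
            "mean_precision": float(prec_def.mean()) if len(prec_def) else 0.0,
            "median_precision": float(np.median(prec_def)) if len(prec_def) else 0.0,
            "mean_dsc": dsc.mean(),
            "median_dsc": float(np.median(dsc)),
            "fpr": fpr,
            "n_degenerate": int(sum(s.degenerate for s in scores)),
        })
    return MetricsReport(curves=pd.DataFrame(curve_rows),
                         frames=pd.DataFrame(frame_rows),
                         n_obstructed=len(obstructed_probs),
                         n_clean=len(clean_probs))


# ------------------------------------------------------------- experiments

def _as_schedule(detector_config) -> tuple[DetectorConfig, ...]:
    """Normalize a config or a sequence of phase configs to a tuple."""
    if detector_config is None:
        return (DetectorConfig(),)
    if isinstance(detector_config, DetectorConfig):
        return (detector_config,)
    return tuple(detector_config)


def _generate_group(sim: FrameSimulator, rng: np.random.Generator, n: int,
                    n0: int | np.ndarray, concentration: float | np.ndarray,
                    volumes: np.ndarray | None):
    """Simulate n frames; returns (images counts/N0, masks, volumes_mm3)."""
    images = np.empty((n, sim.geometry.rows, sim.geometry.cols),
                      dtype=np.float32)
    masks = np.zeros_like(images, dtype=bool)
    vols = np.zeros(n)
    n0s = np.broadcast_to(np.asarray(n0), (n,))
    concs = np.broadcast_to(np.asarray(concentration, dtype=float), (n,))
    for i in range(n):
        target = None if volumes is None else float(volumes[i])
        rad, mask, scene = sim.render(rng, int(n0s[i]), float(concs[i]),
                                      target, frame_index=i)
        images[i] = rad.counts / rad.n0
        masks[i] = mask.mask
        vols[i] = scene.obstruction_volume_mm3
    return images, masks, vols


@dataclass
class FixedExperimentResult:
    """Output of the fixed-parameter experiment."""

    report: MetricsReport
    model: object
    loss_trace: list[float]
    n_train: int
    config: DetectorConfig
    per_volume: pd.DataFrame = field(default_factory=pd.DataFrame)

    def dsc_by_volume(self, threshold: float = 0.5) -> pd.DataFrame:
        sel = self.report.frames
        sel = sel[np.isclose(sel["threshold"], threshold)]
        return sel[["frame", "volume_mm3", "dsc"]].reset_index(drop=True)


def run_fixed_experiment(volume: MaterialVolume,
                         attenuation: AttenuationTable | None = None,
                         geometry: ProjectionGeometry | None = None,
                         n_train: int = 2500,
                         n_test_obstructed: int = 2500,
                         n_test_clean: int = 2500,
                         n0: int = 400,
                         concentration: float = 2.0,
                         volume_range: tuple[float, float] = OBSTRUCTION_VOLUME_RANGE,
                         detector_config: DetectorConfig | None = None,
                         thresholds: np.ndarray | None = None,
                         n_angles: int = 180,
                         seed: int = 0) -> FixedExperimentResult:
    """Train at fixed N0/concentration and evaluate threshold curves.

    The reference-scale invocation uses 2500 training and 2500 + 2500 test
    frames; smaller counts give a desk-scale run of the same experiment.
    Training frames all carry one obstruction with volume drawn uniformly
    over ``volume_range``; the test set is split into obstructed and clean
    groups.  Deterministic for a fixed seed.
    """
    if min(n_train, n_test_obstructed, n_test_clean) < 1:
        raise ValueError("all frame counts must be >= 1")
    attenuation = attenuation or AttenuationTable()
    geometry = geometry or ProjectionGeometry.ml_default()
    schedule = _as_schedule(detector_config)
    cfg = schedule[0]
    sim = FrameSimulator(volume, attenuation, geometry, n_angles=n_angles)

    rng_train = np.random.default_rng([seed, 1])
    rng_test = np.random.default_rng([seed, 2])
    lo, hi = volume_range
    train_vols = rng_train.uniform(lo, hi, n_train)
    x_train, y_train, _ = _generate_group(sim, rng_train, n_train, n0,
                                          concentration, train_vols)
    test_vols = rng_test.uniform(lo, hi, n_test_obstructed)
    x_obs, y_obs, v_obs = _generate_group(sim, rng_test, n_test_obstructed,
                                          n0, concentration, test_vols)
    x_clean, _, _ = _generate_group(sim, rng_test, n_test_clean, n0,
                                    concentration, None)

    model = build_model(cfg)
    trace = []
    for phase_cfg in schedule:
        trace += train(model, x_train, y_train.astype(np.float32), phase_cfg)
    model.loss_trace = trace
    p_obs = predict_batch(model, x_obs)
    p_clean = predict_batch(model, x_clean)
    report = aggregate(p_obs, y_obs, p_clean, thresholds,
                       obstruction_volumes=v_obs)

    by_vol = report.frames[np.isclose(report.frames["threshold"], 0.5)]
    per_volume = by_vol[["frame", "volume_mm3", "dsc", "sensitivity",
                         "precision"]].reset_index(drop=True)
    return FixedExperimentResult(report=report, model=model, loss_trace=trace,
                                 n_train=n_train, config=cfg,
                                 per_volume=per_volume)


@dataclass
class SweepResult:
    """Per-cell medians of the size x concentration x statistics sweep."""

    table: pd.DataFrame
    n_train_frames: int
    n_test_frames: int
    config: DetectorConfig

    def cell(self, volume: float, concentration: float, n0: int) -> pd.Series:
        t = self.table
        sel = t[np.isclose(t["volume_mm3"], volume)
                & np.isclose(t["concentration"], concentration)
                & (t["n0"] == n0)]
        return sel.iloc[0]


def run_sweep_experiment(volume: MaterialVolume,
                         attenuation: AttenuationTable | None = None,
                         geometry: ProjectionGeometry | None = None,
                         volumes: tuple = DEFAULT_SWEEP_VOLUMES,
                         concentrations: tuple = DEFAULT_SWEEP_CONCENTRATIONS,
                         open_beam: tuple = DEFAULT_SWEEP_OPEN_BEAM,
                         n_per_cell: int = 10,
                         detector_config: DetectorConfig | None = None,
                         threshold: float = 0.5,
                         n_angles: int = 180,
                         seed: int = 0) -> SweepResult:
    """Parameter-dependency sweep with a mixed-parameter training set.

    Each cell of the size x concentration x open-beam grid contributes
    ``n_per_cell`` training and ``n_per_cell`` test projections (the
    default 5 x 5 x 5 grid with 10 per cell gives the 1250-projection
    train and test sets).  One detector is trained on the mixed training
    set; the table reports per-cell median/mean DSC at the given threshold.
    """
    attenuation = attenuation or AttenuationTable()
    geometry = geometry or ProjectionGeometry.ml_default()
    schedule = _as_schedule(detector_config)
    cfg = schedule[0]
    sim = FrameSimulator(volume, attenuation, geometry, n_angles=n_angles)

    cells = [(v, c, n) for v in volumes for c in concentrations
             for n in open_beam]
    rng_train = np.random.default_rng([seed, 11])
    rng_test = np.random.default_rng([seed, 12])

    vols = np.repeat([c[0] for c in cells], n_per_cell)
    concs = np.repeat([c[1] for c in cells], n_per_cell)
    n0s = np.repeat([c[2] for c in cells], n_per_cell).astype(int)
    n_total = len(cells) * n_per_cell

    x_tr, y_tr, _ = _generate_group(sim, rng_train, n_total, n0s, concs, vols)
    x_te, y_te, v_te = _generate_group(sim, rng_test, n_total, n0s, concs, vols)

    model = build_model(cfg)
    for phase_cfg in schedule:
        train(model, x_tr, y_tr.astype(np.float32), phase_cfg)
    probs = predict_batch(model, x_te)

    rows = []
    for ci, (v, c, n0) in enumerate(cells):
        sl = slice(ci * n_per_cell, (ci + 1) * n_per_cell)
        scores = [score_frame(p, m, threshold, vol) for p, m, vol in
                  zip(probs[sl], y_te[sl], v_te[sl])]
        dsc = np.array([s.dsc for s in scores])
        rows.append({"volume_mm3": v, "concentration": c, "n0": n0,
                     "median_dsc": float(np.median(dsc)),
                     "mean_dsc": float(dsc.mean()),
                     "n_frames": len(scores)})
    return SweepResult(table=pd.DataFrame(rows), n_train_frames=n_total,
                       n_test_frames=n_total, config=cfg)
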