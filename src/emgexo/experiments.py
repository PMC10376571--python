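"""End-to-end study runners: gesture classification, reference tracking,
and EMG-driven fatigue compensation.

Each runner wires the pipeline stages together — synthetic acquisition →
segmentation → features → normalization → models → control — and returns
a :class:`ScenarioReport` whose metrics are all recomputable from the
logged artifacts.  All randomness flows from a single top-level seed,
split deterministically per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, fatigue, fuzzy, gestures, mpc, synth
from .plant import PlantConfig

logger = logging.getLogger("emgexo")

TRACKING_SPEEDS_MM_S = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**31


@dataclass
class ScenarioReport:
    scenario: str
    seed: int
    configs: dict
    metrics: dict
    artifacts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Gesture classification study
# ---------------------------------------------------------------------------

def run_gesture_study(
    protocol: synth.AcquisitionProtocol | None = None,
    train_config: gestures.TrainConfig | None = None,
    model_kinds: tuple[str, ...] = gestures.MODEL_KINDS,
    out_dir: str | Path | None = None,
) -> ScenarioReport:
    """Generate the gesture dataset, extract 40-feature vectors from the
    whole-repetition windows, normalize (fit on train only), split 70/30,
    tune/train the classifiers and report confusion-matrix metrics."""
    protocol = protocol or synth.AcquisitionProtocol()
    train_config = train_config or gestures.TrainConfig(
        seed=_stage_seed(protocol.seed, "split")
    )
    logger.info("generating %d recordings", protocol.n_total)
    recordings = synth.generate_gesture_dataset(protocol)

    spec = synth.SegmentationSpec(window_s=protocol.rep_duration_s, overlap_frac=0.0)
    X, y = [], []
    for rec in recordings:
        for window in synth.segment(rec, spec):
            X.append(features.extract_gesture_features(window))
            y.append(rec.gesture)
    X = np.asarray(X)
    y = np.asarray(y)

    X_tr, X_te, y_tr, y_te = gestures.split_dataset(X, y, train_config)
    X_tr_n, params = features.minmax_normalize(X_tr)
    X_te_n, _ = features.minmax_normalize(X_te, params)

    metrics: dict = {
        "n_observations": int(len(y)),
        "per_gesture_counts": {
            str(g): int(c) for g, c in zip(*np.unique(y, return_counts=True))
        },
        "train_per_gesture": {
            str(g): int(c) for g, c in zip(*np.unique(y_tr, return_counts=True))
        },
        "models": {},
    }
    artifacts: dict = {}
    for kind in model_kinds:
        logger.info("tuning %s", kind)
        model, cv = gestures.tune_and_train(kind, X_tr_n, y_tr, train_config)
        cm, report = gestures.evaluate(model, X_te_n, y_te, labels=sorted(set(y)))
        metrics["models"][kind] = {
            "cv_mean_accuracy": cv.mean_accuracy,
            "cv_std_accuracy": cv.std_accuracy,
            "cv_min_accuracy": cv.min_accuracy,
            "best_params": {k: str(v) for k, v in cv.best_params.items()},
            "test": report.to_dict(),
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                cm.counts, index=cm.labels, columns=cm.labels
            ).to_csv(out_dir / f"confusion_{kind}.csv")
            artifacts[f"confusion_{kind}"] = str(out_dir / f"confusion_{kind}.csv")
            import joblib

            joblib.dump(model, out_dir / f"model_{kind}.joblib")
            artifacts[f"model_{kind}"] = str(out_dir / f"model_{kind}.joblib")

    report = ScenarioReport(
        scenario="gesture_study",
        seed=protocol.seed,
        configs={
            "protocol": asdict(protocol),
            "train": {
                "test_fraction": train_config.test_fraction,
                "cv_folds": train_config.cv_folds,
                "seed": train_config.seed,
            },
        },
        metrics=metrics,
        artifacts=artifacts,
    )
    if out_dir is not None:
        report.to_json(Path(out_dir) / "gesture_study.json")
    return report


# ---------------------------------------------------------------------------
# Reference-tracking study (ramp flexion/extension sweep)
# ---------------------------------------------------------------------------

def run_tracking_study(
    speeds_mm_s: tuple[float, ...] = TRACKING_SPEEDS_MM_S,
    cycles: int = 7,
    cycle_period_s: float = 4.0,
    plant_config: PlantConfig | None = None,
    mpc_config: mpc.MpcConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Closed-loop ramp tracking (therapy priority) for each peak speed.

    Returns one row per speed with position and velocity MSE in controller
    units (m², (m/s)²) over ``cycles`` opening/closing cycles.
    """
    plant_config = plant_config or PlantConfig()
    mpc_config = mpc_config or mpc.MpcConfig()
    rows = []
    for speed in speeds_mm_s:
        ref = mpc.ramp_reference(
            speed, cycles=cycles, cycle_period_s=cycle_period_s, ts=mpc_config.ts
        )
        bundle = mpc.ReferenceBundle(ts=mpc_config.ts, therapy_v=ref, priority="therapy")
        log, metrics = mpc.run_closed_loop(plant_config, mpc_config, bundle)
        rows.append(
            {
                "speed_mm_s": speed,
                "mse_position": metrics["mse_position"],
                "mse_velocity": metrics["mse_velocity"],
            }
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            log.to_csv(out_dir / f"tracking_{speed:g}mm_s.csv", index=False)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "tracking_mse.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# Fatigue compensation study
# ---------------------------------------------------------------------------

def _fatigue_training_windows(
    seed: int,
    n_per_level: int = 100,
    duration_s: float = 5.0,
    fs: float = synth.DEFAULT_FS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled ψ matrix for detector training plus the rest baseline."""
    rest = synth.generate_rest_recording(duration_s=5.0, seed=seed)
    baseline = np.sqrt(np.mean(rest.samples**2, axis=1))
    spec = synth.SegmentationSpec(window_s=1.0, overlap_frac=0.3)
    psi, labels = [], []
    rng = np.random.default_rng(seed)
    for level in fatigue.LEVELS:
        count = 0
        while count < n_per_level:
            rec = synth.generate_fatigue_recording(
                level, duration_s=duration_s, seed=int(rng.integers(2**31))
            )
            for window in synth.segment(rec, spec):
                psi.append(features.extract_fatigue_features(window, baseline, fs))
                labels.append(level)
                count += 1
                if count >= n_per_level:
                    break
    return np.asarray(psi), np.asarray(labels), baseline


def run_fatigue_compensation_study(
    reference_kind: str = "pwm",
    seed: int = 0,
    amplitude_mm_s: float = 5.0,
    duration_s: float = 10.4,
    plant_config: PlantConfig | None = None,
    mpc_config: mpc.MpcConfig | None = None,
    out_dir: str | Path | None = None,
) -> ScenarioReport:
    """Full fatigue-compensation pipeline.

    Generates a fatigue progression (levels 1 → 2 → 3), scores its 1 s /
    30 %-overlap windows with freshly trained level detectors, integrates
    the fuzzy assistance velocity, and runs the EMG-priority closed loop
    against the chosen therapy reference (ramp or PWM).  Reports MSE/RMSE
    and per-phase correlations between the MPC command and the EMG-derived
    assistance reference.
    """
    if reference_kind not in ("ramp", "pwm"):
        raise ValueError(f"unknown reference kind {reference_kind!r}")
    plant_config = plant_config or PlantConfig()
    # the assistance channel may legitimately exceed the nominal band; keep
    # the soft-constraint penalty low so the compensation can develop
    mpc_config = mpc_config or mpc.MpcConfig(slack_penalty=0.01)

    psi, labels, baseline = _fatigue_training_windows(_stage_seed(seed, "fatigue-train"))
    psi_std = features.zscore(psi, axis=0)
    mu, sd = psi.mean(axis=0), psi.std(axis=0)
    bank = fatigue.train_level_detectors(
        psi_std, labels, fatigue.AnnSpec(seed=_stage_seed(seed, "ann"))
    )

    # fatigue progression trace: one third of the duration per level
    fs = synth.DEFAULT_FS
    seg = synth.SegmentationSpec(window_s=1.0, overlap_frac=0.3)
    third = duration_s / 3.0
    parts = [
        synth.generate_fatigue_recording(
            lv, duration_s=third, seed=_stage_seed(seed, f"trace-{lv}")
        ).samples
        for lv in fatigue.LEVELS
    ]
    trace = synth.EmgRecording(samples=np.concatenate(parts, axis=1), fs=fs)
    windows = synth.segment(trace, seg)
    psi_trace = np.asarray(
        [features.extract_fatigue_features(w, baseline, fs) for w in windows]
    )
    psi_trace = np.divide(
        psi_trace - mu, sd, out=np.zeros_like(psi_trace), where=sd > 0
    )
    scores = bank.scores(psi_trace)

    rulebase = fuzzy.build_rulebase()
    window_dt = seg.window_s * (1.0 - seg.overlap_frac)
    emg_v_windows = fuzzy.simulate_velocity(rulebase, scores, v0=0.0, dt=window_dt)

    ts = mpc_config.ts
    if reference_kind == "pwm":
        therapy = mpc.pwm_reference(amplitude_mm_s, duration_s=duration_s, ts=ts)
    else:
        therapy = mpc.ramp_reference(
            amplitude_mm_s, cycles=max(int(duration_s // 4), 1), ts=ts
        )
    n = therapy.size
    # zero-order hold of the fuzzy command between window updates, signed by
    # the therapy phase so assistance follows the flexion/extension direction
    idx = np.minimum((np.arange(n) * ts / window_dt).astype(int), len(emg_v_windows) - 1)
    emg_v = emg_v_windows[idx] * np.sign(np.where(therapy == 0, 1.0, therapy))
    bundle = mpc.ReferenceBundle(
        ts=ts, therapy_v=therapy, emg_v=emg_v, priority="emg"
    )
    log, metrics = mpc.run_closed_loop(plant_config, mpc_config, bundle)
    metrics = dict(metrics)
    metrics["rmse_position"] = float(np.sqrt(metrics["mse_position"]))
    metrics["fuzzy_rule_count"] = rulebase.rule_count
    metrics["detector_nmse"] = {str(k): v for k, v in bank.nmse_per_level.items()}

    report = ScenarioReport(
        scenario=f"fatigue_compensation_{reference_kind}",
        seed=seed,
        configs={
            "reference_kind": reference_kind,
            "amplitude_mm_s": amplitude_mm_s,
            "duration_s": duration_s,
            "mpc": asdict(mpc_config),
            "plant": asdict(plant_config),
        },
        metrics=metrics,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log.to_csv(out_dir / "fatigue_compensation.csv", index=False)
        report.artifacts["trajectory"] = str(out_dir / "fatigue_compensation.csv")
        report.to_json(out_dir / "fatigue_compensation.json")
    return report
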