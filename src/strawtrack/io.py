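"""CSV schemas, readers/writers and the end-to-end pipeline runner.

Schemas (comma-separated, UTF-8, '.' decimal, ISO-8601 timestamps with an
explicit offset):

* ``detections.csv`` — timestamp, pig_id, receiver_id, rssi_dbm
* ``calibration.csv`` — distance_m, rssi_dbm
* ``env.csv`` — timestamp, temp_c, rh_pct, pm1, pm25, pm10
* ``hourly.csv`` — pig_id, day, hour, dist_cm_per_h, n_detections, valid

Movement is serialized at one decimal place (cm/h); every writer/reader
pair round-trips losslessly at its declared precision.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import sensor, synthetic
from .config import PipelineConfig
from .env import aggregate_env, fit_env_model, movement_to_blocks, pm_screen
from .lmm import MovementLMM
from .sensor import PathLossModel, aggregate_hourly, analysis_table, fit_path_loss
from .synthetic import (
    BarnGeometry,
    DiurnalProfile,
    EnvTruth,
    GenerativeTruth,
    simulate_detections,
    simulate_env,
    simulate_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_detections",
    "write_detections",
    "read_calibration",
    "write_calibration",
    "read_env",
    "write_env",
    "read_hourly",
    "write_hourly",
    "run_pipeline",
]

DETECTION_COLUMNS = ["timestamp", "pig_id", "receiver_id", "rssi_dbm"]
ENV_COLUMNS = ["timestamp", "temp_c", "rh_pct", "pm1", "pm25", "pm10"]
HOURLY_COLUMNS = ["pig_id", "day", "hour", "dist_cm_per_h", "n_detections", "valid"]


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_detections(path) -> pd.DataFrame:
    """Read and validate a detection log; malformed rows are counted and
    skipped with a warning, rows are sorted per pig by timestamp."""
    df = pd.read_csv(path, dtype={"pig_id": str, "receiver_id": str})
    _require_columns(df, DETECTION_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    rssi = pd.to_numeric(df["rssi_dbm"], errors="coerce")
    bad = ts.isna() | rssi.isna()
    if bad.any():
        logger.warning("read_detections: skipped %d malformed rows", int(bad.sum()))
    out = df.loc[~bad].copy()
    out["timestamp"] = ts[~bad]
    out["rssi_dbm"] = rssi[~bad]
    out = out.sort_values(["pig_id", "timestamp"], kind="stable").reset_index(drop=True)
    logger.info("read_detections: %d events from %s", len(out), path)
    return out


def write_detections(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )
    out[DETECTION_COLUMNS].to_csv(path, index=False, float_format="%.2f")


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["distance_m", "rssi_dbm"], path)
    return df


def write_calibration(df: pd.DataFrame, path) -> None:
    df[["distance_m", "rssi_dbm"]].to_csv(path, index=False, float_format="%.4f")


def read_env(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ENV_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def write_env(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out[ENV_COLUMNS].to_csv(path, index=False, float_format="%.4f")


def read_hourly(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HOURLY_COLUMNS, path)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_hourly(df: pd.DataFrame, path) -> None:
    out = df[HOURLY_COLUMNS].copy()
    out["dist_cm_per_h"] = out["dist_cm_per_h"].round(1)
    out.to_csv(path, index=False, float_format="%.1f")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _tz(config: PipelineConfig) -> dt.timezone:
    return dt.timezone(dt.timedelta(hours=config.tz_offset_hours))


def _truth_from_config(config: PipelineConfig) -> GenerativeTruth:
    t = config.truth
    diurnal = DiurnalProfile.cosine_anchored(
        peak_hour=t.diurnal_peak_hour,
        trough_hour=t.diurnal_trough_hour,
        peak=t.diurnal_peak,
        trough=t.diurnal_trough,
    )
    rng = np.random.default_rng(config.child_seed("day-effects"))
    day_eff = rng.normal(0.0, t.day_effect_sd, config.n_days)
    if t.day_effect_sd > 0:
        day_eff -= day_eff.mean()
    return GenerativeTruth(
        grand_mean=float(diurnal.values.mean()),
        day_effects=tuple(day_eff),
        diurnal=diurnal,
        interaction_amplitude=t.interaction_amplitude,
        sigma2_pig=t.sigma2_pig,
        sigma2_res=t.sigma2_res,
        rho=t.rho,
        seed=config.child_seed("truth"),
    )


def simulate_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Generate calibration.csv, detections.csv and env.csv."""
    geometry = BarnGeometry()
    radio = config.radio
    truth = _truth_from_config(config)
    model = PathLossModel(radio.tx_power, radio.n)
    tz = _tz(config)
    start = dt.datetime.combine(config.study_start, dt.time(0), tzinfo=tz)

    # calibration records: replicated known distances with RSSI noise
    rng = np.random.default_rng(config.child_seed("calibration"))
    dists = np.repeat(radio.calibration_distances, radio.calibration_replicates)
    rssi = (
        radio.tx_power
        - 10.0 * radio.n * np.log10(dists)
        + rng.normal(0.0, radio.rssi_noise_sd, dists.size)
    )
    calib = pd.DataFrame({"distance_m": dists, "rssi_dbm": rssi})
    write_calibration(calib, out_dir / "calibration.csv")

    # per-pig trajectories -> detections
    rng = np.random.default_rng(config.child_seed("trajectories"))
    baselines = np.exp(rng.normal(0.0, config.pig_baseline_cv, config.n_pigs))
    frames = []
    for i in range(config.n_pigs):
        pig = f"ET{i + 1:05d}"
        for day in range(1, config.n_days + 1):
            traj = simulate_trajectory(baselines[i], truth, geometry, day, rng)
            t_s, det_rssi = simulate_detections(
                traj, model, geometry, radio.rssi_noise_sd, radio.dropout_prob,
                rng, min_distance=radio.min_distance,
            )
            ts = (
                pd.Timestamp(start)
                + pd.to_timedelta((day - 1) * 86_400 + t_s, unit="s")
            )
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": ts,
                        "pig_id": pig,
                        "receiver_id": "RX01",
                        "rssi_dbm": det_rssi,
                    }
                )
            )
    detections = pd.concat(frames, ignore_index=True)
    detections = detections.sort_values(
        ["timestamp", "pig_id"], kind="stable"
    ).reset_index(drop=True)
    write_detections(detections, out_dir / "detections.csv")

    env_truth = EnvTruth(
        temp_mean=config.env.temp_mean,
        temp_sd=config.env.temp_sd,
        rh_mean=config.env.rh_mean,
        rh_sd=config.env.rh_sd,
        pm_base_mean=config.env.pm_base_mean,
        pm_cross_correlation=config.env.pm_cross_correlation,
        records_per_day=(config.env.records_per_day_min, config.env.records_per_day_max),
    )
    env = simulate_env(
        env_truth, config.n_days, np.random.default_rng(config.child_seed("env"))
    )
    env = env.assign(
        timestamp=pd.Timestamp(start)
        + pd.to_timedelta((env["day"] - 1) * 86_400 + env["time_s"], unit="s")
    )
    write_env(env, out_dir / "env.csv")
    logger.info(
        "simulate: %d detections, %d env records", len(detections), len(env)
    )
    return {"n_detections": len(detections), "n_env_records": len(env)}


def calibrate_stage(config: PipelineConfig, out_dir: Path) -> PathLossModel:
    calib = read_calibration(out_dir / "calibration.csv")
    model = fit_path_loss(
        sensor.CalibrationRecord(d, r)
        for d, r in zip(calib["distance_m"], calib["rssi_dbm"])
    )
    pd.DataFrame(
        {"tx_power": [model.tx_power], "n": [model.n], "resid_se": [model.resid_se]}
    ).to_csv(out_dir / "calibration_fit.csv", index=False, float_format="%.6f")
    return model


def movement_stage(config: PipelineConfig, out_dir: Path, model: PathLossModel):
    events = read_detections(out_dir / "detections.csv")
    start = dt.datetime.combine(config.study_start, dt.time(0), tzinfo=_tz(config))
    hourly = aggregate_hourly(events, model, start, n_days=config.n_days)
    write_hourly(hourly, out_dir / "hourly.csv")
    return hourly


def fit_lmm_stage(config: PipelineConfig, out_dir: Path) -> MovementLMM:
    hourly = read_hourly(out_dir / "hourly.csv")
    analysis = analysis_table(hourly)
    fit = MovementLMM(
        n_starts=config.analysis.n_starts, ci_level=config.analysis.ci_level
    ).fit(analysis)
    pd.concat([fit.lsmeans("hour"), fit.lsmeans("day")]).to_csv(
        out_dir / "lsmeans.csv", index=False, float_format="%.4f"
    )
    fit.blups().to_csv(out_dir / "blups.csv", index=False, float_format="%.4f")
    pd.concat([fit.type3(), fit.slice_tests().rename(columns={"day": "effect"})]).to_csv(
        out_dir / "type3.csv", index=False, float_format="%.6g"
    )
    vc = fit.vc_
    pd.DataFrame(
        {
            "sigma2_pig": [vc.sigma2_pig],
            "sigma2_res": [vc.sigma2_res],
            "rho": [vc.rho],
            "icc": [fit.icc_],
            "reml_neg2loglik": [fit.reml_value_],
        }
    ).to_csv(out_dir / "variance_components.csv", index=False, float_format="%.6f")
    return fit


def fit_env_stage(config: PipelineConfig, out_dir: Path):
    env = read_env(out_dir / "env.csv")
    start = dt.datetime.combine(config.study_start, dt.time(0), tzinfo=_tz(config))
    local = env["timestamp"].dt.tz_convert(_tz(config))
    records = env.assign(
        day=(local.dt.normalize() - pd.Timestamp(start)).dt.days + 1,
        time_s=local.dt.hour * 3600 + local.dt.minute * 60 + local.dt.second,
    )
    env_blocks = aggregate_env(records)
    env_blocks.to_csv(out_dir / "env_blocks.csv", index=False, float_format="%.4f")

    hourly = read_hourly(out_dir / "hourly.csv")
    blocks = movement_to_blocks(hourly)
    blocks.to_csv(out_dir / "movement_blocks.csv", index=False, float_format="%.4f")

    retained, report = pm_screen(env_blocks, config.analysis.r_threshold)
    report.to_csv(out_dir / "pm_screen.csv", index=False, float_format="%.4f")
    type3, fit = fit_env_model(
        blocks, env_blocks, retained=["temp_mean", "rh_mean", *retained],
        n_starts=config.analysis.n_starts,
    )
    type3.to_csv(out_dir / "env_type3.csv", index=False, float_format="%.6g")
    return type3, fit


def report_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Descriptive summary: hourly-movement statistics (mean, SE, min, max,
    IQR) and record-weighted environmental summaries."""
    hourly = read_hourly(out_dir / "hourly.csv")
    valid = hourly[hourly["valid"]]
    move = valid["dist_cm_per_h"]
    env_blocks = pd.read_csv(out_dir / "env_blocks.csv")
    w = env_blocks["n_records"]

    def wmean(col):
        return float(np.average(env_blocks[col], weights=w))

    report = {
        "possible_records": int(len(hourly)),
        "analyzed_records": int(len(valid)),
        "excluded_records": int(len(hourly) - len(valid)),
        "movement": {
            "n": int(move.size),
            "mean": float(move.mean()),
            "se": float(move.std(ddof=1) / np.sqrt(move.size)),
            "sd": float(move.std(ddof=1)),
            "min": float(move.min()),
            "max": float(move.max()),
            "iqr": [float(move.quantile(0.25)), float(move.quantile(0.75))],
        },
        "environment": {
            "n_blocks": int(len(env_blocks)),
            "n_records": int(w.sum()),
            "temp_mean": wmean("temp_mean"),
            "rh_mean": wmean("rh_mean"),
            "pm1_mean": wmean("pm1_mean"),
            "pm25_mean": wmean("pm25_mean"),
            "pm10_mean": wmean("pm10_mean"),
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> calibrate -> movement -> fit-lmm -> fit-env -> report.

    Any stage failure aborts with the stage name attached.  Returns a dict
    with the report and the fitted model objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage = "simulate"
    try:
        artifacts["simulate"] = simulate_stage(config, out_dir)
        stage = "calibrate"
        model = calibrate_stage(config, out_dir)
        artifacts["path_loss"] = model
        stage = "movement"
        movement_stage(config, out_dir, model)
        stage = "fit-lmm"
        artifacts["lmm"] = fit_lmm_stage(config, out_dir)
        stage = "fit-env"
        artifacts["env_type3"], artifacts["env_fit"] = fit_env_stage(config, out_dir)
        stage = "report"
        artifacts["report"] = report_stage(config, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete; outputs in %s", out_dir)
    return artifacts
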