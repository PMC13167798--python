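"""Calibration and movement-metric construction.

RSSI is converted to tag-to-receiver distance with the empirical
log-distance path-loss model

    distance = 10 ** ((tx_power - rssi) / (10 * n)),

where ``tx_power`` is the assumed received signal strength (dBm) at 1 m and
``n`` the path-loss exponent, both estimated from calibration records by
least squares.  Movement is the sum, within each clock hour, of absolute
changes in estimated distance between consecutive detections (reported in
cm/h); an hour with no detections cannot be positioned and is flagged
invalid rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationRecord",
    "PathLossModel",
    "PathLossRegressor",
    "fit_path_loss",
    "distance_from_rssi",
    "total_incremental_distance",
    "aggregate_hourly",
    "analysis_table",
    "coverage_summary",
]


@dataclass(frozen=True)
class CalibrationRecord:
    true_distance: float  # m
    rssi: float  # dBm

    def __post_init__(self):
        if self.true_distance <= 0:
            raise ValueError("true_distance must be > 0")


@dataclass(frozen=True)
class PathLossModel:
    """Log-distance propagation parameters: RSSI at 1 m and decay exponent."""

    tx_power: float  # dBm at the 1 m reference distance
    n: float  # path-loss exponent
    resid_se: float = float("nan")

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("path-loss exponent n must be > 0")


class PathLossRegressor(BaseEstimator, RegressorMixin):
    """Least-squares fit of the log-distance path-loss model.

    ``fit`` regresses measured RSSI on -10*log10(distance); the intercept is
    the 1 m reference power ``tx_power_`` and the slope the path-loss
    exponent ``n_``.  ``predict`` maps distances to expected RSSI and
    ``estimate_distance`` inverts the model.

    Parameters
    ----------
    plausibility_cap : float
        Distances above this (m) returned by ``estimate_distance`` are
        flagged in ``last_flagged_`` but never altered.
    """

    def __init__(self, plausibility_cap: float = 50.0):
        self.plausibility_cap = plausibility_cap

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        rssi = np.asarray(y, dtype=float).ravel()
        if d.size != rssi.size:
            raise ValueError("distance and rssi arrays must have equal length")
        if d.size < 2:
            raise ValueError("need at least 2 calibration records")
        if np.any(d <= 0):
            raise ValueError("calibration distances must be > 0")
        if np.unique(d).size < 2:
            raise ValueError(
                "path-loss model unidentifiable: all calibration distances "
                f"equal {d[0]} m; need >= 2 distinct distances"
            )
        A = np.column_stack([np.ones_like(d), -10.0 * np.log10(d)])
        coef, *_ = np.linalg.lstsq(A, rssi, rcond=None)
        self.tx_power_ = float(coef[0])
        self.n_ = float(coef[1])
        resid = rssi - A @ coef
        dof = max(d.size - 2, 1)
        self.resid_se_ = float(np.sqrt(resid @ resid / dof))
        self.n_obs_ = int(d.size)
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float)
        return self.tx_power_ - 10.0 * self.n_ * np.log10(d)

    def estimate_distance(self, rssi):
        model = self.model_
        dist = distance_from_rssi(rssi, model)
        self.last_flagged_ = np.asarray(dist) > self.plausibility_cap
        return dist

    @property
    def model_(self) -> PathLossModel:
        return PathLossModel(self.tx_power_, self.n_, self.resid_se_)


def fit_path_loss(records: Iterable[CalibrationRecord]) -> PathLossModel:
    """Fit (tx_power, n) from calibration records by least squares."""
    records = list(records)
    d = [r.true_distance for r in records]
    rssi = [r.rssi for r in records]
    est = PathLossRegressor().fit(d, rssi)
    logger.info(
        "fit_path_loss: tx_power=%.3f dBm, n=%.4f, resid SE=%.3f (%d records)",
        est.tx_power_, est.n_, est.resid_se_, est.n_obs_,
    )
    return est.model_


def distance_from_rssi(rssi, model: PathLossModel):
    """Invert the path-loss model: 10**((tx_power - rssi)/(10*n)), metres."""
    rssi = np.asarray(rssi, dtype=float)
    out = 10.0 ** ((model.tx_power - rssi) / (10.0 * model.n))
    return float(out) if out.ndim == 0 else out


def total_incremental_distance(distances: Sequence[float]) -> float:
    """Sum of absolute changes between consecutive distance estimates.

    E.g. 4 m -> 2 m -> 5 m is |2-4| + |5-2| = 5 m moved.  Length <= 1 gives 0.
    """
    d = np.asarray(distances, dtype=float)
    if d.size <= 1:
        return 0.0
    return float(np.sum(np.abs(np.diff(d))))


def aggregate_hourly(
    events: pd.DataFrame,
    model: PathLossModel,
    study_start,
    n_days: int = 20,
    receiver_id=None,
) -> pd.DataFrame:
    """Turn a detection stream into the hourly movement response.

    ``events`` needs columns timestamp, pig_id, receiver_id, rssi_dbm; rows
    are sorted per pig by timestamp.  Each consecutive-pair increment
    |d_k+1 - d_k| is credited to the pig/day/clock-hour of the *later*
    detection (increments may cross hour and midnight boundaries).  Sums are
    converted m -> cm.  The output covers the full pig x day x hour grid of
    the pigs present; an hour is valid iff at least one detection falls in
    it, and invalid hours carry NaN movement.

    Events outside days 1..n_days (day 1 starts at ``study_start``) are
    dropped with a warning count, as are events from receivers other than
    the single expected one (``receiver_id``; defaults to the most frequent).
    """
    required = {"timestamp", "pig_id", "receiver_id", "rssi_dbm"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events missing required columns: {sorted(missing)}")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])

    if receiver_id is None and len(ev):
        receiver_id = ev["receiver_id"].mode().iloc[0]
    foreign = ev["receiver_id"] != receiver_id
    if foreign.any():
        logger.warning(
            "aggregate_hourly: dropped %d events from other receivers "
            "(expected %r)", int(foreign.sum()), receiver_id,
        )
        ev = ev[~foreign]

    start = pd.Timestamp(study_start)
    if len(ev) and ev["timestamp"].dt.tz is not None:
        if start.tz is None:
            start = start.tz_localize(ev["timestamp"].dt.tz)
        else:
            # days and hours are labelled in the study's local time
            ev["timestamp"] = ev["timestamp"].dt.tz_convert(start.tz)
    day = (ev["timestamp"].dt.normalize() - start.normalize()).dt.days + 1
    out_of_window = (day < 1) | (day > n_days)
    if out_of_window.any():
        logger.warning(
            "aggregate_hourly: dropped %d events outside days 1..%d",
            int(out_of_window.sum()), n_days,
        )
        ev = ev[~out_of_window]
        day = day[~out_of_window]

    ev = ev.assign(day=day, hour=ev["timestamp"].dt.hour)
    # stable sort keeps duplicate timestamps in ingestion order
    ev = ev.sort_values(["pig_id", "timestamp"], kind="stable").reset_index(drop=True)
    ev["dist_m"] = distance_from_rssi(ev["rssi_dbm"].to_numpy(), model)

    pigs = sorted(ev["pig_id"].unique())
    grid = pd.MultiIndex.from_product(
        [pigs, np.arange(1, n_days + 1), np.arange(24)],
        names=["pig_id", "day", "hour"],
    )

    counts = ev.groupby(["pig_id", "day", "hour"]).size().reindex(grid, fill_value=0)

    # consecutive-pair increments within pig, credited to the later detection
    same_pig = ev["pig_id"].to_numpy()[1:] == ev["pig_id"].to_numpy()[:-1]
    inc = np.abs(np.diff(ev["dist_m"].to_numpy()))
    later = ev.iloc[1:]
    pairs = pd.DataFrame(
        {
            "pig_id": later["pig_id"].to_numpy(),
            "day": later["day"].to_numpy(),
            "hour": later["hour"].to_numpy(),
            "inc_m": np.where(same_pig, inc, np.nan),
        }
    ).dropna(subset=["inc_m"])
    sums = (
        pairs.groupby(["pig_id", "day", "hour"])["inc_m"].sum().reindex(grid, fill_value=0.0)
    )

    out = pd.DataFrame(index=grid).reset_index()
    valid = counts.to_numpy() > 0
    out["dist_cm_per_h"] = np.where(valid, sums.to_numpy() * 100.0, np.nan)
    out["n_detections"] = counts.to_numpy()
    out["valid"] = valid
    logger.info(
        "aggregate_hourly: %d pigs, %d events -> %d grid cells (%d valid)",
        len(pigs), len(ev), len(out), int(valid.sum()),
    )
    return out


def coverage_summary(hourly: pd.DataFrame) -> pd.DataFrame:
    """Per-pig counts of valid hourly observations (coverage report)."""
    g = hourly.groupby("pig_id")["valid"]
    return pd.DataFrame({"n_valid": g.sum().astype(int), "n_possible": g.size()})


def analysis_table(hourly: pd.DataFrame) -> pd.DataFrame:
    """Analysis-ready records: valid rows only, with coverage logged.

    Hours without valid positioning data reflect missing information, not
    confirmed inactivity, and are excluded from inference.
    """
    out = hourly[hourly["valid"].astype(bool)].reset_index(drop=True)
    cov = coverage_summary(hourly)
    logger.info(
        "analysis_table: retained %d of %d rows; per-pig coverage:\n%s",
        len(out), len(hourly), cov.to_string(),
    )
    if out.empty:
        logger.warning("analysis_table: no valid rows retained")
    return out
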