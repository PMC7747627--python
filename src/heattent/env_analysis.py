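"""Post-hoc reduction of tent environmental logs.

Treatment differentials, per-clock-hour temperature profiles, inter-sensor
uniformity metrics, vapor pressure deficit and CO2/RH summaries.  Log streams
are paired by exact timestamp (both are minute-aligned by construction); no
interpolation is performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .controller import ClockWindow, ControllerConfig, EnvLog

__all__ = [
    "saturation_vp_kPa",
    "vpd_kPa",
    "nightly_differential",
    "sensor_uniformity",
    "hourly_profile",
    "summarize_environment",
    "heater_rule_violations",
    "EnvSummary",
    "UniformityReport",
]

# Magnus form, FAO-56 constants (air temperature, tent-level sensors).
_MAGNUS_A = 0.6108
_MAGNUS_B = 17.27
_MAGNUS_C = 237.3


def saturation_vp_kPa(temp_C):
    """Saturation vapor pressure es(T) in kPa, Magnus form."""
    t = np.asarray(temp_C, dtype=float)
    es = _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))
    return float(es) if np.isscalar(temp_C) or es.ndim == 0 else es


def vpd_kPa(temp_C, rh_pct):
    """Vapor pressure deficit es(T) * (1 - RH/100) in kPa.

    RH outside [0, 100] raises ValueError.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("rh_pct must lie in [0, 100]")
    out = saturation_vp_kPa(temp_C) * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(rh_pct) and np.isscalar(temp_C) else out


@dataclass
class UniformityReport:
    """Inter-sensor spread of one tent's array, averaged over time.

    ``mean_pairwise_abs_diff_C`` is the primary statistic; ``mean_range_C``
    (time-averaged max-min) is reported alongside because the corresponding
    field summary statistic is ambiguous between the two readings.
    """

    mean_pairwise_abs_diff_C: float
    mean_range_C: float
    per_sensor_bias_C: Dict[str, float]
    n_timestamps: int


@dataclass
class EnvSummary:
    mean_diff_C: float
    mean_T_stress_C: float
    mean_T_control_C: float
    nightly_diff_C: pd.Series
    hourly_profile: Optional[pd.DataFrame] = None
    day_offset_C: Optional[Dict[str, float]] = None
    co2_stats: Optional[Dict[str, float]] = None
    rh_diff_pct: Optional[Dict[str, float]] = None


def _night_key(ts: pd.Timestamp):
    # Shift by 12 h so an evening and the following morning share one key.
    return (ts - pd.Timedelta(hours=12)).date()


def nightly_differential(
    log_stress: EnvLog,
    log_control: EnvLog,
    stress_window: Optional[ClockWindow] = None,
) -> Tuple[float, pd.Series]:
    """Mean stress-minus-control differential over the stress window.

    Records are paired by exact timestamp; minutes where either aggregate is
    missing are excluded pairwise.  Returns the overall mean and a per-night
    series keyed by the evening's date.  Raises ValueError when the two logs
    share no usable timestamps.
    """
    if stress_window is None:
        stress_window = ControllerConfig().stress_window
    s = log_stress.avg_series()
    c = log_control.avg_series()
    joined = pd.concat([s.rename("stress"), c.rename("control")], axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("logs share no overlapping timestamps with aggregates")
    mask = [t in stress_window for t in joined.index]
    joined = joined.loc[mask]
    if joined.empty:
        raise ValueError("no overlapping timestamps inside the stress window")
    diff = joined["stress"] - joined["control"]
    nights = diff.groupby([_night_key(t) for t in diff.index]).mean()
    nights.index.name = "night"
    return float(diff.mean()), nights


def sensor_uniformity(log: EnvLog) -> UniformityReport:
    """Time-averaged inter-sensor spread metrics over successful readings.

    At each timestamp with >= 2 ok sensors, computes the mean absolute
    pairwise difference and the range (max - min); both are then averaged
    over time.  Per-sensor bias is the sensor's mean deviation from the
    concurrent cross-sensor mean.  Raises ValueError when no timestamp has
    two working sensors.
    """
    n_sensors = len(log.sensor_ids)
    vals = np.full((len(log.records), n_sensors), np.nan)
    for i, rec in enumerate(log.records):
        for j, v in enumerate(rec.sensor_values[:n_sensors]):
            if v is not None:
                vals[i, j] = v
    ok_counts = np.sum(~np.isnan(vals), axis=1)
    usable = ok_counts >= 2
    if not np.any(usable):
        raise ValueError("fewer than 2 ok sensors at every timestamp")
    pair_means = []
    ranges = []
    for row in vals[usable]:
        v = row[~np.isnan(row)]
        diffs = [abs(a - b) for a, b in itertools.combinations(v, 2)]
        pair_means.append(float(np.mean(diffs)))
        ranges.append(float(v.max() - v.min()))
    row_mean = np.nanmean(vals[usable], axis=1)
    bias = {}
    for j, sid in enumerate(log.sensor_ids):
        dev = vals[usable, j] - row_mean
        bias[sid] = float(np.nanmean(dev)) if np.any(~np.isnan(dev)) else float("nan")
    return UniformityReport(
        mean_pairwise_abs_diff_C=float(np.mean(pair_means)),
        mean_range_C=float(np.mean(ranges)),
        per_sensor_bias_C=bias,
        n_timestamps=int(np.sum(usable)),
    )


def _as_series(obj) -> pd.Series:
    if isinstance(obj, EnvLog):
        return obj.avg_series()
    if isinstance(obj, pd.Series):
        return obj
    raise TypeError(f"expected EnvLog or pandas Series, got {type(obj)!r}")


def hourly_profile(
    logs: Mapping[str, "EnvLog | pd.Series"],
    ambient=None,
    day_hours: Tuple[int, int] = (7, 18),
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-clock-hour mean temperature for each labelled stream.

    ``ambient`` may be an AmbientTrace-like object (attributes ``start_time``,
    ``temp_C``, ``step_s``) or a pandas Series; when present an ``ambient``
    column is added and the day-period (default 07:00-18:00) tent-minus-ambient
    offsets are returned as the second element.  Empty hour bins are NaN.
    """
    series = {label: _as_series(obj) for label, obj in logs.items()}
    if ambient is not None:
        if isinstance(ambient, pd.Series):
            amb = ambient
        else:
            idx = pd.date_range(
                ambient.start_time, periods=len(ambient.temp_C), freq=f"{int(ambient.step_s)}s"
            )
            amb = pd.Series(np.asarray(ambient.temp_C, dtype=float), index=idx)
        series["ambient"] = amb
    prof = pd.DataFrame(index=pd.Index(range(24), name="hour"))
    for label, s in series.items():
        prof[label] = s.groupby(s.index.hour).mean()
    offsets: Dict[str, float] = {}
    if ambient is not None:
        amb = series["ambient"]
        lo, hi = day_hours
        for label, s in series.items():
            if label == "ambient":
                continue
            joined = pd.concat([s.rename("t"), amb.rename("a")], axis=1, join="inner").dropna()
            day = joined[(joined.index.hour >= lo) & (joined.index.hour < hi)]
            offsets[label] = float((day["t"] - day["a"]).mean()) if not day.empty else float("nan")
    return prof, offsets


def summarize_environment(
    log_stress: EnvLog,
    log_control: EnvLog,
    stress_window: Optional[ClockWindow] = None,
    ambient=None,
    truth_stress: Optional[pd.DataFrame] = None,
    truth_control: Optional[pd.DataFrame] = None,
) -> EnvSummary:
    """Bundle the headline environmental statistics for one paired run.

    RH differences require the simulator's ground-truth frames (the
    controller log carries no humidity channel); they are omitted when the
    truth frames are not supplied.
    """
    if stress_window is None:
        stress_window = ControllerConfig().stress_window
    mean_diff, nights = nightly_differential(log_stress, log_control, stress_window)
    s = log_stress.avg_series()
    c = log_control.avg_series()
    joined = pd.concat([s.rename("stress"), c.rename("control")], axis=1, join="inner").dropna()
    joined = joined.loc[[t in stress_window for t in joined.index]]
    prof, offsets = hourly_profile({"stress": s, "control": c}, ambient=ambient)
    co2_vals = [r.co2_ppm for r in log_stress.records if r.co2_ppm is not None]
    co2_stats = None
    if co2_vals:
        arr = np.asarray(co2_vals, dtype=float)
        co2_stats = {"mean_ppm": float(arr.mean()), "min_ppm": float(arr.min()), "max_ppm": float(arr.max())}
    rh_diff = None
    if truth_stress is not None and truth_control is not None:
        ts = truth_stress.set_index("time") if "time" in truth_stress else truth_stress
        tc = truth_control.set_index("time") if "time" in truth_control else truth_control
        j = pd.concat([ts["rh_pct"].rename("s"), tc["rh_pct"].rename("c")], axis=1, join="inner").dropna()
        in_win = np.array([t in stress_window for t in j.index])
        rh_diff = {
            "stress_period": float((j["s"] - j["c"])[in_win].mean()) if in_win.any() else float("nan"),
            "non_stress": float((j["s"] - j["c"])[~in_win].mean()) if (~in_win).any() else float("nan"),
        }
    return EnvSummary(
        mean_diff_C=mean_diff,
        mean_T_stress_C=float(joined["stress"].mean()),
        mean_T_control_C=float(joined["control"].mean()),
        nightly_diff_C=nights,
        hourly_profile=prof,
        day_offset_C=offsets or None,
        co2_stats=co2_stats,
        rh_diff_pct=rh_diff,
    )


def heater_rule_violations(
    log_stress: EnvLog, log_control: EnvLog, cfg: ControllerConfig
) -> pd.DataFrame:
    """Cross-module audit of the control law on a pair of logs.

    Returns the records where the heater was on although the measured
    stress-minus-control differential was at or above the setpoint at
    decision time (empty frame = law held everywhere).
    """
    c = log_control.avg_series()
    rows = []
    for rec in log_stress.records:
        if not rec.heater_on or rec.tent_avg_C is None:
            continue
        if rec.time in c.index:
            diff = rec.tent_avg_C - float(c.loc[rec.time])
            if diff >= cfg.setpoint_diff_C:
                rows.append({"time": rec.time, "diff_C": diff})
    return pd.DataFrame(rows, columns=["time", "diff_C"])
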