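"""Bang-bang thermostat controller for paired stress/control heat tents.

Mirrors the field device: once per read interval the controller polls a
six-sensor temperature array, averages the readings that succeeded, compares
the tent average against the most recent wireless message from the paired
control tent and drives the heater relay when the stress-minus-control
differential is below the setpoint.  Sensor read failures never raise; they
feed a reboot/degraded finite state machine and are recorded in the per-cycle
health token of the log.

Decision rule (single threshold, no hysteresis): the heater engages iff the
measured differential is strictly below the setpoint.  A differential exactly
equal to the setpoint leaves the heater off.  A missing or stale paired
message fails safe to heater off with a ``stale_msg`` health flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "HEALTH_OK",
    "HEALTH_SENSOR_ERROR",
    "HEALTH_REBOOTED",
    "HEALTH_DEGRADED",
    "HEALTH_STALE",
    "ClockWindow",
    "ControllerConfig",
    "SensorReading",
    "ControlMessage",
    "ControllerState",
    "LogRecord",
    "EnvLog",
    "aggregate_array",
    "message_stale",
    "decide_heater",
    "control_cycle",
    "run_controller",
]

HEALTH_OK = "ok"
HEALTH_SENSOR_ERROR = "sensor_error"
HEALTH_REBOOTED = "rebooted"
HEALTH_DEGRADED = "degraded"
HEALTH_STALE = "stale_msg"

HEALTH_TOKENS = (
    HEALTH_OK,
    HEALTH_SENSOR_ERROR,
    HEALTH_REBOOTED,
    HEALTH_DEGRADED,
    HEALTH_STALE,
)

STATUS_OK = "ok"
STATUS_FAILED = "failed"


@dataclass(frozen=True)
class ClockWindow:
    """Half-open clock-time interval [start, end), possibly crossing midnight."""

    start: time
    end: time

    def contains(self, t: "datetime | time") -> bool:
        if isinstance(t, datetime):
            t = t.time()
        if self.start <= self.end:
            return self.start <= t < self.end
        return t >= self.start or t < self.end

    def __contains__(self, t: "datetime | time") -> bool:
        return self.contains(t)


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable parameters of the thermostat loop.

    ``relay_enabled=False`` turns the unit into a pure logger (the control
    tents run the identical stack without a heater relay).
    """

    setpoint_diff_C: float = 4.0
    read_interval_s: int = 60
    n_sensors: int = 6
    max_consec_errors: int = 5
    max_reboots: int = 3
    stale_msg_max_min: float = 5.0
    active_window: ClockWindow = ClockWindow(time(19, 0), time(6, 0))
    stress_window: ClockWindow = ClockWindow(time(20, 0), time(6, 0))
    relay_enabled: bool = True

    def __post_init__(self) -> None:
        if self.setpoint_diff_C <= 0:
            raise ValueError("setpoint_diff_C must be > 0")
        if self.read_interval_s <= 0:
            raise ValueError("read_interval_s must be > 0")
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if self.max_consec_errors < 1 or self.max_reboots < 0:
            raise ValueError("invalid fault-policy counters")
        if self.stale_msg_max_min <= 0:
            raise ValueError("stale_msg_max_min must be > 0")


@dataclass(frozen=True)
class SensorReading:
    """One timestamped observation from one sensor; failed reads carry no value."""

    sensor_id: str
    time: datetime
    value_C: Optional[float]
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status not in (STATUS_OK, STATUS_FAILED):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == STATUS_OK) != (self.value_C is not None):
            raise ValueError("status=ok iff value_C present")

    @classmethod
    def ok(cls, sensor_id: str, when: datetime, value_C: float) -> "SensorReading":
        return cls(sensor_id, when, float(value_C), STATUS_OK)

    @classmethod
    def failed(cls, sensor_id: str, when: datetime) -> "SensorReading":
        return cls(sensor_id, when, None, STATUS_FAILED)


@dataclass(frozen=True)
class ControlMessage:
    """Aggregate temperature wirelessly relayed from a control tent."""

    source_tent: str
    time: datetime
    avg_temp_C: float

    def __post_init__(self) -> None:
        if not (self.avg_temp_C == self.avg_temp_C and abs(self.avg_temp_C) < 1e6):
            raise ValueError("avg_temp_C must be finite")


@dataclass(frozen=True)
class ControllerState:
    heater_on: bool = False
    consec_errors: int = 0
    reboot_count: int = 0
    degraded: bool = False
    last_msg: Optional[ControlMessage] = None
    relay_channels: tuple = (False, False, False, False)


@dataclass(frozen=True)
class LogRecord:
    """One per-cycle log row: per-sensor values (None = failed), aggregate, relay and health."""

    time: datetime
    sensor_values: tuple
    tent_avg_C: Optional[float]
    co2_ppm: Optional[float]
    heater_on: bool
    health: str

    def __post_init__(self) -> None:
        if self.health not in HEALTH_TOKENS:
            raise ValueError(f"unknown health token {self.health!r}")


@dataclass
class EnvLog:
    """Minute-resolution record stream produced by one controller."""

    tent_id: str
    sensor_ids: tuple
    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def times(self) -> list:
        return [r.time for r in self.records]

    def avg_series(self) -> pd.Series:
        """Tent-average temperature indexed by timestamp; failed cycles dropped."""
        idx, vals = [], []
        for r in self.records:
            if r.tent_avg_C is not None:
                idx.append(r.time)
                vals.append(r.tent_avg_C)
        return pd.Series(vals, index=pd.DatetimeIndex(idx), name=self.tent_id, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        cols: dict = {"timestamp": [r.time for r in self.records]}
        for j, sid in enumerate(self.sensor_ids):
            cols[f"sensor_{j + 1}"] = [
                (r.sensor_values[j] if j < len(r.sensor_values) else None)
                for r in self.records
            ]
        cols["tent_avg"] = [r.tent_avg_C for r in self.records]
        cols["co2_ppm"] = [r.co2_ppm for r in self.records]
        cols["heater_on"] = [int(r.heater_on) for r in self.records]
        cols["health"] = [r.health for r in self.records]
        return pd.DataFrame(cols)


def aggregate_array(readings: Sequence[SensorReading]):
    """Arithmetic mean over successful readings.

    Returns ``(avg_C, n_ok)``; ``avg_C`` is None when every read failed
    (a failed cycle feeds the fault policy rather than raising).
    """
    vals = [r.value_C for r in readings if r.status == STATUS_OK]
    if not vals:
        return None, 0
    return sum(vals) / len(vals), len(vals)


def message_stale(msg: Optional[ControlMessage], now: datetime, cfg: ControllerConfig) -> bool:
    """True when no paired-tent message is cached or it is older than the maximum age."""
    if msg is None:
        return True
    return (now - msg.time) > timedelta(minutes=cfg.stale_msg_max_min)


def decide_heater(
    stress_avg_C: Optional[float],
    control_msg: Optional[ControlMessage],
    cfg: ControllerConfig,
    now: datetime,
) -> bool:
    """Single-threshold heater decision.

    True iff the aggregate exists, ``now`` is inside the active window, the
    paired message is fresh and (stress - control) is strictly below the
    setpoint.  A differential of exactly the setpoint returns False.
    """
    if stress_avg_C is None:
        return False
    if now not in cfg.active_window:
        return False
    if message_stale(control_msg, now, cfg):
        return False
    return (stress_avg_C - control_msg.avg_temp_C) < cfg.setpoint_diff_C


def control_cycle(
    state: ControllerState,
    readings: Sequence[SensorReading],
    msg: Optional[ControlMessage],
    cfg: ControllerConfig,
    now: datetime,
    co2_ppm: Optional[float] = None,
):
    """One sense -> aggregate -> decide -> log cycle.

    Failed aggregates increment ``consec_errors``; reaching
    ``max_consec_errors`` triggers a simulated reboot (counters reset, message
    cache cleared, heater forced off for the cycle); after ``max_reboots``
    reboots the controller marks itself degraded but keeps looping and
    logging.  Never raises on sensor failure.
    """
    avg, _n_ok = aggregate_array(readings)
    consec = state.consec_errors
    reboots = state.reboot_count
    degraded = state.degraded
    last_msg = msg if msg is not None else state.last_msg
    health = HEALTH_OK
    heater = False

    if avg is None:
        consec += 1
        if consec >= cfg.max_consec_errors and reboots < cfg.max_reboots:
            # simulated reboot: state reset + one forced heater-off cycle
            consec = 0
            reboots += 1
            last_msg = None
            health = HEALTH_REBOOTED
            if reboots >= cfg.max_reboots:
                degraded = True
        elif degraded:
            health = HEALTH_DEGRADED
        else:
            health = HEALTH_SENSOR_ERROR
    else:
        consec = 0
        if cfg.relay_enabled and now in cfg.active_window:
            if message_stale(last_msg, now, cfg):
                health = HEALTH_STALE
            else:
                heater = decide_heater(avg, last_msg, cfg, now)

    new_state = ControllerState(
        heater_on=heater,
        consec_errors=consec,
        reboot_count=reboots,
        degraded=degraded,
        last_msg=last_msg,
        relay_channels=(heater, False, False, False),
    )
    record = LogRecord(
        time=now,
        sensor_values=tuple(r.value_C for r in readings),
        tent_avg_C=avg,
        co2_ppm=co2_ppm,
        heater_on=heater,
        health=health,
    )
    return new_state, record


def run_controller(
    session: Iterable,
    cfg: ControllerConfig,
    tent_id: str = "tent",
    sensor_ids: Optional[Sequence[str]] = None,
) -> EnvLog:
    """Drive the controller over a pre-assembled session.

    ``session`` yields ``(now, readings, msg)`` or ``(now, readings, msg,
    co2_ppm)`` tuples in strictly increasing time order; out-of-order input
    raises ValueError.  The run is deterministic: identical input yields an
    identical log.
    """
    state = ControllerState()
    records = []
    prev_time: Optional[datetime] = None
    inferred_ids: Optional[tuple] = tuple(sensor_ids) if sensor_ids is not None else None
    for item in session:
        if len(item) == 3:
            now, readings, msg = item
            co2 = None
        else:
            now, readings, msg, co2 = item
        if prev_time is not None and now <= prev_time:
            raise ValueError(f"session timestamps not strictly increasing at {now}")
        prev_time = now
        if inferred_ids is None:
            inferred_ids = tuple(r.sensor_id for r in readings)
        state, rec = control_cycle(state, readings, msg, cfg, now, co2_ppm=co2)
        records.append(rec)
    if inferred_ids is None:
        inferred_ids = tuple(f"sensor_{i + 1}" for i in range(cfg.n_sensors))
    return EnvLog(tent_id=tent_id, sensor_ids=inferred_ids, records=records)
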