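"""Closed-loop paired-tent microclimate simulator.

A single well-mixed air node per tent (lumped capacitance, first order in
time, explicit Euler at the 1-minute sensing cadence) is driven by a diurnal
sinusoid-plus-AR(1) ambient trace.  Each simulated night the stress tent is
fully closed, the paired control tent is closed to a ventilation gap, and the
thermostat controller is invoked once a minute for both tents: the control
tent's aggregate becomes the wireless paired-tent message for the stress
tent, whose heater decision feeds back into the physics.

Spatial nonuniformity is represented only through fixed per-sensor biases;
sensor faults are modeled at the read level (independent per-read failure
probability plus an optional stuck-after timestamp) and never perturb the
true state trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .controller import (
    ClockWindow,
    ControlMessage,
    ControllerConfig,
    ControllerState,
    EnvLog,
    LogRecord,
    SensorReading,
    control_cycle,
)
from .env_analysis import saturation_vp_kPa

__all__ = [
    "VENT_OPEN",
    "VENT_GAP",
    "VENT_CLOSED",
    "AmbientParams",
    "AmbientTrace",
    "ThermalParams",
    "SensorSpec",
    "TentEnvState",
    "SimConfig",
    "default_sensor_array",
    "default_sim_config",
    "generate_ambient",
    "step_tent",
    "sample_sensors",
    "run_paired_night",
    "run_experiment",
]

VENT_OPEN = "open"
VENT_GAP = "control_gap"
VENT_CLOSED = "closed"
_VENT_STATES = (VENT_OPEN, VENT_GAP, VENT_CLOSED)


@dataclass(frozen=True)
class AmbientParams:
    """Diurnal sinusoid + AR(1) noise driving the ambient air."""

    mean_C: float = 18.0
    amplitude_C: float = 6.0
    peak_hour: float = 15.5  # daily maximum mid-afternoon; minimum pre-dawn
    noise_sd_C: float = 0.3
    ar1: float = 0.9
    rh_mean_pct: float = 70.0
    rh_amplitude_pct: float = 15.0
    rh_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd_C < 0 or self.rh_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass
class AmbientTrace:
    """Minute-resolution ambient temperature / relative humidity series."""

    start_time: datetime
    temp_C: np.ndarray
    rh_pct: np.ndarray
    step_s: int = 60

    def __post_init__(self) -> None:
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.rh_pct = np.asarray(self.rh_pct, dtype=float)
        if self.temp_C.shape != self.rh_pct.shape:
            raise ValueError("temp_C and rh_pct must have equal length")
        if np.any(self.rh_pct < 0) or np.any(self.rh_pct > 100):
            raise ValueError("rh_pct must lie in [0, 100]")
        if self.step_s <= 0:
            raise ValueError("step_s must be > 0")

    def __len__(self) -> int:
        return len(self.temp_C)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq=f"{self.step_s}s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times(), "temp_C": self.temp_C, "rh_pct": self.rh_pct})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, step_s: int = 60) -> "AmbientTrace":
        """Build a trace from a frame with ``time``/``temp_C``/``rh_pct`` columns."""
        t0 = pd.Timestamp(df["time"].iloc[0]).to_pydatetime()
        return cls(t0, df["temp_C"].to_numpy(float), df["rh_pct"].to_numpy(float), step_s)


@dataclass(frozen=True)
class ThermalParams:
    """Lumped first-order thermal/moisture/CO2 parameters for one tent.

    ``q_heat / k_closed`` is the steady-state heater elevation above ambient;
    the defaults keep it above 6 degC so heater capacity never limits the
    closed-loop setpoint.
    """

    k_closed: float = 0.07  # 1/min, vents closed
    k_open: float = 0.5  # 1/min, vents open
    q_heat: float = 0.45  # degC/min while the heater runs
    day_bias_C: float = 0.4  # mean daytime tent-minus-ambient offset, vents open
    rh_gain: float = 40.0  # closed-tent moisture source, % of es(T_amb) at equilibrium
    co2_base_ppm: float = 457.0
    co2_resp_ppm_per_min: float = 1.1
    co2_leak_per_min: float = 0.01

    def __post_init__(self) -> None:
        if min(self.k_closed, self.k_open, self.q_heat, self.rh_gain) < 0:
            raise ValueError("rates must be >= 0")
        if self.k_open <= self.k_closed:
            raise ValueError("k_open must exceed k_closed")
        if self.co2_base_ppm <= 0 or self.co2_leak_per_min < 0 or self.co2_resp_ppm_per_min < 0:
            raise ValueError("invalid CO2 parameters")

    @property
    def k_gap(self) -> float:
        # Control tents close to a 20 cm ventilation gap: between open and closed.
        return 0.5 * (self.k_open + self.k_closed)


@dataclass(frozen=True)
class SensorSpec:
    sensor_id: str
    bias_C: float = 0.0
    noise_sd_C: float = 0.1
    fail_prob: float = 0.0
    stuck_fail_from: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.noise_sd_C < 0:
            raise ValueError("noise_sd_C must be >= 0")
        if not (0.0 <= self.fail_prob <= 1.0):
            raise ValueError("fail_prob must lie in [0, 1]")


@dataclass(frozen=True)
class TentEnvState:
    """Instantaneous true environment of one tent."""

    time: datetime
    temp_C: float
    rh_pct: float
    co2_ppm: float
    vent_state: str = VENT_OPEN
    heater_on: bool = False

    def __post_init__(self) -> None:
        if self.vent_state not in _VENT_STATES:
            raise ValueError(f"invalid vent_state {self.vent_state!r}")
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError("rh_pct must lie in [0, 100]")
        if self.co2_ppm <= 0:
            raise ValueError("co2_ppm must be > 0")
        if self.heater_on and self.vent_state != VENT_CLOSED:
            raise ValueError("heater_on requires vent_state == closed")


@dataclass
class SimConfig:
    """Full configuration of one paired-tent simulation."""

    thermal_stress: ThermalParams = field(default_factory=ThermalParams)
    thermal_control: ThermalParams = field(default_factory=ThermalParams)
    sensors_stress: List[SensorSpec] = field(default_factory=lambda: default_sensor_array("s"))
    sensors_control: List[SensorSpec] = field(default_factory=lambda: default_sensor_array("c"))
    ambient: AmbientParams = field(default_factory=AmbientParams)
    seed: int = 0
    n_nights: int = 1
    close_time: time = time(18, 30)
    open_time: time = time(6, 0)
    power_window: ClockWindow = ClockWindow(time(19, 0), time(6, 0))
    co2_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


_DEFAULT_BIASES = (-0.30, -0.18, -0.06, 0.06, 0.18, 0.30)


def default_sensor_array(prefix: str = "s", noise_sd_C: float = 0.1) -> List[SensorSpec]:
    """Six temperature sensors with symmetric spatial biases and Gaussian read noise."""
    return [
        SensorSpec(f"{prefix}{i + 1}", bias_C=b, noise_sd_C=noise_sd_C)
        for i, b in enumerate(_DEFAULT_BIASES)
    ]


def default_sim_config(seed: int = 0, n_nights: int = 1, **overrides) -> SimConfig:
    return SimConfig(seed=seed, n_nights=n_nights, **overrides)


def generate_ambient(
    params: AmbientParams, start_time: datetime, n_minutes: int, seed: int = 0
) -> AmbientTrace:
    """Diurnal sinusoid plus AR(1) noise; deterministic under a fixed seed."""
    if n_minutes < 1:
        raise ValueError("n_minutes must be >= 1")
    rng = np.random.default_rng(seed)
    minute0 = start_time.hour * 60 + start_time.minute
    hours = ((minute0 + np.arange(n_minutes)) / 60.0) % 24.0
    phase = 2.0 * math.pi * (hours - params.peak_hour) / 24.0
    temp = params.mean_C + params.amplitude_C * np.cos(phase)
    if params.noise_sd_C > 0:
        innov_sd = params.noise_sd_C * math.sqrt(1.0 - params.ar1**2)
        eps = rng.normal(0.0, 1.0, n_minutes)
        noise = np.empty(n_minutes)
        noise[0] = params.noise_sd_C * eps[0]
        for i in range(1, n_minutes):
            noise[i] = params.ar1 * noise[i - 1] + innov_sd * eps[i]
        temp = temp + noise
    else:
        rng.normal(0.0, 1.0, n_minutes)  # keep the stream position stable
    rh = params.rh_mean_pct - params.rh_amplitude_pct * np.cos(phase)
    if params.rh_noise_sd > 0:
        rh = rh + rng.normal(0.0, params.rh_noise_sd, n_minutes)
    rh = np.clip(rh, 0.0, 100.0)
    return AmbientTrace(start_time=start_time, temp_C=temp, rh_pct=rh, step_s=60)


def _loss_rate(params: ThermalParams, vent_state: str) -> float:
    if vent_state == VENT_OPEN:
        return params.k_open
    if vent_state == VENT_GAP:
        return params.k_gap
    if vent_state == VENT_CLOSED:
        return params.k_closed
    raise ValueError(f"invalid vent_state {vent_state!r}")


def step_tent(
    state: TentEnvState,
    ambient: Tuple[float, float],
    params: ThermalParams,
    heater_on: bool,
    dt_min: float = 1.0,
) -> TentEnvState:
    """Advance one tent by ``dt_min`` minutes (explicit Euler).

    Temperature relaxes toward ambient (plus the daytime bias when vents are
    open) at the vent-state-dependent loss rate, with an additive heater
    term.  Moisture is tracked as vapor pressure relaxing toward ambient with
    a closed-tent transpiration source; RH is recomputed at the new
    temperature and clipped to [0, 100].  CO2 gains a respiration source
    while closed and leaks toward the baseline.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    t_amb, rh_amb = ambient
    k = _loss_rate(params, state.vent_state)
    target = t_amb + (params.day_bias_C if state.vent_state == VENT_OPEN else 0.0)
    t_new = state.temp_C + dt_min * (k * (target - state.temp_C) + (params.q_heat if heater_on else 0.0))

    e = saturation_vp_kPa(state.temp_C) * state.rh_pct / 100.0
    e_amb = saturation_vp_kPa(t_amb) * rh_amb / 100.0
    source = (
        params.rh_gain / 100.0 * saturation_vp_kPa(t_amb) * params.k_closed
        if state.vent_state == VENT_CLOSED
        else 0.0
    )
    e_new = e + dt_min * (k * (e_amb - e) + source)
    rh_new = float(np.clip(100.0 * e_new / saturation_vp_kPa(t_new), 0.0, 100.0))

    c = state.co2_ppm
    if state.vent_state == VENT_OPEN:
        c_new = c + dt_min * (10.0 * params.co2_leak_per_min * (params.co2_base_ppm - c))
    else:
        source_c = params.co2_resp_ppm_per_min
        c_new = c + dt_min * (source_c - params.co2_leak_per_min * (c - params.co2_base_ppm))
    c_new = max(c_new, 1.0)

    return TentEnvState(
        time=state.time + timedelta(minutes=dt_min),
        temp_C=float(t_new),
        rh_pct=rh_new,
        co2_ppm=float(c_new),
        vent_state=state.vent_state,
        heater_on=bool(heater_on) and state.vent_state == VENT_CLOSED,
    )


def sample_sensors(
    state: TentEnvState, sensors: Sequence[SensorSpec], rng: np.random.Generator
) -> List[SensorReading]:
    """One reading per sensor: true temperature + spatial bias + read noise.

    A sensor fails independently with its per-read probability, or always
    after its ``stuck_fail_from`` timestamp.  Failures yield value-free
    readings, never exceptions, and the failure draw never perturbs the
    noise stream (both are consumed for every sensor on every read).
    """
    out: List[SensorReading] = []
    for spec in sensors:
        u = rng.random()
        noise = rng.normal(0.0, spec.noise_sd_C) if spec.noise_sd_C > 0 else 0.0
        stuck = spec.stuck_fail_from is not None and state.time >= spec.stuck_fail_from
        if stuck or u < spec.fail_prob:
            out.append(SensorReading.failed(spec.sensor_id, state.time))
        else:
            out.append(SensorReading.ok(spec.sensor_id, state.time, state.temp_C + spec.bias_C + noise))
    return out


def _is_night(t: time, close_time: time, open_time: time) -> bool:
    if close_time > open_time:  # crosses midnight (the usual case)
        return t >= close_time or t < open_time
    return close_time <= t < open_time


def _truth_row(state: TentEnvState) -> dict:
    return {
        "time": state.time,
        "temp_C": state.temp_C,
        "rh_pct": state.rh_pct,
        "co2_ppm": state.co2_ppm,
        "vent_state": state.vent_state,
        "heater_on": state.heater_on,
    }


def run_paired_night(
    sim: SimConfig,
    controller_cfg: Optional[ControllerConfig] = None,
    start_evening: datetime = datetime(2019, 5, 26, 18, 0),
    night_index: int = 0,
):
    """Simulate one paired control/stress night, controller in the loop.

    The simulation covers noon of ``start_evening``'s date through 06:00 the
    next morning.  Stress tents close fully and control tents drop to the
    ventilation gap at ``close_time``; controllers are powered inside
    ``power_window`` and log once a minute; everything opens at ``open_time``.
    A controller exception is contained (logged as a crash, heater forced
    off) so the simulated experiment keeps running.

    Returns ``(log_control, log_stress, truth)`` where ``truth`` maps
    ``ambient``/``control``/``stress`` to ground-truth DataFrames and
    ``crashes`` to a list of contained controller exceptions.
    """
    cfg_s = controller_cfg or ControllerConfig()
    cfg_c = replace(cfg_s, relay_enabled=False)
    day0 = datetime.combine(start_evening.date(), time(12, 0))
    n_min = 18 * 60  # noon -> 06:00
    ambient_seed = int(np.random.SeedSequence([sim.seed, night_index, 0]).generate_state(1)[0])
    ambient = generate_ambient(sim.ambient, day0, n_min + 1, seed=ambient_seed)
    rng = np.random.default_rng([sim.seed, night_index, 1])

    state_c = TentEnvState(day0, float(ambient.temp_C[0]), float(ambient.rh_pct[0]),
                           sim.thermal_control.co2_base_ppm, VENT_OPEN, False)
    state_s = TentEnvState(day0, float(ambient.temp_C[0]), float(ambient.rh_pct[0]),
                           sim.thermal_stress.co2_base_ppm, VENT_OPEN, False)
    ctrl_c = ControllerState()
    ctrl_s = ControllerState()
    last_msg: Optional[ControlMessage] = None
    recs_c: List[LogRecord] = []
    recs_s: List[LogRecord] = []
    truth_c, truth_s, crashes = [], [], []

    for i in range(n_min):
        t = day0 + timedelta(minutes=i)
        night = _is_night(t.time(), sim.close_time, sim.open_time)
        state_c = replace(state_c, vent_state=VENT_GAP if night else VENT_OPEN,
                          heater_on=False)
        state_s = replace(state_s, vent_state=VENT_CLOSED if night else VENT_OPEN,
                          heater_on=state_s.heater_on and night)
        heater_cmd = False
        if t in sim.power_window:
            readings_c = sample_sensors(state_c, sim.sensors_control, rng)
            readings_s = sample_sensors(state_s, sim.sensors_stress, rng)
            co2_s = float(state_s.co2_ppm + rng.normal(0.0, sim.co2_noise_sd))
            try:
                ctrl_c, rec_c = control_cycle(ctrl_c, readings_c, None, cfg_c, t)
                recs_c.append(rec_c)
                if rec_c.tent_avg_C is not None:
                    last_msg = ControlMessage("control", t, rec_c.tent_avg_C)
            except Exception as exc:  # contained: the experiment must go on
                crashes.append((t, "control", repr(exc)))
            try:
                ctrl_s, rec_s = control_cycle(ctrl_s, readings_s, last_msg, cfg_s, t, co2_ppm=co2_s)
                recs_s.append(rec_s)
                heater_cmd = rec_s.heater_on
            except Exception as exc:
                crashes.append((t, "stress", repr(exc)))
                heater_cmd = False
        truth_c.append(_truth_row(state_c))
        truth_s.append(_truth_row(replace(state_s, heater_on=heater_cmd and night)))
        state_c = step_tent(state_c, (float(ambient.temp_C[i]), float(ambient.rh_pct[i])),
                            sim.thermal_control, False, 1.0)
        state_s = step_tent(state_s, (float(ambient.temp_C[i]), float(ambient.rh_pct[i])),
                            sim.thermal_stress, heater_cmd and night, 1.0)

    sensor_ids_c = tuple(s.sensor_id for s in sim.sensors_control)
    sensor_ids_s = tuple(s.sensor_id for s in sim.sensors_stress)
    log_c = EnvLog("control", sensor_ids_c, recs_c)
    log_s = EnvLog("stress", sensor_ids_s, recs_s)
    truth = {
        "ambient": ambient.to_frame(),
        "control": pd.DataFrame(truth_c),
        "stress": pd.DataFrame(truth_s),
        "crashes": crashes,
    }
    return log_c, log_s, truth


def run_experiment(
    sim: SimConfig,
    controller_cfg: Optional[ControllerConfig] = None,
    start_evening: datetime = datetime(2019, 5, 26, 18, 0),
):
    """Run ``sim.n_nights`` consecutive nights and concatenate logs and truth."""
    all_c: List[LogRecord] = []
    all_s: List[LogRecord] = []
    frames = {"ambient": [], "control": [], "stress": []}
    crashes = []
    for night in range(sim.n_nights):
        evening = start_evening + timedelta(days=night)
        log_c, log_s, truth = run_paired_night(sim, controller_cfg, evening, night_index=night)
        all_c.extend(log_c.records)
        all_s.extend(log_s.records)
        for key in frames:
            frames[key].append(truth[key])
        crashes.extend(truth["crashes"])
    sensor_ids_c = tuple(s.sensor_id for s in sim.sensors_control)
    sensor_ids_s = tuple(s.sensor_id for s in sim.sensors_stress)
    truth = {k: pd.concat(v, ignore_index=True) for k, v in frames.items()}
    truth["crashes"] = crashes
    return EnvLog("control", sensor_ids_c, all_c), EnvLog("stress", sensor_ids_s, all_s), truth
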