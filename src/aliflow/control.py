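"""Discrete PID liquid-level control with a simulated open-chamber fluid plant.

The physical system is a small open culture dish held at the air-liquid
interface: medium is pumped in and out by peristaltic pumps while a laser
distance sensor reads the surface height. The controller regulates the net
flow so the surface stays at a setpoint despite evaporation and boluses.

The controller is the positional discrete PID

    u(t) = Kp*e(t) + Ki * sum_{s<=t} e(s)*Ts + Kd * (e(t) - e(t-1)) / Ts

with rectangular integration and a backward-difference derivative; ``e`` is
the setpoint error in mm and ``Ts`` the control interval in seconds. The
plant is a mass balance: d(level)/dt = (net_flow - evaporation) / dish_area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ControllerGains",
    "ControllerState",
    "PlantParams",
    "LevelTrace",
    "FlowSchedule",
    "REFERENCE_PLANT",
    "REFERENCE_GAINS",
    "pid_command",
    "plant_step",
    "run_closed_loop",
    "make_flow_schedule",
    "ControlDivergenceError",
]


class ControlDivergenceError(RuntimeError):
    """Raised when a closed-loop run diverges beyond the abort bound."""


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ControllerGains:
    """PID gains and the control interval.

    kp : flow-command units per mm of error
    ki : flow-command units per mm*s of accumulated error
    kd : flow-command units per mm/s of error slope
    ts : control interval in seconds
    """

    kp: float
    ki: float = 0.0
    kd: float = 0.0
    ts: float = 0.1

    def __post_init__(self) -> None:
        _require_finite("gains", self.kp, self.ki, self.kd, self.ts)
        if self.ts <= 0:
            raise ValueError(f"control interval ts must be > 0, got {self.ts}")
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("gains must be non-negative")


@dataclass(frozen=True)
class ControllerState:
    """Controller memory: setpoint, integral accumulator and last error."""

    setpoint: float
    integral_accum: float = 0.0
    prev_error: float = 0.0


@dataclass(frozen=True)
class PlantParams:
    """Open-dish fluid plant.

    dish_area : mm^2, free surface of the chamber
    evaporation_rate : µL/min lost to the incubator atmosphere
    pump_gain : µL/min of actuated flow per unit of controller command
    max_flow : µL/min actuator saturation (symmetric)
    sensor_quantum : mm, laser distance sensor resolution (0 disables)
    initial_level : mm at t = 0
    """

    dish_area: float
    evaporation_rate: float = 0.0
    pump_gain: float = 1000.0
    max_flow: float = math.inf
    sensor_quantum: float = 0.0
    initial_level: float = 0.0

    def __post_init__(self) -> None:
        if self.dish_area <= 0:
            raise ValueError("dish_area must be > 0")
        if self.sensor_quantum < 0:
            raise ValueError("sensor_quantum must be >= 0")
        # evaporation must be compensable at full actuation
        if not 0 <= self.evaporation_rate < self.max_flow:
            raise ValueError(
                "evaporation_rate must be in [0, max_flow): losses beyond the "
                "actuator limit cannot be compensated"
            )


#: 6-mm culture chamber at the air-liquid interface: the bench configuration
#: the convergence figure refers to (28.3 mm^2 surface holds ~150 µL of
#: medium at a ~5 mm level, resolvable by a 0.1-mm laser sensor).
REFERENCE_PLANT = PlantParams(
    dish_area=math.pi * 3.0**2,  # 6 mm diameter
    evaporation_rate=20.0,  # µL/min at 37 °C in the incubator
    pump_gain=10_000.0,  # one command unit = 10 mL/min
    max_flow=2_000.0,  # 2 mL/min peristaltic limit
    sensor_quantum=0.1,  # 100 µm laser precision
    initial_level=5.0,
)

#: Proportional-only tuning used on the bench.
REFERENCE_GAINS = ControllerGains(kp=0.3, ki=0.0, kd=0.0, ts=0.1)


def pid_command(
    gains: ControllerGains, state: ControllerState, measured_level: float
) -> Tuple[float, ControllerState]:
    """One PID update: return the flow command and the advanced state.

    The command is ``kp*e + ki*I' + kd*(e - e_prev)/ts`` where
    ``e = setpoint - measured_level`` and ``I' = I + e*ts``.
    """
    if not math.isfinite(measured_level):
        raise ValueError(f"measured_level must be finite, got {measured_level!r}")
    e = state.setpoint - measured_level
    integral = state.integral_accum + e * gains.ts
    command = gains.kp * e + gains.ki * integral + gains.kd * (e - state.prev_error) / gains.ts
    return command, replace(state, integral_accum=integral, prev_error=e)


def plant_step(params: PlantParams, level: float, net_flow: float, dt: float) -> float:
    """Advance the dish level by one mass-balance step.

    net_flow is in µL/min (positive = into the dish); the level cannot go
    below zero (dry dish), which is logged when it clips.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new_level = level + (net_flow - params.evaporation_rate) * dt / 60.0 / params.dish_area
    if new_level < 0:
        logger.warning("dish ran dry: level clipped to 0 (was %.4f mm)", new_level)
        new_level = 0.0
    return new_level


@dataclass
class LevelTrace:
    """Closed-loop run record: true level, quantized measurement, command."""

    times: np.ndarray  # s
    levels: np.ndarray  # mm, true
    measured: np.ndarray  # mm, quantized sensor reading
    commands: np.ndarray  # controller output, flow-command units
    setpoint: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.levels) == len(self.measured) == len(self.commands) == n):
            raise ValueError("trace arrays must have equal lengths")

    def max_deviation(self, after_s: float = 0.0) -> float:
        """Largest |level - setpoint| over times >= after_s."""
        sel = self.times >= after_s
        return float(np.max(np.abs(self.levels[sel] - self.setpoint)))


def _quantize(level: float, quantum: float) -> float:
    if quantum <= 0:
        return level
    return round(level / quantum) * quantum


def run_closed_loop(
    params: PlantParams,
    gains: ControllerGains,
    setpoint: float,
    duration: float,
    disturbance: Optional[Tuple[float, float]] = None,
) -> LevelTrace:
    """Simulate the quantize -> PID -> saturate -> mass-balance loop.

    disturbance is an (time_s, step_mm) instantaneous level step. The
    integral accumulator is frozen while the actuator is saturated
    (anti-windup by conditional integration). Aborts if the level departs
    from the setpoint by more than 10x the applied excitation.
    """
    ts = gains.ts
    n_steps = round(duration / ts)
    if abs(n_steps * ts - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("control interval ts must divide duration")
    dist_time, dist_step = disturbance if disturbance is not None else (0.0, 0.0)
    if disturbance is not None and duration < dist_time:
        raise ValueError("duration must cover the disturbance time")

    excitation = max(abs(dist_step), abs(params.initial_level - setpoint))
    abort_bound = 10.0 * excitation if excitation > 0 else math.inf

    times = np.arange(n_steps + 1) * ts
    levels = np.empty(n_steps + 1)
    measured = np.empty(n_steps + 1)
    commands = np.empty(n_steps + 1)

    level = params.initial_level
    state = ControllerState(setpoint=setpoint)
    dist_applied = disturbance is None
    for k in range(n_steps + 1):
        t = k * ts
        if not dist_applied and t >= dist_time - ts / 2:
            level += dist_step
            dist_applied = True
        if abs(level - setpoint) > abort_bound:
            raise ControlDivergenceError(
                f"level diverged to {level:.3f} mm at t={t:.2f} s "
                f"(setpoint {setpoint} mm, bound ±{abort_bound:.3f} mm)"
            )
        m = _quantize(level, params.sensor_quantum)
        command, new_state = pid_command(gains, state, m)
        flow = command * params.pump_gain
        if abs(flow) > params.max_flow:
            flow = math.copysign(params.max_flow, flow)
            # anti-windup: do not accumulate integral while saturated
            new_state = replace(new_state, integral_accum=state.integral_accum)
        times[k], levels[k], measured[k], commands[k] = t, level, m, command
        state = new_state
        if k < n_steps:
            level = plant_step(params, level, flow, ts)
    return LevelTrace(times=times, levels=levels, measured=measured, commands=commands, setpoint=setpoint)


@dataclass(frozen=True)
class FlowSchedule:
    """Periodic bolus schedule: (start_s, duration_s, rate_µL_per_min) events."""

    events: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, dur, _rate in self.events:
            if start < prev_end:
                raise ValueError("flow events must be sorted and non-overlapping")
            prev_end = start + dur

    def rate_at(self, t: float) -> float:
        """Scheduled inflow (µL/min) at time t."""
        for start, dur, rate in self.events:
            if start <= t < start + dur:
                return rate
        return 0.0


def make_flow_schedule(
    bolus_ul: float, bolus_duration_s: float, period_s: float, total_s: float
) -> FlowSchedule:
    """Periodic medium bolus: ``bolus_ul`` delivered over ``bolus_duration_s``
    every ``period_s``, starting at t = 0, for ``total_s`` seconds.

    A 600 µL bolus over 1 min every 20 min for 24 h yields 72 events at
    600 µL/min.
    """
    if period_s <= 0:
        raise ValueError("period_s must be > 0")
    if bolus_duration_s <= 0 or bolus_duration_s >= period_s:
        raise ValueError("bolus_duration_s must be in (0, period_s)")
    rate = bolus_ul / (bolus_duration_s / 60.0)
    events = []
    t = 0.0
    while t < total_s:
        events.append((t, bolus_duration_s, rate))
        t += period_s
    if not events:  # total shorter than one period still gets the t=0 bolus
        events.append((0.0, bolus_duration_s, rate))
    return FlowSchedule(events=tuple(events))
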