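"""Closed-loop pipette internal pressure.

A discrete PID controller (derivative on measurement, clamped integral
and output) drives a simulated pneumatic plant.  The physical valve
network (positive branch, Venturi vacuum branch, 3-port selector) is
collapsed into a signed first-order system: the controller output is a
valve-drive percentage u in [-100, 100]; its equilibrium pressure is
(u/100) * supply_pressure on the positive branch and
(u/100) * |vacuum_limit| on the vacuum branch, so fluctuations of the
supply genuinely disturb the loop and must be rejected by feedback.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PidGains", "PidController", "PneumaticPlant", "SettleResult",
           "pid_step", "plant_step", "settle"]


@dataclass
class PidGains:
    kp: float = 6.0
    ki: float = 60.0
    kd: float = 0.0
    output_limits: tuple = (-100.0, 100.0)
    integral_limit: float = 100.0
    sample_dt: float = 0.001            # s


class PidController:
    """Standard discrete PID with anti-windup and derivative on measurement."""

    def __init__(self, gains: PidGains = None):
        self.gains = gains or PidGains()
        self.reset()

    def reset(self):
        self.integral = 0.0
        self._last_measurement = None

    def step(self, setpoint: float, measurement: float) -> float:
        g = self.gains
        error = setpoint - measurement
        self.integral += error * g.sample_dt
        self.integral = float(np.clip(self.integral, -g.integral_limit,
                                      g.integral_limit))
        if self._last_measurement is None:
            dmeas = 0.0
        else:
            dmeas = (measurement - self._last_measurement) / g.sample_dt
        self._last_measurement = measurement
        u = g.kp * error + g.ki * self.integral - g.kd * dmeas
        return float(np.clip(u, *g.output_limits))


def pid_step(controller: PidController, setpoint: float,
             measurement: float) -> float:
    return controller.step(setpoint, measurement)


@dataclass
class PneumaticPlant:
    """Signed first-order pressure plant with saturation.

    The first-order update uses the exact exponential solution, so the
    one-time-constant 63.2% property holds for any step size.
    """

    pressure: float = 0.0            # kPa, signed (negative = suction)
    tau: float = 0.1                 # s
    supply_pressure: float = 50.0    # kPa
    vacuum_limit: float = -80.0      # kPa
    noise_sd: float = 0.0            # kPa / sqrt(s)
    supply_nominal: float = 50.0     # kPa used for valve-drive scaling
    branch: str = "positive"

    def equilibrium(self, command: float) -> float:
        """Pressure the plant settles to for a constant valve drive."""
        u = float(np.clip(command, -100.0, 100.0))
        if u >= 0:
            return (u / 100.0) * self.supply_pressure
        return (u / 100.0) * abs(self.vacuum_limit)

    def step(self, command: float, dt: float, rng=None):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.branch = "positive" if command >= 0 else "negative"
        target = self.equilibrium(command)
        alpha = 1.0 - np.exp(-dt / self.tau)
        self.pressure += alpha * (target - self.pressure)
        if self.noise_sd > 0 and rng is not None:
            self.pressure += self.noise_sd * np.sqrt(dt) * rng.standard_normal()
        self.pressure = float(np.clip(self.pressure, self.vacuum_limit,
                                      self.supply_pressure))
        return self


def plant_step(plant: PneumaticPlant, command: float, dt: float,
               rng=None) -> PneumaticPlant:
    return plant.step(command, dt, rng)


@dataclass
class SettleResult:
    settled: bool
    trace: dict                      # t, setpoint, pressure, command arrays


def settle(controller: PidController, plant: PneumaticPlant, setpoint: float,
           tolerance: float = 0.5, timeout: float = 5.0,
           dwell: float = 0.05, rng=None,
           supply_schedule=None) -> SettleResult:
    """Run the closed loop until the pressure holds within tolerance.

    ``supply_schedule(t)`` may return a supply pressure to emulate input
    fluctuations.  Returns the full (t, setpoint, pressure, command) trace.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    dt = controller.gains.sample_dt
    n = max(1, int(round(timeout / dt)))
    dwell_n = max(1, int(round(dwell / dt)))
    ts, ps, us = np.zeros(n), np.zeros(n), np.zeros(n)
    in_band = 0
    settled = False
    k_end = n
    for k in range(n):
        t = k * dt
        if supply_schedule is not None:
            plant.supply_pressure = float(supply_schedule(t))
        u = controller.step(setpoint, plant.pressure)
        plant.step(u, dt, rng)
        ts[k], ps[k], us[k] = t, plant.pressure, u
        in_band = in_band + 1 if abs(plant.pressure - setpoint) <= tolerance else 0
        if in_band >= dwell_n:
            settled = True
            k_end = k + 1
            break
    trace = {"t": ts[:k_end], "setpoint": np.full(k_end, setpoint),
             "pressure": ps[:k_end], "command": us[:k_end]}
    return SettleResult(settled=settled, trace=trace)
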