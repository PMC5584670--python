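"""Seal-test electrophysiology: signal synthesis, resistance estimation,
the pipette/membrane impedance simulator, and the adaptive-suction seal
and break-in logic.

The amplifier applies a 10 mV, 10 Hz square seal-test signal (optionally
superimposed on a -70 mV holding potential); the evoked current is
sampled at 20 kHz, low-pass Bessel filtered, and the pipette resistance
is computed per cycle as the applied voltage over the peak-to-peak
current.  Units: mV, nA, MOhm, kPa, s (10 mV / 2 nA = 5 MOhm).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SealTestConfig", "ImpedanceModel", "SuctionPolicy", "ResistanceEstimate",
    "seal_test_waveform", "bessel_lowpass", "estimate_resistance",
    "impedance_response", "detect_engagement", "adaptive_suction_step",
    "detect_seal", "detect_breakin", "breakin_pulses", "check_pipette",
]

GIGAOHM = 1000.0  # MOhm


@dataclass
class SealTestConfig:
    amplitude: float = 10.0          # mV, peak-to-peak of the square wave
    frequency: float = 10.0          # Hz
    sample_rate: float = 20000.0     # Hz
    filter_cutoff: float = 9000.0    # Hz; realizable digital stand-in for the
                                     # amplifier's 10 kHz analog Bessel filter
    holding_potential: float = 0.0   # mV (0 or -70)
    filter_order: int = 4
    noise_floor: float = 1e-4        # nA; below this, resistance unmeasurable

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.filter_cutoff >= self.sample_rate / 2.0:
            raise ValueError("filter_cutoff must be below Nyquist")


def seal_test_waveform(config: SealTestConfig, duration: float) -> np.ndarray:
    """Square test signal: levels {holding, holding + amplitude}."""
    period = 1.0 / config.frequency
    if duration < period:
        raise ValueError("duration must span at least one period")
    n = int(round(duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    phase = (t * config.frequency) % 1.0
    return config.holding_potential + config.amplitude * (phase < 0.5)


def bessel_lowpass(trace: np.ndarray, config: SealTestConfig) -> np.ndarray:
    """Causal digital Bessel low-pass at the configured cutoff, DC gain 1."""
    sos = sps.bessel(config.filter_order, config.filter_cutoff,
                     btype="low", fs=config.sample_rate, output="sos")
    return sps.sosfilt(sos, np.asarray(trace, dtype=float))


@dataclass
class ResistanceEstimate:
    per_cycle: list                  # MOhm, one per full cycle
    megaohms: float                  # median across cycles
    unmeasurable: bool = False       # current below the noise floor


def estimate_resistance(voltage_amplitude: float, current_trace: np.ndarray,
                        config: SealTestConfig) -> ResistanceEstimate:
    """R = V / I_pp per test cycle; median across cycles.

    The per-cycle peak-to-peak current is measured as the difference of
    the 97.5th and 2.5th percentiles (the plateau levels of the square
    response), which is exact for an ideal resistor and robust to filter
    edge transients.  Currents below the noise floor yield an
    unmeasurable (open-circuit / deep-gigaohm) sentinel.
    """
    x = np.asarray(current_trace, dtype=float)
    cycle = int(round(config.sample_rate / config.frequency))
    n_cycles = x.size // cycle
    if n_cycles < 1:
        raise ValueError("trace must span at least one full cycle")
    per_cycle = []
    unmeasurable = False
    for i in range(n_cycles):
        seg = x[i * cycle:(i + 1) * cycle]
        ipp = float(np.percentile(seg, 97.5) - np.percentile(seg, 2.5))
        if ipp < config.noise_floor:
            per_cycle.append(math.inf)
            unmeasurable = True
        else:
            per_cycle.append(voltage_amplitude / ipp)
    return ResistanceEstimate(per_cycle=per_cycle,
                              megaohms=float(np.median(per_cycle)),
                              unmeasurable=unmeasurable)


@dataclass
class ImpedanceModel:
    """Stage-dependent pipette/membrane resistance dynamics.

    Sealing follows logistic growth toward ``seal_resistance_target`` with
    rate ``seal_rate * g(suction, holding)`` where
    ``g = (1 + a|P_neg|)(1 + b|V_hold|/70)``: both gentle suction and
    hyperpolarization accelerate gigaseal formation.
    """

    r_bath: float = 6.0                      # MOhm, pipette in bath (5-7)
    contact_factor: float = 1.5              # relative rise on membrane contact
    seal_resistance_target: float = 1800.0   # MOhm
    seal_rate: float = 0.35                  # 1/s logistic growth constant
    suction_gain: float = 0.15               # a, per kPa of suction
    holding_gain: float = 1.0                # b, per 70 mV of hyperpolarization
    r_access_wholecell: float = 16.0         # MOhm after break-in
    clog_factor: float = 2.5
    stage: str = "bath"                      # bath|contact|sealing|sealed|wholecell|clogged
    resistance: float = None                 # MOhm, current value
    holding_mv: float = 0.0
    contact_tau: float = 0.3                 # s, rise time on contact
    rupture_threshold: float = 6.0           # kPa*s of suction-pulse impulse
    rupture_accum: float = 0.0

    def __post_init__(self):
        if self.resistance is None:
            self.resistance = self.r_bath

    def growth_factor(self, pressure_kpa: float) -> float:
        suction = max(0.0, -pressure_kpa)
        return ((1.0 + self.suction_gain * suction)
                * (1.0 + self.holding_gain * abs(self.holding_mv) / 70.0))

    def evolve(self, dt: float, pressure_kpa: float = 0.0):
        """Advance R(t) by dt under the current stage rules."""
        if self.stage == "bath":
            self.resistance = self.r_bath
        elif self.stage == "contact":
            target = self.r_bath * self.contact_factor
            alpha = 1.0 - math.exp(-dt / self.contact_tau)
            self.resistance += alpha * (target - self.resistance)
        elif self.stage in ("sealing", "sealed"):
            k = self.seal_rate * self.growth_factor(pressure_kpa)
            K = self.seal_resistance_target
            r0 = max(self.resistance, 1e-6)
            # closed-form logistic step
            self.resistance = K / (1.0 + (K - r0) / r0 * math.exp(-k * dt))
        elif self.stage == "wholecell":
            self.resistance = self.r_access_wholecell
        elif self.stage == "clogged":
            self.resistance = self.r_bath * self.clog_factor
        return self.resistance

    def apply_suction_impulse(self, amplitude_kpa: float, duration_s: float):
        """Accumulate break-in pulse dose; rupture when the threshold is crossed."""
        if self.stage not in ("sealed", "sealing"):
            return False
        self.rupture_accum += abs(min(0.0, amplitude_kpa)) * duration_s
        if self.rupture_accum >= self.rupture_threshold:
            self.stage = "wholecell"
            self.resistance = self.r_access_wholecell
            return True
        return False


def impedance_response(model: ImpedanceModel, voltage_trace: np.ndarray,
                       pressure_kpa: float, dt: float):
    """Current evoked by a voltage trace while R evolves over its duration.

    Returns ``(current_trace_nA, model)``.  R is evolved with the stage
    rules across the trace duration; the current is V/R with R linearly
    interpolated between the start and end values (R varies slowly on the
    scale of one measurement).
    """
    v = np.asarray(voltage_trace, dtype=float)
    r0 = model.resistance
    model.evolve(v.size * dt, pressure_kpa)
    r1 = model.resistance
    r = np.linspace(r0, r1, v.size)
    return v / r, model


def detect_engagement(r_history, baseline_window: int = 10,
                      rel_increase: float = 0.2, dwell: int = 3) -> bool:
    """Membrane contact: sustained rise of R above its pre-approach baseline."""
    r = np.asarray(r_history, dtype=float)
    if r.size < baseline_window + dwell:
        return False
    baseline = float(np.median(r[:baseline_window]))
    return bool(np.all(r[-dwell:] >= baseline * (1.0 + rel_increase)))


@dataclass
class SuctionPolicy:
    s_th: float = 5.0                # MOhm minimum required rise over t_seal
    t_seal: float = 2.0              # s evaluation window
    low_fraction: float = 0.15       # of the target seal resistance
    suction_step: float = -1.0       # kPa per deepening
    seal_threshold: float = 1000.0   # MOhm (1-1.5 GOhm band)
    time_limit: float = 30.0         # s to attain a seal
    max_suction: float = -12.0       # kPa, deepest allowed setpoint

    def __post_init__(self):
        if not 0.0 < self.low_fraction < 1.0:
            raise ValueError("low_fraction must be in (0, 1)")
        if self.time_limit <= self.t_seal:
            raise ValueError("time_limit must exceed t_seal")


def adaptive_suction_step(policy: SuctionPolicy, r_history, t_history,
                          current_setpoint: float):
    """One evaluation of the adaptive-suction rule.

    Suction is deepened iff R is below ``low_fraction`` of the seal
    threshold AND R failed to rise by at least ``s_th`` over the last
    ``t_seal`` seconds.  Otherwise the current setpoint is held (eased to
    hold once R is past the low fraction).  Returns ``(action, setpoint)``
    with action in {'deepen', 'hold'}.
    """
    r = np.asarray(r_history, dtype=float)
    ts = np.asarray(t_history, dtype=float)
    if r.size < 2 or ts[-1] - ts[0] < policy.t_seal:
        return "hold", current_setpoint
    t_now = ts[-1]
    idx = int(np.searchsorted(ts, t_now - policy.t_seal, side="right") - 1)
    idx = max(idx, 0)
    delta = r[-1] - r[idx]
    low = r[-1] < policy.low_fraction * policy.seal_threshold
    stalled = delta < policy.s_th
    if low and stalled:
        new = max(policy.max_suction, current_setpoint + policy.suction_step)
        return "deepen", new
    return "hold", current_setpoint


def detect_seal(resistance: float, policy: SuctionPolicy) -> bool:
    """Gigaseal: R at or above the user-defined threshold."""
    return resistance >= policy.seal_threshold


def detect_breakin(r_history, drop_factor: float = 10.0,
                   window: int = 5) -> bool:
    """Break-in: R dropped by >= drop_factor from the sealed value within a window."""
    r = np.asarray(r_history, dtype=float)
    if r.size < 2:
        return False
    recent = r[-(window + 1):]
    return bool(recent.max() >= drop_factor * recent.min() > 0)


@dataclass
class BreakinSchedule:
    pulse_amplitude: float = -8.0     # kPa
    pulse_duration: float = 0.15      # s
    escalation: float = 1.25          # amplitude multiplier per pulse
    budget: int = 10
    inter_pulse_dwell: float = 0.2    # s between pulses for the R check


def breakin_pulses(apply_pulse, model: ImpedanceModel,
                   schedule: BreakinSchedule = None, log=None):
    """Apply suction pulses until break-in is detected or the budget runs out.

    ``apply_pulse(amplitude_kpa, duration_s)`` drives the pneumatics; the
    impedance simulator accumulates pulse dose and ruptures when its
    (seeded) threshold is crossed.  Returns ``(success, pulses_applied)``.
    """
    schedule = schedule or BreakinSchedule()
    amp = schedule.pulse_amplitude
    r_hist = [model.resistance]
    for k in range(1, schedule.budget + 1):
        apply_pulse(amp, schedule.pulse_duration)
        model.apply_suction_impulse(amp, schedule.pulse_duration)
        r_hist.append(model.resistance)
        if log is not None:
            log("breakin_pulse", pulse=k, amplitude=amp,
                resistance=model.resistance)
        if detect_breakin(r_hist):
            return True, k
        amp *= schedule.escalation
    return False, schedule.budget


def check_pipette(resistance: float, baseline: float,
                  clog_factor: float = 1.5) -> str:
    """'clogged' iff R is at or above clog_factor * baseline (boundary inclusive)."""
    return "clogged" if resistance >= clog_factor * baseline else "ok"
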