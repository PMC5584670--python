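"""Orchestration of the full virtual patching procedure.

Wires the scene simulator, vision, autofocus, tracking, servo,
pneumatics, and seal-test electrophysiology into the closed loop:
pipette positioning -> automatic approach (interleaved step/reacquire
with pressure staging) -> target engagement (impedance rise) -> seal
formation (pressure release, -70 mV holding, adaptive suction) ->
break-in (suction pulses) -> whole-cell.  All timing uses a simulated
clock at fixed ticks, so runs are bit-deterministic for a given
(config, seed).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autofocus as af
from . import ephys, pneumatics, scene as scn, servo, tracking, vision

__all__ = ["ExperimentConfig", "EventLog", "ExperimentResult", "Objective",
           "default_scene_config", "default_config", "select_target",
           "run_experiment", "run_batch", "STAGES"]

STAGES = ["positioning", "approach", "engagement", "seal", "breakin", "wholecell"]

FRAME_DT = 0.25          # s per acquired frame (two-photon frame period)
MEAS_DT = 0.1            # s per seal-test resistance measurement (one cycle)
PERIODIC_REFOCUS_STEPS = 6
NEAR_REFOCUS_STEPS = 3       # tighter refocus cadence close to the target,
NEAR_REFOCUS_DISTANCE = 40.0  # where per-step tissue push is largest (um)


class EventLog:
    """Append-only, monotone-time event log with one terminal event."""

    def __init__(self):
        self.events = []

    def append(self, t: float, stage: str, event: str, **payload):
        if self.events and t < self.events[-1]["t"] - 1e-9:
            raise ValueError("event timestamps must be monotone")
        self.events.append({"t": float(t), "stage": stage, "event": event,
                            "payload": payload})

    def terminal(self):
        term = [e for e in self.events
                if e["event"] in ("wholecell", "fail")]
        return term[-1] if term else None

    def stage_sequence(self):
        seq = []
        for e in self.events:
            if not seq or seq[-1] != e["stage"]:
                seq.append(e["stage"])
        return seq

    def validate(self):
        """Schema check: required keys, monotone t, exactly one terminal event."""
        last = -np.inf
        for e in self.events:
            assert set(e) == {"t", "stage", "event", "payload"}
            assert isinstance(e["payload"], dict)
            assert e["t"] >= last - 1e-9
            last = e["t"]
        terms = [e for e in self.events if e["event"] in ("wholecell", "fail")]
        assert len(terms) == 1, "exactly one terminal event required"
        return True

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


class Objective:
    """Virtual objective lens: holds and moves the focal plane."""

    def __init__(self, z: float = 0.0):
        self.z = float(z)

    def move(self, z: float):
        self.z = float(z)


def default_scene_config(seed: int) -> dict:
    """Study conditions: one labelled target soma ~120 um deep plus
    distractors, seeded position jitter, default deformation and motion."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    jitter = lambda s: rng.uniform(-s, s, size=3)
    target = np.array([0.0, 0.0, -120.0]) + jitter(4.0)
    distractors = [
        np.array([-25.0, 18.0, -114.0]) + jitter(4.0),
        np.array([22.0, -24.0, -126.0]) + jitter(4.0),
        np.array([-16.0, -30.0, -110.0]) + jitter(4.0),
    ]
    cells = [{"id": 0, "center": target.tolist(), "diameter": 10.0,
              "channel": "green", "peak_intensity": 15000.0}]
    for i, c in enumerate(distractors, start=1):
        cells.append({"id": i, "center": c.tolist(),
                      "diameter": float(rng.uniform(7.0, 12.0)),
                      "channel": "green",
                      "peak_intensity": float(rng.uniform(9000.0, 15000.0))})
    return {
        "cells": cells,
        "volume_bounds": [[-60, 60], [-60, 60], [-170, 10]],
        "pipette": {"tip": [-80.0, 0.0, 40.0], "axis": [0.819, 0.0, -0.574],
                    "dye_channel": "red"},
        "deformation": {},
        "motion": {},
        "imaging": {},
    }


@dataclass
class ExperimentConfig:
    seed: int
    scene: dict = None
    segmentation: vision.SegmentationConfig = field(
        default_factory=vision.SegmentationConfig)
    approach: servo.ApproachConfig = field(default_factory=servo.ApproachConfig)
    autofocus: af.AutofocusParams = field(default_factory=af.AutofocusParams)
    pid: pneumatics.PidGains = field(default_factory=pneumatics.PidGains)
    plant: pneumatics.PneumaticPlant = field(
        default_factory=pneumatics.PneumaticPlant)
    sealtest: ephys.SealTestConfig = field(default_factory=ephys.SealTestConfig)
    policy: ephys.SuctionPolicy = field(default_factory=ephys.SuctionPolicy)
    breakin: ephys.BreakinSchedule = field(default_factory=ephys.BreakinSchedule)
    mode: str = "targeted"           # targeted | blind | manual_assist
    blind_target: tuple = (0.0, 0.0, -120.0)  # nominal descent point, blind mode
    out_dir: str = None
    noise: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.scene is None:
            self.scene = default_scene_config(self.seed)
        if self.mode not in ("targeted", "blind", "manual_assist"):
            raise ValueError(f"bad mode {self.mode!r}")


def default_config(seed: int, **overrides) -> ExperimentConfig:
    return ExperimentConfig(seed=seed, **overrides)


@dataclass
class ExperimentResult:
    status: str                       # wholecell | seal_only | fail
    fail_reason: str
    log: EventLog
    traces: pd.DataFrame
    trajectory: pd.DataFrame
    steps: int
    time_to_seal: float               # simulated s from sealing start, or nan
    tracked_errors: list              # |tracked - true| um at each reacquisition


def select_target(objects, geometry, focal_z: float, point=None,
                  rule: str = "nearest") -> tracking.Track:
    """Initialize a track from a detection chosen by click point or rule.

    ``rule='nearest'`` picks the object nearest to ``point`` (um);
    ``rule='brightest'`` the one with the highest CFS.  Distance ties
    break toward the lower label.
    """
    if not objects:
        raise ValueError("no detected objects to select from")
    if rule == "brightest":
        chosen = max(objects, key=lambda o: (o.cfs if o.cfs_usable else -np.inf,
                                             -o.label))
    else:
        if point is None:
            raise ValueError("rule='nearest' requires a point")
        def key(o):
            x, y = geometry.pixel_to_um(o.centroid[0], o.centroid[1])
            return (float(np.hypot(x - point[0], y - point[1])), o.label)
        chosen = min(objects, key=key)
    x, y = geometry.pixel_to_um(chosen.centroid[0], chosen.centroid[1])
    track = tracking.Track(target_id=chosen.label)
    track.append(0.0, float(x), float(y), focal_z, cfs=chosen.cfs)
    track.last_object = chosen
    return track


class _Clock:
    def __init__(self):
        self.t = 0.0

    def advance(self, dt: float) -> float:
        self.t += dt
        return self.t


class _Rig:
    """Mutable run state shared between the stage handlers."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        s_scene, s_ephys = ss.spawn(2)
        self.scene = scn.make_scene(config.scene,
                                    int(s_scene.generate_state(1)[0] % (2 ** 31)))
        self.ephys_rng = np.random.default_rng(s_ephys)
        self.clock = _Clock()
        self.objective = Objective()
        self.log = EventLog()
        self.stage = "positioning"
        self.controller = pneumatics.PidController(config.pid)
        self.plant = dataclasses.replace(config.plant)
        self.pressure_setpoint = 0.0
        self.model = ephys.ImpedanceModel(
            seal_rate=float(0.35 * self.ephys_rng.lognormal(0.0, 0.5)),
            rupture_threshold=float(self.ephys_rng.lognormal(np.log(6.0), 0.4)),
        )
        self.r_hist, self.r_times = [], []
        self.traces = {k: [] for k in ("time", "resistance", "current",
                                       "holding", "pressure", "depth")}
        self.pose = servo.PipettePose(tip=self.scene.pipette.tip,
                                      axis=self.scene.pipette.axis)
        self.track = None
        self.tracked_errors = []
        self.trajectory_rows = []

    # --- hardware-facing closures -------------------------------------
    def acquire(self, z: float):
        t = self.clock.advance(FRAME_DT)
        self.advance_pneumatics(FRAME_DT)
        return scn.render_frame(self.scene, z, t, noise=self.config.noise)

    def segment(self, frame):
        objs = vision.segment_frame(frame, self.config.segmentation)
        return objs, frame.geometry(self.scene.imaging)

    def advance_pneumatics(self, duration: float):
        dt = self.controller.gains.sample_dt
        for _ in range(int(round(duration / dt))):
            u = self.controller.step(self.pressure_setpoint, self.plant.pressure)
            self.plant.step(u, dt)

    def set_pressure(self, setpoint: float):
        self.pressure_setpoint = float(setpoint)

    def measure_resistance(self):
        """One seal-test cycle through the full signal chain."""
        cfg = self.config.sealtest
        v = ephys.seal_test_waveform(cfg, MEAS_DT)
        i, _ = ephys.impedance_response(self.model, v, self.plant.pressure,
                                        1.0 / cfg.sample_rate)
        i_f = ephys.bessel_lowpass(i, cfg)
        est = ephys.estimate_resistance(cfg.amplitude, i_f, cfg)
        r = est.megaohms
        self.r_hist.append(r)
        self.r_times.append(self.clock.t)
        ipp = cfg.amplitude / r if np.isfinite(r) and r > 0 else 0.0
        self.record_trace(r, ipp)
        return r

    def record_trace(self, r, ipp):
        tr = self.traces
        tr["time"].append(self.clock.t)
        tr["resistance"].append(r)
        tr["current"].append(ipp)
        tr["holding"].append(self.model.holding_mv)
        tr["pressure"].append(self.plant.pressure)
        tr["depth"].append(self.pose.depth)

    def emit(self, event, **payload):
        self.log.append(self.clock.t, self.stage, event, **payload)

    def true_target_position(self):
        return self.scene.cell_position(self.scene.find_cell(0), self.clock.t)


def _stage_positioning(rig: _Rig):
    cfg = rig.config
    rig.emit("stage_enter")
    rig.set_pressure(cfg.approach.high_pressure)
    rig.advance_pneumatics(1.0)
    rig.clock.advance(1.0)
    # pipette impedance check in the bath
    r = rig.measure_resistance()
    verdict = ephys.check_pipette(r, rig.model.r_bath)
    rig.emit("pipette_check", resistance=r, verdict=verdict)
    if verdict == "clogged":
        return "fail", "clogged"
    if cfg.mode == "blind":
        return None, None
    # operator focuses near the target and clicks it
    true_target = rig.true_target_position()
    rig.objective.move(true_target[2] +
                       float(rig.ephys_rng.uniform(-2.0, 2.0)))
    frame = rig.acquire(rig.objective.z)
    objs, geom = rig.segment(frame)
    if not objs:
        return "fail", "no_target"
    rig.track = select_target(objs, geom, rig.objective.z,
                              point=(true_target[0], true_target[1]))
    rig.track.search_radius = cfg.approach.smallest_target_diameter / 2.0
    sweep = af.autofocus_target(rig.track, rig.objective, rig.acquire,
                                rig.segment, cfg.autofocus)
    if sweep.target_lost:
        return "fail", "no_target"
    p = rig.track.last_position()
    rig.track.positions[-1] = (rig.track.positions[-1][0], p[0], p[1],
                               rig.objective.z)
    rig.emit("target_acquired", position=rig.track.last_position().tolist())
    try:
        lateral, standoff = servo.plan_entry(rig.pose,
                                             rig.track.last_position(),
                                             cfg.approach)
    except servo.PlanningError as exc:
        return "fail", f"planning: {exc}"
    rig.pose = servo.PipettePose(tip=standoff, axis=rig.pose.axis)
    rig.scene.pipette.tip = standoff.copy()
    rig.emit("moved_to_standoff", tip=standoff.tolist())
    return None, None


def _record_tracking_error(rig: _Rig):
    tracked = rig.track.last_position()
    true = rig.true_target_position()
    rig.tracked_errors.append(float(np.linalg.norm(tracked - true)))


def _stage_approach(rig: _Rig):
    cfg = rig.config
    rig.emit("stage_enter")
    steps_since_meas = [0]
    steps_since_focus = [0]

    def reacquire(track):
        steps_since_meas[0] += 1
        steps_since_focus[0] += 1
        dist = float(np.linalg.norm(track.last_position() - rig.pose.tip))
        cadence = (NEAR_REFOCUS_STEPS if dist <= NEAR_REFOCUS_DISTANCE
                   else PERIODIC_REFOCUS_STEPS)
        if steps_since_focus[0] >= cadence:
            af.autofocus_target(track, rig.objective, rig.acquire,
                                rig.segment, cfg.autofocus)
            steps_since_focus[0] = 0
        track = tracking.reacquire_after_step(
            track, rig.objective, rig.acquire, rig.segment,
            cfg.autofocus, t=rig.clock.t)
        while track.status == "occluded":
            track = tracking.reacquire_after_step(
                track, rig.objective, rig.acquire, rig.segment,
                cfg.autofocus, t=rig.clock.t)
        _record_tracking_error(rig)
        if steps_since_meas[0] >= 5:
            rig.measure_resistance()
            steps_since_meas[0] = 0
        return track

    def apply_step(old_tip, new_tip):
        rig.scene = scn.apply_insertion_step(rig.scene, old_tip, new_tip,
                                             t=rig.clock.t)
        rig.pose = servo.PipettePose(tip=np.asarray(new_tip),
                                     axis=rig.pose.axis)

    def log_event(event, **payload):
        rig.emit(event, **payload)

    pose, result = servo.run_approach(rig.pose, rig.track, cfg.approach,
                                      reacquire=reacquire,
                                      apply_step=apply_step,
                                      set_pressure=rig.set_pressure,
                                      log=log_event)
    rig.pose = pose
    rig.trajectory_rows.extend(result.trajectory)
    rig.emit("approach_done", success=result.success, reason=result.reason,
             steps=result.step_count, final_distance=result.final_distance)
    if not result.success:
        reason = {"lost_target": "lost_target"}.get(result.reason,
                                                    result.reason)
        return "fail", reason, result
    return None, None, result


def _stage_engagement(rig: _Rig):
    rig.emit("stage_enter")
    cell = rig.scene.find_cell(0)
    true = rig.true_target_position()
    dist = float(np.linalg.norm(rig.pose.tip - true))
    engage_distance = cell.diameter / 2.0 + 1.5
    if dist > engage_distance:
        rig.emit("no_contact", distance=dist)
        return "fail", "engagement_failed"
    rig.model.stage = "contact"
    rig.emit("membrane_contact", distance=dist)
    for _ in range(15):
        rig.clock.advance(MEAS_DT)
        rig.advance_pneumatics(MEAS_DT)
        rig.measure_resistance()
        if ephys.detect_engagement(rig.r_hist):
            rig.emit("engaged", resistance=rig.r_hist[-1])
            return None, None
    return "fail", "engagement_failed"


def _stage_seal(rig: _Rig):
    cfg = rig.config
    rig.emit("stage_enter")
    rig.set_pressure(0.0)
    rig.advance_pneumatics(1.0)
    rig.clock.advance(1.0)
    rig.emit("pressure_released", pressure=rig.plant.pressure)
    rig.model.holding_mv = -70.0
    rig.emit("holding_applied", holding=-70.0)
    rig.model.stage = "sealing"
    policy = cfg.policy
    t0 = rig.clock.t
    seal_r, seal_t = [], []
    last_rule_t = t0
    while rig.clock.t - t0 < policy.time_limit:
        rig.clock.advance(MEAS_DT)
        rig.advance_pneumatics(MEAS_DT)
        r = rig.measure_resistance()
        seal_r.append(r)
        seal_t.append(rig.clock.t)
        if ephys.detect_seal(r, policy):
            rig.model.stage = "sealed"
            rig.emit("sealed", resistance=r,
                     time_to_seal=rig.clock.t - t0)
            return None, None, rig.clock.t - t0
        if rig.clock.t - last_rule_t >= 0.5:
            action, sp = ephys.adaptive_suction_step(
                policy, seal_r, seal_t, rig.pressure_setpoint)
            last_rule_t = rig.clock.t
            if action == "deepen":
                rig.set_pressure(sp)
                rig.emit("suction_deepened", setpoint=sp,
                         resistance=r)
    return "fail", "seal_timeout", float("nan")


def _stage_breakin(rig: _Rig):
    cfg = rig.config
    rig.emit("stage_enter")

    def apply_pulse(amplitude, duration):
        rig.set_pressure(amplitude)
        rig.advance_pneumatics(duration)
        rig.clock.advance(duration)
        rig.set_pressure(0.0)
        rig.advance_pneumatics(cfg.breakin.inter_pulse_dwell)
        rig.clock.advance(cfg.breakin.inter_pulse_dwell)

    def log_event(event, **payload):
        rig.emit(event, **payload)

    ok, pulses = ephys.breakin_pulses(apply_pulse, rig.model, cfg.breakin,
                                      log=log_event)
    rig.measure_resistance()
    if not ok:
        return "fail", "breakin_budget"
    rig.emit("breakin_detected", pulses=pulses,
             resistance=rig.model.resistance)
    return None, None


def _stage_blind_descent(rig: _Rig):
    """Blind mode: stepwise descent monitoring only the impedance."""
    cfg = rig.config
    rig.stage = "approach"
    rig.emit("stage_enter", mode="blind")
    axis = rig.pose.axis
    # align the descent line through the nominal target point
    nominal = np.asarray(cfg.blind_target, dtype=float)
    standoff = nominal - cfg.approach.standoff_distance * axis
    rig.pose = servo.PipettePose(tip=standoff, axis=axis)
    rig.scene.pipette.tip = standoff.copy()
    budget = 200
    for k in range(budget):
        new_tip = rig.pose.tip + cfg.approach.step_length * axis
        rig.scene = scn.apply_insertion_step(rig.scene, rig.pose.tip.copy(),
                                             new_tip, t=rig.clock.t)
        rig.pose = servo.PipettePose(tip=new_tip, axis=axis)
        rig.clock.advance(FRAME_DT)
        dist = min(np.linalg.norm(rig.pose.tip -
                                  rig.scene.cell_position(c, rig.clock.t))
                   for c in rig.scene.cells)
        rig.set_pressure(servo.pressure_for_distance(float(dist), cfg.approach))
        rig.advance_pneumatics(FRAME_DT)
        cell = min(rig.scene.cells,
                   key=lambda c: np.linalg.norm(
                       rig.pose.tip - rig.scene.cell_position(c, rig.clock.t)))
        if dist <= cell.diameter / 2.0 + 1.5:
            rig.model.stage = "contact"
        rig.measure_resistance()
        rig.emit("insert_step", step=k, tip=rig.pose.tip.tolist())
        if ephys.detect_engagement(rig.r_hist):
            rig.stage = "engagement"
            rig.emit("stage_enter")
            rig.emit("engaged", resistance=rig.r_hist[-1])
            return None, None
        if rig.pose.tip[2] < rig.scene.volume_bounds[2][0]:
            break
    return "fail", "no_target"


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full state machine; deterministic given the seed."""
    rig = _Rig(config)
    steps = 0
    time_to_seal = float("nan")
    status, reason = "fail", ""

    def finish(status, reason):
        if status == "wholecell":
            rig.stage = "wholecell"
            rig.emit("wholecell", resistance=rig.model.resistance)
        else:
            rig.emit("fail", reason=reason)
        traces = pd.DataFrame(rig.traces)
        trajectory = pd.DataFrame(rig.trajectory_rows)
        result = ExperimentResult(
            status=status, fail_reason=reason, log=rig.log, traces=traces,
            trajectory=trajectory, steps=steps, time_to_seal=time_to_seal,
            tracked_errors=rig.tracked_errors)
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            rig.log.to_jsonl(out / "events.jsonl")
            traces.to_csv(out / "trace.csv", index=False)
            trajectory.to_csv(out / "trajectory.csv", index=False)
        return result

    err, why = _stage_positioning(rig)
    if err:
        return finish("fail", why)

    if config.mode == "blind":
        err, why = _stage_blind_descent(rig)
        if err:
            return finish("fail", why)
    else:
        rig.stage = "approach"
        out = _stage_approach(rig)
        err, why, approach_result = out
        steps = approach_result.step_count if approach_result else 0
        if err:
            return finish("fail", why)
        rig.stage = "engagement"
        err, why = _stage_engagement(rig)
        if err:
            return finish("fail", why)

    rig.stage = "seal"
    err, why, time_to_seal = _stage_seal(rig)
    if err:
        return finish("fail", why)

    rig.stage = "breakin"
    err, why = _stage_breakin(rig)
    if err:
        # a seal was obtained but break-in failed
        res = finish("fail", why)
        res.status = "seal_only"
        return res

    return finish("wholecell", "")


def run_batch(base_seed: int, n_seeds: int, mode: str = "targeted",
              config_overrides=None, keep_results: bool = False) -> pd.DataFrame:
    """Run seeds base..base+n-1 and tabulate per-seed outcomes + aggregates.

    With ``keep_results`` the per-seed :class:`ExperimentResult` objects are
    attached as ``df.attrs['results']`` (event logs for invariant checks).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    results = []
    for i in range(n_seeds):
        seed = int((base_seed * 100003 + i) % (2 ** 31 - 1))
        cfg = ExperimentConfig(seed=seed, mode=mode,
                               **(config_overrides or {}))
        res = run_experiment(cfg)
        if keep_results:
            results.append(res)
        log = res.log
        engaged = any(e["event"] == "engaged" for e in log.events)
        sealed = any(e["event"] == "sealed" for e in log.events)
        rows.append({
            "seed": seed, "status": res.status, "fail_reason": res.fail_reason,
            "engaged": engaged, "sealed": sealed,
            "wholecell": res.status == "wholecell",
            "steps": res.steps, "time_to_seal": res.time_to_seal,
            "max_step_um": (res.trajectory["step_length"]
                            [res.trajectory["event"] == "insert_step"].max()
                            if len(res.trajectory) else float("nan")),
            "max_tracking_error": (max(res.tracked_errors)
                                   if res.tracked_errors else float("nan")),
        })
    df = pd.DataFrame(rows)
    df.attrs["engagement_rate"] = float(df["engaged"].mean())
    df.attrs["seal_rate"] = float(df["sealed"].mean())
    df.attrs["wholecell_rate"] = float(df["wholecell"].mean())
    df.attrs["mean_steps"] = float(df["steps"].mean())
    df.attrs["mean_time_to_seal"] = float(df["time_to_seal"].mean())
    if keep_results:
        df.attrs["results"] = results
    return df
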