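"""Closed-loop visual-servo approach of the pipette to the target.

The entry trajectory is planned as a straight line through the target
along the pipette axis; the pipette is rapidly driven to a standoff point
200-300 um from the target and then advanced in small interleaved steps
(3-4 um, never more than half the smallest targeted soma diameter, so a
single step cannot push the target out of the tracking gate).  After
every step the target must be reacquired before the next step is
permitted.  Pipette internal pressure is staged with distance: high
(10-50 kPa) far from the cell to keep the tip clear, reduced to 5-10 kPa
within 20 um of the target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ApproachConfig", "PipettePose", "PlanningError", "ApproachResult",
           "plan_entry", "approach_step", "pressure_for_distance", "run_approach"]


class PlanningError(ValueError):
    pass


@dataclass
class ApproachConfig:
    standoff_distance: float = 250.0       # um, within the 200-300 band
    step_length: float = 3.5               # um, within 3-4
    near_cell_distance: float = 20.0       # um
    high_pressure: float = 25.0            # kPa, within 10-50
    low_pressure: float = 7.0              # kPa, within 5-10
    contact_distance: float = 5.0          # um, ~ cell radius
    max_manual_correction: float = 8.0     # um, single bounded final correction
    smallest_target_diameter: float = 7.0  # um, ~5-8
    max_lateral_correction: float = 3.5    # um per step
    min_axis_pitch_deg: float = 10.0
    max_axis_pitch_deg: float = 80.0
    step_budget_factor: float = 3.0

    def __post_init__(self):
        if self.step_length > self.smallest_target_diameter / 2.0 + 1e-9:
            raise PlanningError(
                "step_length must not exceed half the smallest target diameter")
        if not self.low_pressure < self.high_pressure:
            raise PlanningError("low_pressure must be below high_pressure")
        if not (self.contact_distance < self.near_cell_distance
                < self.standoff_distance):
            raise PlanningError("need contact < near_cell < standoff distances")


@dataclass
class PipettePose:
    tip: np.ndarray
    axis: np.ndarray          # unit vector, direction of travel

    def __post_init__(self):
        self.tip = np.asarray(self.tip, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)

    @property
    def depth(self) -> float:
        """um below the pial surface (z = 0); negative tip z is deeper."""
        return -min(self.tip[2], 0.0)


def plan_entry(pose: PipettePose, target, config: ApproachConfig):
    """Align the axis through the target and place the tip at standoff.

    Returns ``(lateral_move, standoff_point)``: the lateral alignment that
    puts the target on the pipette axis, and the point on the aligned axis
    at ``standoff_distance`` before the target.
    """
    target = np.asarray(target, dtype=float)
    if target[2] >= 0:
        raise PlanningError("target must be below the surface (z < 0)")
    pitch = np.degrees(np.arcsin(max(-1.0, min(1.0, -pose.axis[2]))))
    if not (config.min_axis_pitch_deg <= pitch <= config.max_axis_pitch_deg):
        raise PlanningError(
            f"axis pitch {pitch:.1f} deg outside manipulator range")
    d = target - pose.tip
    axial = float(d @ pose.axis)
    lateral_move = d - axial * pose.axis
    standoff_point = target - config.standoff_distance * pose.axis
    return lateral_move, standoff_point


def pressure_for_distance(distance: float, config: ApproachConfig) -> float:
    """Two-valued pressure staging: high far away, low within 20 um.

    The boundary at exactly ``near_cell_distance`` maps to the low setpoint
    (safer for the target).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return config.high_pressure if distance > config.near_cell_distance \
        else config.low_pressure


def approach_step(pose: PipettePose, target_position, config: ApproachConfig):
    """One re-aimed insertion step toward the tracked target position.

    The step direction passes through the updated target position; the
    lateral component of the re-aim is bounded per step.  Advances
    ``min(step_length, remaining distance)``.  Returns ``(new_pose,
    step_vector)``; the caller applies the tissue deformation.
    """
    target_position = np.asarray(target_position, dtype=float)
    d = target_position - pose.tip
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        return pose, np.zeros(3)
    direction = d / dist
    axial = float(direction @ pose.axis)
    lateral = direction - axial * pose.axis
    lat_norm = float(np.linalg.norm(lateral))
    advance = min(config.step_length, dist)
    if lat_norm * advance > config.max_lateral_correction:
        lateral *= config.max_lateral_correction / (lat_norm * advance)
        direction = axial * pose.axis + lateral
        direction = direction / np.linalg.norm(direction)
    step = advance * direction
    new_pose = PipettePose(tip=pose.tip + step, axis=direction)
    return new_pose, step


@dataclass
class ApproachResult:
    success: bool
    reason: str
    final_distance: float
    step_count: int
    corrected: bool
    trajectory: list = field(default_factory=list)  # dict rows per step


def run_approach(pose: PipettePose, track, config: ApproachConfig,
                 reacquire, apply_step, set_pressure, log=None):
    """Interleaved step-and-reacquire loop from standoff to contact.

    ``reacquire(track) -> track`` must re-detect the target (it may raise
    ``TargetLost``); ``apply_step(old_tip, new_tip)`` deforms the virtual
    tissue; ``set_pressure(kPa)`` stages the internal pressure.  A single
    bounded final correction (< ``max_manual_correction``) closes any
    residual gap and is flagged in the trajectory log.
    """
    from .tracking import TargetLost

    n_min = int(np.ceil((config.standoff_distance - config.contact_distance)
                        / config.step_length))
    budget = int(config.step_budget_factor * n_min)
    result = ApproachResult(False, "", np.inf, 0, False)

    def emit(event, **payload):
        if log is not None:
            log(event, **payload)

    steps = 0
    while True:
        target = track.last_position()
        dist = float(np.linalg.norm(target - pose.tip))
        set_pressure(pressure_for_distance(dist, config))
        if dist <= config.contact_distance:
            result.success = True
            result.reason = "contact"
            break
        if steps >= budget:
            result.reason = "step_budget_exceeded"
            break
        if track.status != "visible":
            result.reason = "target_not_visible"
            break
        new_pose, step = approach_step(pose, target, config)
        apply_step(pose.tip.copy(), new_pose.tip.copy())
        result.trajectory.append({
            "step": steps, "tip": new_pose.tip.tolist(),
            "target": target.tolist(), "distance": dist,
            "pressure": pressure_for_distance(dist, config),
            "step_length": float(np.linalg.norm(step)), "event": "insert_step",
        })
        emit("insert_step", step=steps, tip=new_pose.tip.tolist(),
             distance=dist)
        pose = new_pose
        steps += 1
        try:
            track = reacquire(track)
        except TargetLost:
            result.reason = "lost_target"
            result.step_count = steps
            result.final_distance = float(
                np.linalg.norm(track.last_position() - pose.tip))
            return pose, result
        emit("target_reacquired", step=steps,
             position=track.last_position().tolist())

    if not result.success:
        result.step_count = steps
        result.final_distance = dist
        return pose, result
    target = track.last_position()
    dist = float(np.linalg.norm(target - pose.tip))
    if 1e-6 < dist <= config.max_manual_correction:
        # single bounded correction to close the residual gap (flagged)
        old_tip = pose.tip.copy()
        pose = PipettePose(tip=target.copy(), axis=pose.axis)
        apply_step(old_tip, pose.tip.copy())
        result.corrected = True
        result.trajectory.append({
            "step": steps, "tip": pose.tip.tolist(), "target": target.tolist(),
            "distance": dist, "pressure": pressure_for_distance(0.0, config),
            "step_length": dist, "event": "manual_correction",
        })
        emit("manual_correction", distance=dist)
    result.step_count = steps
    result.final_distance = float(np.linalg.norm(track.last_position() - pose.tip))
    return pose, result
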