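"""Inter-frame correspondence for the selected target.

Because insertion steps are interleaved with position monitoring, the
per-step target migration stays below half the smallest soma diameter and
the correspondence problem can be solved locally: the track is matched to
the nearest detection within a small gate (no motion model).  Breathing
and heartbeat make the target periodically defocus and reappear at the
same point, so transient misses are tolerated (occluded) up to a miss
budget before the target is declared lost.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autofocus as af

__all__ = ["Track", "TargetLost", "associate", "update_track",
           "reacquire_after_step"]


class TargetLost(RuntimeError):
    """Raised when the target cannot be reacquired within the miss budget."""


@dataclass
class Track:
    target_id: int
    positions: list = field(default_factory=list)   # (t, x, y, z)
    cfs_history: list = field(default_factory=list)
    last_object: object = None
    search_radius: float = 3.5       # um; default = half the smallest soma diameter (~7 um)
    status: str = "visible"          # visible | occluded | lost
    consecutive_misses: int = 0
    miss_budget: int = 5
    reference_cfs: float = None      # CFS at acquisition, for focus-drift detection

    def last_position(self) -> np.ndarray:
        t, x, y, z = self.positions[-1]
        return np.array([x, y, z])

    def append(self, t, x, y, z, cfs=None):
        if self.positions and t < self.positions[-1][0]:
            raise ValueError("timestamps must be non-decreasing")
        self.positions.append((float(t), float(x), float(y), float(z)))
        if cfs is not None:
            self.cfs_history.append(float(cfs))
            if self.reference_cfs is None:
                self.reference_cfs = float(cfs)


def associate(track: Track, detections, geometry):
    """Match the track to the nearest in-gate detection.

    The detection whose centroid (converted to um through the frame
    geometry) is nearest to the track's last (x, y) and within
    ``search_radius`` wins; ties are broken by larger CFS, then lower
    label.  Returns None when nothing qualifies.
    """
    if not track.positions:
        return None
    x0, y0, _ = track.last_position()
    best = None
    for det in detections:
        x, y = geometry.pixel_to_um(det.centroid[0], det.centroid[1])
        d = float(np.hypot(x - x0, y - y0))
        if d > track.search_radius:
            continue
        cfs = det.cfs if det.cfs_usable else -np.inf
        key = (d, -cfs, det.label)
        if best is None or key < best[0]:
            best = (key, det, (float(x), float(y)))
    if best is None:
        return None
    det, xy = best[1], best[2]
    det._matched_um = xy  # stashed for update_track
    return det


def update_track(track: Track, match, focal_z: float, t: float) -> Track:
    """Fold one association result into the track state."""
    if match is not None:
        x, y = getattr(match, "_matched_um", match.centroid)
        track.append(t, x, y, focal_z, cfs=match.cfs)
        track.last_object = match
        track.consecutive_misses = 0
        track.status = "visible"
    else:
        track.consecutive_misses += 1
        track.status = ("occluded" if track.consecutive_misses <= track.miss_budget
                        else "lost")
    return track


# CFS fraction of the acquisition reference below which a lateral match is
# treated as defocused and an axial sweep is triggered anyway.
REFOCUS_CFS_FRACTION = 0.65


def reacquire_after_step(track: Track, objective, acquire, segment,
                         af_params: af.AutofocusParams = None, t: float = 0.0):
    """Re-detect the target after one insertion step.

    Must be called once after every insertion step; the servo may not step
    again until this returns with the track visible.  A failed lateral
    match (or a matched object whose CFS collapsed, indicating axial
    migration) triggers an autofocus sweep before the miss is counted.
    Raises :class:`TargetLost` when the miss budget is exhausted.
    """
    frame = acquire(objective.z)
    detections, geom = segment(frame)
    match = associate(track, detections, geom)
    defocused = (match is not None and track.reference_cfs is not None
                 and match.cfs_usable
                 and match.cfs < REFOCUS_CFS_FRACTION * track.reference_cfs)
    if match is not None and not defocused:
        update_track(track, match, objective.z, t)
        return track
    # lateral miss or defocus: the target likely migrated axially
    sweep = af.autofocus_target(track, objective, acquire, segment,
                                af_params)
    if not sweep.target_lost:
        frame = acquire(objective.z)
        detections, geom = segment(frame)
        match = associate(track, detections, geom)
    else:
        match = None
    update_track(track, match, objective.z, t)
    if track.status == "lost":
        raise TargetLost(f"target {track.target_id} lost at t={t:.2f}s")
    return track
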