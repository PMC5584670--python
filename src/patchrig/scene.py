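"""Virtual two-photon preparation.

Simulates the objects a targeted patch-clamp robot has to see and perturb:
sparse fluorescent somata in a 3D volume, the dye-filled pipette cone,
viscoelastic tissue deformation caused by pipette insertion steps, and
periodic breathing/heartbeat motion.  Frames are rendered as two 16-bit
channels (red, green) with a simple two-photon defocus model: lateral blur
grows linearly with defocus and visibility decays with a Gaussian axial
envelope, so objects a few micrometres off the focal plane disappear.

Coordinates: right-handed volume frame in micrometres, z negative going
deeper below the pial surface.  Pixel coordinates are 0-based row-major;
the frame <-> volume mapping is defined by ``FrameGeometry``.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy.special import erf

__all__ = [
    "Cell",
    "DeformationParams",
    "PhysioMotionParams",
    "PipetteGeometry",
    "ImagingParams",
    "FrameGeometry",
    "Frame",
    "Scene",
    "SceneValidationError",
    "make_scene",
    "render_frame",
    "apply_insertion_step",
    "write_stack",
    "read_stack",
]

MAX_INTENSITY = 65535


class SceneValidationError(ValueError):
    """Raised when a scene configuration violates an invariant."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise SceneValidationError("zero-length axis vector")
    return v / n


@dataclass
class Cell:
    """A fluorescent soma (diameter ~5-20 um)."""

    id: int
    center: np.ndarray          # current position, um
    diameter: float             # um
    channel: str                # 'red' | 'green'
    peak_intensity: float       # 16-bit units
    rest_center: np.ndarray     # pre-deformation anchor, um

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.rest_center = np.asarray(self.rest_center, dtype=float)
        if self.diameter <= 0:
            raise SceneValidationError(f"cell {self.id}: diameter must be > 0")
        if not (0 < self.peak_intensity <= MAX_INTENSITY):
            raise SceneValidationError(
                f"cell {self.id}: peak_intensity outside (0, {MAX_INTENSITY}]")
        if self.channel not in ("red", "green"):
            raise SceneValidationError(f"cell {self.id}: bad channel {self.channel!r}")


@dataclass
class DeformationParams:
    """Exponential-in-distance push with partial viscoelastic recoil.

    An insertion step of vector ``s`` displaces a cell at distance ``r`` from
    the (pre-step) tip by ``push_gain * exp(-r / decay_length) * s``.  A
    fraction ``relaxation_fraction`` of that displacement then decays back
    toward rest with time constant ``relaxation_tau``.
    """

    push_gain: float = 0.5
    decay_length: float = 30.0       # um
    relaxation_fraction: float = 0.5
    relaxation_tau: float = 5.0      # s

    def __post_init__(self):
        if not 0.0 <= self.push_gain <= 1.0:
            raise SceneValidationError("push_gain must be in [0, 1]")
        if self.decay_length <= 0:
            raise SceneValidationError("decay_length must be > 0")
        if not 0.0 <= self.relaxation_fraction <= 1.0:
            raise SceneValidationError("relaxation_fraction must be in [0, 1]")


@dataclass
class PhysioMotionParams:
    """Breathing + heartbeat oscillation applied to every cell.

    Both components are zero-mean sinusoids along ``motion_axis``, emulating
    targets that periodically defocus and reappear at the same point.
    """

    breathing_amplitude: float = 0.8     # um
    breathing_period: float = 0.4        # s (~2.5 Hz, anesthetized mouse)
    heartbeat_amplitude: float = 0.25    # um
    heartbeat_period: float = 0.125      # s (~8 Hz)
    motion_axis: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.3, 0.9]))

    def __post_init__(self):
        if self.breathing_amplitude < 0 or self.heartbeat_amplitude < 0:
            raise SceneValidationError("motion amplitudes must be >= 0")
        if self.breathing_period <= 0 or self.heartbeat_period <= 0:
            raise SceneValidationError("motion periods must be > 0")
        self.motion_axis = _unit(self.motion_axis)

    def offset(self, t: float) -> np.ndarray:
        a = self.breathing_amplitude * np.sin(2 * np.pi * t / self.breathing_period)
        b = self.heartbeat_amplitude * np.sin(2 * np.pi * t / self.heartbeat_period)
        return (a + b) * self.motion_axis


@dataclass
class PipetteGeometry:
    """Dye-filled pipette modelled as a cone behind the tip."""

    tip: np.ndarray
    axis: np.ndarray                 # unit vector, direction of travel
    tip_diameter: float = 1.0        # um
    cone_half_angle: float = 10.0    # degrees
    dye_channel: str = "red"
    dye_intensity: float = 30000.0
    shank_length: float = 150.0      # rendered extent behind the tip, um

    def __post_init__(self):
        self.tip = np.asarray(self.tip, dtype=float)
        self.axis = _unit(self.axis)
        if self.tip_diameter <= 0:
            raise SceneValidationError("tip_diameter must be > 0")
        if self.dye_channel not in ("red", "green"):
            raise SceneValidationError(f"bad dye_channel {self.dye_channel!r}")


@dataclass
class ImagingParams:
    """Two-photon image formation model."""

    field_of_view: tuple = (100.0, 100.0)   # um (x, y)
    pixels: tuple = (128, 128)              # (width, height)
    z_sigma0: float = 2.0                   # in-focus lateral blur, um
    z_defocus_rate: float = 0.1            # lateral blur growth per um defocus
    axial_visibility_sigma: float = 2.5     # um; small => shallow depth of field
    shot_noise_scale: float = 0.1           # photons per intensity count
    read_noise_sd: float = 60.0             # intensity counts
    background_level: float = 5000.0        # neuropil/autofluorescence counts
    background_gradient: tuple = (0.15, 0.08)  # relative slope across the FOV
    bit_depth: int = 16

    def __post_init__(self):
        if min(self.pixels) <= 0:
            raise SceneValidationError("pixels must be positive")
        if self.axial_visibility_sigma <= 0:
            raise SceneValidationError("axial_visibility_sigma must be > 0")


@dataclass
class FrameGeometry:
    """Mapping between pixel indices and volume coordinates.

    ``stage_xy`` is the volume (x, y) of the field-of-view centre.
    """

    stage_xy: tuple
    field_of_view: tuple
    pixels: tuple

    @property
    def px_size(self) -> tuple:
        return (self.field_of_view[0] / self.pixels[0],
                self.field_of_view[1] / self.pixels[1])

    def pixel_to_um(self, col, row):
        """(col, row) pixel centre -> volume (x, y) um."""
        w, h = self.pixels
        pw, ph = self.px_size
        x = self.stage_xy[0] + (np.asarray(col) + 0.5 - w / 2.0) * pw
        y = self.stage_xy[1] + (np.asarray(row) + 0.5 - h / 2.0) * ph
        return x, y

    def um_to_pixel(self, x, y):
        """Volume (x, y) um -> fractional (col, row)."""
        w, h = self.pixels
        pw, ph = self.px_size
        col = (np.asarray(x) - self.stage_xy[0]) / pw + w / 2.0 - 0.5
        row = (np.asarray(y) - self.stage_xy[1]) / ph + h / 2.0 - 0.5
        return col, row


@dataclass
class Frame:
    """One time-stamped two-channel 16-bit frame."""

    red: np.ndarray
    green: np.ndarray
    focal_z: float
    timestamp: float
    stage_xy: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.red.shape != self.green.shape:
            raise SceneValidationError("channel shape mismatch")

    def channel(self, name: str) -> np.ndarray:
        return {"red": self.red, "green": self.green}[name]

    def geometry(self, imaging: ImagingParams) -> FrameGeometry:
        return FrameGeometry(tuple(self.stage_xy), tuple(imaging.field_of_view),
                             tuple(imaging.pixels))


@dataclass
class _Transient:
    cell_id: int
    vector: np.ndarray  # decaying part of a displacement
    t0: float


@dataclass
class Scene:
    cells: list
    volume_bounds: np.ndarray        # shape (3, 2): [[xmin, xmax], ...]
    pipette: PipetteGeometry
    deformation: DeformationParams
    motion: PhysioMotionParams
    imaging: ImagingParams
    rng_seed: int
    max_insertion_step: float = 8.0  # um; servo must never request more
    transients: list = field(default_factory=list)
    _rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        self.volume_bounds = np.asarray(self.volume_bounds, dtype=float)
        if self._rng is None:
            self._rng = np.random.default_rng(self.rng_seed)
        for c in self.cells:
            lo, hi = self.volume_bounds[:, 0], self.volume_bounds[:, 1]
            if np.any(c.rest_center < lo) or np.any(c.rest_center > hi):
                raise SceneValidationError(
                    f"cell {c.id} rest_center {c.rest_center.tolist()} outside volume bounds")

    def cell_position(self, cell: Cell, t: float) -> np.ndarray:
        """Effective position at time t: deformation transients + physiology."""
        p = cell.center.copy()
        for tr in self.transients:
            if tr.cell_id == cell.id and t >= tr.t0:
                p += tr.vector * np.exp(-(t - tr.t0) / self.deformation.relaxation_tau)
        return p + self.motion.offset(t)

    def find_cell(self, cell_id: int) -> Cell:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)


_DEFAULT_VOLUME = [[-60.0, 60.0], [-60.0, 60.0], [-170.0, 10.0]]


def make_scene(config: dict, seed: int) -> Scene:
    """Build a scene from a plain config mapping (YAML/JSON friendly).

    Deterministic for a fixed (config, seed); every stochastic draw made by
    the scene derives from ``seed``.
    """
    cells = []
    for i, c in enumerate(config.get("cells", [])):
        center = np.asarray(c["center"], dtype=float)
        cells.append(Cell(
            id=c.get("id", i),
            center=center,
            diameter=float(c.get("diameter", 10.0)),
            channel=c.get("channel", "green"),
            peak_intensity=float(c.get("peak_intensity", 40000.0)),
            rest_center=center.copy(),
        ))
    if not cells:
        raise SceneValidationError("config must specify at least one cell")
    pip_cfg = dict(config.get("pipette", {}))
    pip_cfg.setdefault("tip", [0.0, 0.0, 50.0])
    pip_cfg.setdefault("axis", [0.819, 0.0, -0.574])
    pipette = PipetteGeometry(**pip_cfg)
    scene = Scene(
        cells=cells,
        volume_bounds=np.asarray(config.get("volume_bounds", _DEFAULT_VOLUME)),
        pipette=pipette,
        deformation=DeformationParams(**config.get("deformation", {})),
        motion=PhysioMotionParams(**config.get("motion", {})),
        imaging=ImagingParams(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in config.get("imaging", {}).items()}),
        rng_seed=int(seed),
        max_insertion_step=float(config.get("max_insertion_step", 8.0)),
    )
    return scene


def _background_plane(geom: FrameGeometry, imaging: ImagingParams) -> np.ndarray:
    """Smooth neuropil/autofluorescence background with a gentle gradient
    (the non-uniform lighting the background-correction stage removes)."""
    w, h = geom.pixels
    if imaging.background_level <= 0:
        return np.zeros((h, w), dtype=float)
    gx, gy = imaging.background_gradient
    u = (np.arange(w) + 0.5) / w - 0.5
    v = (np.arange(h) + 0.5) / h - 0.5
    return imaging.background_level * (1.0 + gx * u[None, :] + gy * v[:, None])


def _add_cell_blob(img, geom: FrameGeometry, imaging: ImagingParams,
                   pos, diameter, peak, focal_z):
    dz = abs(pos[2] - focal_z)
    amp = peak * np.exp(-dz ** 2 / (2.0 * imaging.axial_visibility_sigma ** 2))
    if amp < 0.5:
        return
    sigma = imaging.z_sigma0 + imaging.z_defocus_rate * dz
    h, w = img.shape
    cols = np.arange(w)
    rows = np.arange(h)
    xs, _ = geom.pixel_to_um(cols, np.zeros_like(cols))
    _, ys = geom.pixel_to_um(np.zeros_like(rows), rows)
    dx = xs[None, :] - pos[0]
    dy = ys[:, None] - pos[1]
    r = np.hypot(dx, dy)
    # soma disk convolved with the defocus blur: erf edge profile whose core
    # amplitude erodes once the blur approaches the soma radius; normalized
    # so the in-focus centre carries exactly peak_intensity
    R = diameter / 2.0
    core = 1.0 - np.exp(-R ** 2 / (2.0 * sigma ** 2))
    core0 = 1.0 - np.exp(-R ** 2 / (2.0 * imaging.z_sigma0 ** 2))
    edge = 0.5 * (1.0 - erf((r - R) / (sigma * np.sqrt(2.0))))
    center = 0.5 * (1.0 - erf(-R / (sigma * np.sqrt(2.0))))
    img += amp * (core / core0) * edge / center


def _add_pipette(img, geom: FrameGeometry, imaging: ImagingParams,
                 pip: PipetteGeometry, focal_z):
    h, w = img.shape
    cols = np.arange(w)
    rows = np.arange(h)
    xs, _ = geom.pixel_to_um(cols, np.zeros_like(cols))
    _, ys = geom.pixel_to_um(np.zeros_like(rows), rows)
    X, Y = np.meshgrid(xs, ys)
    P = np.stack([X, Y, np.full_like(X, focal_z)], axis=-1)  # points in the focal plane
    V = P - pip.tip
    s = V @ (-pip.axis)              # distance behind the tip along the shank
    lat = np.linalg.norm(V + s[..., None] * pip.axis[None, None, :], axis=-1)
    radius = pip.tip_diameter / 2.0 + np.tan(np.radians(pip.cone_half_angle)) * np.clip(s, 0, None)
    inside = (s >= 0) & (s <= pip.shank_length) & (lat <= radius)
    img[inside] = np.maximum(img[inside], pip.dye_intensity)
    # defocused glow at the tip itself
    dzt = abs(pip.tip[2] - focal_z)
    amp = pip.dye_intensity * np.exp(-dzt ** 2 / (2.0 * imaging.axial_visibility_sigma ** 2))
    if amp >= 0.5:
        sigma = imaging.z_sigma0 + imaging.z_defocus_rate * dzt
        rt = np.hypot(X - pip.tip[0], Y - pip.tip[1])
        img += amp * np.exp(-rt ** 2 / (2.0 * max(sigma, pip.tip_diameter / 2.0) ** 2))


def render_frame(scene: Scene, focal_z: float, t: float = 0.0,
                 noise: bool = False, stage_xy: tuple = (0.0, 0.0),
                 include_pipette: bool = True) -> Frame:
    """Render one two-channel frame at the given focal plane and time."""
    imaging = scene.imaging
    w, h = imaging.pixels
    geom = FrameGeometry(tuple(stage_xy), tuple(imaging.field_of_view), (w, h))
    bg = _background_plane(geom, imaging)
    planes = {"red": bg.copy(), "green": bg.copy()}
    for cell in scene.cells:
        pos = scene.cell_position(cell, t)
        _add_cell_blob(planes[cell.channel], geom, imaging, pos,
                       cell.diameter, cell.peak_intensity, focal_z)
    if include_pipette:
        _add_pipette(planes[scene.pipette.dye_channel], geom, imaging,
                     scene.pipette, focal_z)
    out = {}
    for name, img in planes.items():
        if noise:
            img = _apply_noise(img, imaging, scene._rng)
        out[name] = np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)
    return Frame(red=out["red"], green=out["green"], focal_z=float(focal_z),
                 timestamp=float(t), stage_xy=tuple(stage_xy))


_POISSON_GAUSSIAN_CROSSOVER = 1000.0  # expected photon count above which Gaussian approx is used


def _apply_noise(img, imaging: ImagingParams, rng):
    g = imaging.shot_noise_scale  # photons per intensity count
    out = img.copy()
    if g > 0:
        lam = img * g
        small = lam < _POISSON_GAUSSIAN_CROSSOVER
        if np.any(small):
            out[small] = rng.poisson(lam[small]) / g
        big = ~small
        if np.any(big):
            out[big] = img[big] + rng.standard_normal(int(big.sum())) * np.sqrt(img[big] / g)
    if imaging.read_noise_sd > 0:
        out = out + rng.standard_normal(img.shape) * imaging.read_noise_sd
    return out


def apply_insertion_step(scene: Scene, old_tip, new_tip, t: float = 0.0) -> Scene:
    """Advance the pipette tip and deform the tissue.

    Every cell is displaced by ``push_gain * exp(-r/decay_length) * step``
    where ``r`` is its distance from the pre-step tip.  A fraction
    ``relaxation_fraction`` of the displacement is registered as a transient
    that recoils toward rest with time constant ``relaxation_tau``.
    Returns a new Scene; the input is not mutated.
    """
    old_tip = np.asarray(old_tip, dtype=float)
    new_tip = np.asarray(new_tip, dtype=float)
    step = new_tip - old_tip
    step_len = np.linalg.norm(step)
    if step_len > scene.max_insertion_step + 1e-9:
        raise ValueError(
            f"insertion step {step_len:.2f} um exceeds max {scene.max_insertion_step} um")
    new = copy.copy(scene)
    new.cells = [replace(c, center=c.center.copy(), rest_center=c.rest_center.copy())
                 for c in scene.cells]
    new.transients = list(scene.transients)
    new.pipette = replace(scene.pipette, tip=new_tip.copy(), axis=scene.pipette.axis.copy())
    if step_len == 0:
        return new
    d = scene.deformation
    for c in new.cells:
        r = np.linalg.norm(c.center - old_tip)
        disp = d.push_gain * np.exp(-r / d.decay_length) * step
        c.center = c.center + (1.0 - d.relaxation_fraction) * disp
        if d.relaxation_fraction > 0:
            new.transients.append(_Transient(c.id, d.relaxation_fraction * disp, t))
    return new


class StackIOError(IOError):
    """Raised when a TIFF stack cannot be read; carries the frame index."""

    def __init__(self, msg, frame_index=None):
        super().__init__(msg)
        self.frame_index = frame_index


def write_stack(frames, path) -> None:
    """Write frames as a multi-page 16-bit TIFF.

    Dialect: two pages per frame (red then green); the red page's
    ImageDescription tag holds the per-frame metadata as JSON.
    """
    with tifffile.TiffWriter(str(path)) as tif:
        for fr in frames:
            meta = json.dumps({"focal_z": fr.focal_z, "timestamp": fr.timestamp,
                               "stage_xy": list(fr.stage_xy), "channel": "red"})
            tif.write(fr.red, description=meta, contiguous=False)
            tif.write(fr.green, description=json.dumps({"channel": "green"}),
                      contiguous=False)


def read_stack(path):
    """Read a stack written by :func:`write_stack`; lossless round trip."""
    frames = []
    try:
        with tifffile.TiffFile(str(path)) as tif:
            pages = tif.pages
            n = len(pages)
            if n % 2 != 0:
                raise StackIOError(f"odd page count {n}: not a two-channel stack",
                                   frame_index=n // 2)
            for i in range(0, n, 2):
                try:
                    red = pages[i].asarray()
                    green = pages[i + 1].asarray()
                    desc = pages[i].tags.get("ImageDescription")
                    meta = json.loads(desc.value) if desc is not None else {}
                except StackIOError:
                    raise
                except Exception as exc:  # truncated page, bad JSON, ...
                    raise StackIOError(f"frame {i // 2}: {exc}", frame_index=i // 2) from exc
                frames.append(Frame(
                    red=red, green=green,
                    focal_z=float(meta.get("focal_z", 0.0)),
                    timestamp=float(meta.get("timestamp", 0.0)),
                    stage_xy=tuple(meta.get("stage_xy", (0.0, 0.0))),
                ))
    except StackIOError:
        raise
    except Exception as exc:
        raise StackIOError(f"cannot read stack {path}: {exc}") from exc
    return frames
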