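"""On-line quantification of two-photon frames.

Pipeline (in order): channel separation, background correction, Otsu
interclass-variance thresholding, hole filling, per-object erosion, and
particle analysis.  Each detected particle carries the contrast-focus
score

    CFS_i = (<I>_internal,i - <I>_external,i) / <I>_internal,i

where the averages run over the eroded interior of the particle and over
the ring between the original and eroded boundaries.  The CFS doubles as
a detection-contrast measure and as the focus metric maximized by the
autofocus loop.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform

from .scene import Frame, MAX_INTENSITY

__all__ = [
    "DetectedObject",
    "SegmentationConfig",
    "split_channels",
    "background_correct",
    "otsu_threshold",
    "fill_holes",
    "erode",
    "particle_analysis",
    "compute_cfs",
    "segment_frame",
]

CFS_UNDEFINED = float("nan")


@dataclass
class SegmentationConfig:
    channel_mode: str = "green"        # 'red' | 'green' | 'sum'
    background_window: int = 48        # px; must exceed ~2x a cell diameter
    erosion_radius: int = 2            # px
    min_particle_area: int = 20        # px
    max_particle_area: int = 1200      # px
    max_foreground_fraction: float = 0.2
    # above this mask fraction the Otsu cut sits inside the noise floor
    # (percolating speckle, no real foreground) and the frame is degenerate

    def __post_init__(self):
        if self.erosion_radius < 1:
            raise ValueError("erosion_radius must be >= 1")
        if self.channel_mode not in ("red", "green", "sum"):
            raise ValueError(f"bad channel_mode {self.channel_mode!r}")


@dataclass
class DetectedObject:
    """One segmented particle and its contrast-focus score."""

    label: int
    contour: np.ndarray              # ordered boundary, (N, 2) of (row, col)
    area: int
    centroid: tuple                  # sub-pixel (x, y) = (col, row), binary centre of mass
    bbox: tuple                      # (min_row, min_col, max_row, max_col), half-open
    internal_mask: np.ndarray        # bool, full-frame
    external_ring: np.ndarray        # bool, full-frame; disjoint from internal_mask
    cfs: float = CFS_UNDEFINED

    @property
    def cfs_usable(self) -> bool:
        return not math.isnan(self.cfs)


def split_channels(frame: Frame, mode: str) -> np.ndarray:
    """Select a single plane or the saturating red+green sum."""
    if mode == "sum":
        s = frame.red.astype(np.uint32) + frame.green.astype(np.uint32)
        return np.minimum(s, MAX_INTENSITY).astype(np.uint16)
    return frame.channel(mode)


def background_correct(image: np.ndarray, window: int = 48) -> np.ndarray:
    """Subtract a smooth local-background estimate, flooring at zero.

    The background is a large-window local median, computed on a
    block-reduced copy and bilinearly resized back (a full-resolution
    median at this window size would dominate the per-frame budget).
    A constant image maps to all zeros.
    """
    img = np.asarray(image, dtype=float)
    ds = max(1, window // 8)
    pad = (-img.shape[0]) % ds, (-img.shape[1]) % ds
    padded = np.pad(img, ((0, pad[0]), (0, pad[1])), mode="edge")
    small = transform.downscale_local_mean(padded, (ds, ds))
    size = max(3, int(round(window / ds)) | 1)
    bg_small = ndimage.median_filter(small, size=size, mode="nearest")
    bg = transform.resize(bg_small, padded.shape, order=1, mode="edge",
                          anti_aliasing=False)[:img.shape[0], :img.shape[1]]
    out = np.clip(img - bg, 0, MAX_INTENSITY)
    return np.rint(out).astype(np.uint16)


def _exact_between_class_key(n0, s0, n, s):
    """Exact integer (numerator, denominator) proportional to between-class variance."""
    num = (s0 * n - s * n0) ** 2
    den = n0 * (n - n0)
    return num, den


def otsu_threshold(image: np.ndarray):
    """Otsu interclass-variance threshold.

    Returns ``(threshold, mask)`` with ``mask = image > threshold``.  The
    threshold maximizes the between-class variance over the image
    histogram; ties are broken toward the lowest threshold.  A constant
    image is degenerate: returns ``(None, all-False mask)``.

    The maximizer is located with a fast float64 scan and then refined by
    exact integer arithmetic among near-tied candidates, so the result is
    the exact exhaustive maximizer.
    """
    img = np.asarray(image)
    if img.dtype.kind == "f":
        img = np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)
    vals, counts = np.unique(img.ravel(), return_counts=True)
    if vals.size < 2:
        return None, np.zeros(img.shape, dtype=bool)
    n = counts.sum()
    s = int((vals.astype(np.int64) * counts).sum())
    n0 = np.cumsum(counts)[:-1].astype(float)       # class 0 = values <= vals[k]
    s0 = np.cumsum(vals.astype(np.int64) * counts)[:-1].astype(float)
    n1 = n - n0
    sigma_b = (s0 * n - s * n0) ** 2 / (n0 * n1)    # proportional to w0*w1*(mu0-mu1)^2
    best = float(sigma_b.max())
    cand = np.flatnonzero(sigma_b >= best * (1.0 - 1e-9))
    if cand.size > 1:
        n0i = np.cumsum(counts)[:-1]
        s0i = np.cumsum(vals.astype(object) * counts)[:-1]
        best_k, best_key = None, None
        for k in cand:
            key = _exact_between_class_key(int(n0i[k]), int(s0i[k]), int(n), s)
            if best_key is None or key[0] * best_key[1] > best_key[0] * key[1]:
                best_key, best_k = key, k
        k = int(best_k)
    else:
        k = int(cand[0])
    threshold = int(vals[k])
    return threshold, img > threshold


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the border (4-connected holes)."""
    return ndimage.binary_fill_holes(mask)


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological erosion with a disk structuring element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndimage.binary_erosion(mask, structure=morphology.disk(radius),
                                  border_value=0)


def _component_contour(comp_mask: np.ndarray) -> np.ndarray:
    padded = np.pad(comp_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    contour = max(contours, key=len) - 1.0  # undo padding
    return contour


def particle_analysis(mask: np.ndarray, image: np.ndarray,
                      config: SegmentationConfig):
    """Label connected components (8-connectivity) and measure each particle.

    Components with area outside [min, max] are discarded.  Labels are
    re-numbered 1.. in raster-scan order of first encounter.  The centroid
    is the binary centre of mass.  The internal mask is the per-component
    erosion (disk of ``erosion_radius``); the external ring is the rest of
    the component.
    """
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    objects = []
    footprint = morphology.disk(config.erosion_radius)
    next_label = 1
    for sl, lab in zip(ndimage.find_objects(labels),
                       range(1, labels.max() + 1)):
        if sl is None:
            continue
        comp_local = labels[sl] == lab
        area = int(comp_local.sum())
        if not (config.min_particle_area <= area <= config.max_particle_area):
            continue
        rows, cols = np.nonzero(comp_local)
        r0, c0 = sl[0].start, sl[1].start
        centroid = (float(cols.mean() + c0), float(rows.mean() + r0))  # (x, y)
        bbox = (r0, c0, sl[0].stop, sl[1].stop)
        internal_local = ndimage.binary_erosion(comp_local, structure=footprint,
                                                border_value=0)
        internal = np.zeros(mask.shape, dtype=bool)
        internal[sl] = internal_local
        comp = np.zeros(mask.shape, dtype=bool)
        comp[sl] = comp_local
        ring = comp & ~internal
        contour = _component_contour(comp_local)
        if contour.size:
            contour = contour + np.array([r0, c0], dtype=float)
        objects.append(DetectedObject(
            label=next_label, contour=contour, area=area, centroid=centroid,
            bbox=bbox, internal_mask=internal, external_ring=ring))
        next_label += 1
    return objects


def compute_cfs(image: np.ndarray, obj: DetectedObject) -> float:
    """Contrast-focus score of one object on the given intensity image.

    Returns NaN (object unusable for focus) when the interior mean is zero
    or either region is empty.
    """
    if not obj.internal_mask.any() or not obj.external_ring.any():
        return CFS_UNDEFINED
    mi = float(image[obj.internal_mask].mean())
    if mi == 0.0:
        return CFS_UNDEFINED
    me = float(image[obj.external_ring].mean())
    return (mi - me) / mi


def segment_frame(frame: Frame, config: SegmentationConfig):
    """Run the full segmentation chain and attach a CFS to every object.

    The CFS is measured on the selected channel prior to background
    correction (intensities of the original image are probed through the
    segment masks).  Returns objects sorted by label; deterministic for a
    fixed frame and config.
    """
    channel = split_channels(frame, config.channel_mode)
    corrected = background_correct(channel, config.background_window)
    threshold, mask = otsu_threshold(corrected)
    if threshold is None or mask.mean() > config.max_foreground_fraction:
        return []
    mask = fill_holes(mask)
    objects = particle_analysis(mask, channel, config)
    for obj in objects:
        obj.cfs = compute_cfs(channel, obj)
    return objects
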