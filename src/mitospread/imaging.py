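"""Image operations: segmentation, particle analysis, projection, ROI series.

Turns raw grayscale microscopy into the records the dispersion and
morphometry stages consume: a binary mask (Otsu or fixed threshold),
connected-component particles with centroids and calibrated areas,
arc-length positions along a manually traced axon, translation registration
of fundus frame stacks, and per-day ROI intensity ratios.

Conventions: 0-based pixel indices, 8-connected components, mask (not
intensity-weighted) centroids, and half-open compartments downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import DegenerateImageError, ParameterError
from .trace import AxonTrace

__all__ = [
    "AxonTrace",
    "ParticleSet",
    "RoiIntensitySeries",
    "binarize",
    "find_particles",
    "straighten_and_project",
    "register_stack",
    "measure_roi_series",
    "count_particles_2d",
    "DEFAULT_MAX_OFFSET_UM",
    "DEFAULT_ROI_SIZE_PX",
]

#: Gate for projecting particles onto a trace: particles farther than this
#: from the path are treated as belonging to another axon and excluded
#: (analysis assumes a single axon that does not overlap with others).
DEFAULT_MAX_OFFSET_UM = 5.0

#: Side length of the square photometry ROIs, in pixels.
DEFAULT_ROI_SIZE_PX = 200


@dataclass
class ParticleSet:
    """Detected particles: 2-D centroids, areas, optional 1-D positions.

    ``positions_um`` is present only after projection onto a trace, in which
    case all arrays are sorted by position. ``n_filtered_out`` counts
    components discarded by the area gate; ``n_offpath`` counts particles
    dropped by the projection distance gate.
    """

    centroids_px: np.ndarray
    areas_um2: np.ndarray
    positions_um: np.ndarray | None = None
    source_image_id: str | None = None
    n_filtered_out: int = 0
    n_offpath: int = 0

    def __post_init__(self) -> None:
        self.centroids_px = np.asarray(self.centroids_px,
                                       dtype=float).reshape(-1, 2)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if np.any(self.areas_um2 <= 0):
            raise ParameterError("particle areas must be > 0")
        if self.positions_um is not None:
            self.positions_um = np.asarray(self.positions_um, dtype=float)

    def __len__(self) -> int:
        return len(self.areas_um2)


@dataclass
class RoiIntensitySeries:
    """Per-day mean ROI intensities, normalized to the day-0 baseline.

    ``mean_intensity`` has shape (n_days, n_rois); ``ratio_to_baseline`` is
    the per-day mean over ROIs divided by the day-0 value, so day 0 is
    exactly 1.
    """

    days: list
    roi_boxes: list[tuple[int, int]]
    roi_size_px: int
    mean_intensity: np.ndarray
    ratio_to_baseline: np.ndarray


def binarize(image: np.ndarray, method: str = "otsu",
             manual_threshold: float | None = None) -> np.ndarray:
    """Threshold a 2-D grayscale image; foreground is strictly above.

    ``method="otsu"`` computes the Otsu threshold; ``method="fixed"`` uses
    ``manual_threshold``. A constant image has no Otsu threshold and raises
    :class:`DegenerateImageError`.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ParameterError("binarize expects a 2-D grayscale image")
    if method == "otsu":
        if img.min() == img.max():
            raise DegenerateImageError(
                "constant image: Otsu threshold undefined")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if manual_threshold is None:
            raise ParameterError("fixed method needs manual_threshold")
        thr = manual_threshold
    else:
        raise ParameterError(f"unknown binarization method {method!r}")
    return img > thr


def find_particles(mask: np.ndarray, pixel_size_um: float,
                   min_area_um2: float | None = None,
                   max_area_um2: float | None = None,
                   source_image_id: str | None = None) -> ParticleSet:
    """8-connected component analysis of a binary mask.

    Per component: mask centroid (intensity-unweighted) and pixel-count area
    scaled by ``pixel_size_um**2``. Components outside [min, max] area are
    discarded and counted in ``n_filtered_out``. The default minimum is two
    pixels' worth of area, suppressing single-pixel noise.
    """
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be > 0")
    if min_area_um2 is None:
        min_area_um2 = 2 * pixel_size_um ** 2
    if min_area_um2 < 0:
        raise ParameterError("min_area_um2 must be >= 0")
    labels, n = ndimage.label(np.asarray(mask, bool), structure=np.ones((3, 3)))
    if n == 0:
        return ParticleSet(np.empty((0, 2)), np.empty(0),
                           source_image_id=source_image_id)
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    areas = sizes * pixel_size_um ** 2
    keep = areas >= min_area_um2
    if max_area_um2 is not None:
        keep &= areas <= max_area_um2
    centroids = np.asarray(ndimage.center_of_mass(
        np.ones_like(labels), labels, idx[keep])).reshape(-1, 2)
    return ParticleSet(centroids_px=centroids, areas_um2=areas[keep],
                       source_image_id=source_image_id,
                       n_filtered_out=int((~keep).sum()))


def straighten_and_project(particles: ParticleSet, trace: AxonTrace,
                           max_offset_um: float = DEFAULT_MAX_OFFSET_UM
                           ) -> ParticleSet:
    """Map particle centroids to 1-D arc-length positions along a trace.

    Each centroid is projected to its nearest point on the polyline; its
    position is that foot point's cumulative arc length. Particles farther
    than ``max_offset_um`` from the path are excluded and counted in
    ``n_offpath``. Output is sorted by position. The operation is
    idempotent: re-projecting a projected set reproduces it.
    """
    if max_offset_um <= 0:
        raise ParameterError("max_offset_um must be > 0")
    if len(particles) == 0:
        return replace(particles, positions_um=np.empty(0))
    s_um, dist_um = trace.project(particles.centroids_px)
    keep = dist_um <= max_offset_um
    order = np.argsort(s_um[keep], kind="stable")
    return ParticleSet(
        centroids_px=particles.centroids_px[keep][order],
        areas_um2=particles.areas_um2[keep][order],
        positions_um=s_um[keep][order],
        source_image_id=particles.source_image_id,
        n_filtered_out=particles.n_filtered_out,
        n_offpath=int((~keep).sum()))


def register_stack(frames) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Translation-only registration of a frame stack to its first frame.

    Shifts are located by integer-pixel cross-correlation peak. Returns the
    mean (stacked) image over the region covered by every aligned frame and
    the per-frame displacements relative to frame 0, so a frame rendered at
    true shift (dr, dc) reports approximately (dr, dc).
    """
    frame_list = [np.asarray(f, dtype=float) for f in frames] \
        if not isinstance(frames, np.ndarray) else None
    if frame_list is not None:
        if any(f.shape != frame_list[0].shape for f in frame_list):
            raise ParameterError("all frames must share one shape")
        frames = np.stack(frame_list)
    else:
        frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ParameterError("register_stack expects a stack of 2-D frames")
    ref = frames[0]
    aligned = np.empty_like(frames)
    valid = np.ones(frames.shape, dtype=bool)
    shifts: list[tuple[int, int]] = [(0, 0)]
    aligned[0] = ref
    for i in range(1, len(frames)):
        if frames[i].shape != ref.shape:
            raise ParameterError("all frames must share one shape")
        corr, _, _ = phase_cross_correlation(ref, frames[i], upsample_factor=1)
        dr, dc = int(round(-corr[0])), int(round(-corr[1]))
        shifts.append((dr, dc))
        aligned[i] = ndimage.shift(frames[i], (-dr, -dc), order=0, cval=np.nan)
        valid[i] = ~np.isnan(aligned[i])
        aligned[i] = np.nan_to_num(aligned[i])
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stacked = np.where(n_valid == len(frames),
                           aligned.sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    return stacked, shifts


def measure_roi_series(images, roi_boxes, days=None,
                       roi_size_px: int = DEFAULT_ROI_SIZE_PX
                       ) -> RoiIntensitySeries:
    """Mean intensity of fixed square ROIs across acquisition days.

    The same ROI boxes (top-left corners of ``roi_size_px`` squares) are
    applied to every image; the per-day value is the mean of the ROI means,
    and the ratio series divides by the day-0 value, which is therefore
    exactly 1.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if not images:
        raise ParameterError("need at least one image")
    if days is None:
        days = list(range(len(images)))
    if len(days) != len(images):
        raise ParameterError("days and images must align")
    boxes = [(int(r), int(c)) for r, c in roi_boxes]
    for im in images:
        for r, c in boxes:
            if r < 0 or c < 0 or r + roi_size_px > im.shape[0] \
                    or c + roi_size_px > im.shape[1]:
                raise ParameterError(f"ROI at ({r}, {c}) exceeds image bounds")
    means = np.array([[im[r:r + roi_size_px, c:c + roi_size_px].mean()
                       for r, c in boxes] for im in images])
    per_day = means.mean(axis=1)
    ratios = per_day / per_day[0]
    ratios[0] = 1.0
    return RoiIntensitySeries(days=list(days), roi_boxes=boxes,
                              roi_size_px=roi_size_px, mean_intensity=means,
                              ratio_to_baseline=ratios)


def count_particles_2d(image: np.ndarray, pixel_size_um: float = 1.0,
                       min_area_um2: float | None = None) -> int:
    """Binarize then count connected particles (generic cell counter)."""
    img = np.asarray(image)
    if img.min() == img.max():
        return 0  # featureless field: nothing to count
    mask = binarize(img, "otsu")
    return len(find_particles(mask, pixel_size_um, min_area_um2))
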