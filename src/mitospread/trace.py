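"""Calibrated axon polylines and arc-length geometry.

An :class:`AxonTrace` is the manual annotation of one axon's path: an ordered
polyline in pixel coordinates plus a pixel-size calibration. It provides the
arc-length parameterization used everywhere downstream — sampling positions
along the path, and projecting 2-D particle centroids back to 1-D arc-length
coordinates (the "straightening" step of the analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["AxonTrace"]


@dataclass
class AxonTrace:
    """An axon path as an ordered pixel-coordinate polyline.

    Parameters
    ----------
    control_points_px
        Array of shape (n, 2) of (row, col) pixel coordinates, n >= 2,
        consecutive points distinct.
    pixel_size_um
        Physical size of one pixel in micrometres (> 0). For pixel-calibrated
        modalities without a physical calibration, pass 1.0 and interpret all
        arc lengths in pixels.
    """

    control_points_px: np.ndarray
    pixel_size_um: float = 1.0

    _cumlen_px: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points_px, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("trace needs >= 2 two-dimensional control points")
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen == 0):
            raise GeometryError("consecutive control points must be distinct")
        if not self.pixel_size_um > 0:
            raise GeometryError("pixel_size_um must be > 0")
        self.control_points_px = pts
        self._cumlen_px = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def arc_length_um(self) -> float:
        """Total path length: sum of segment lengths times the calibration."""
        return float(self._cumlen_px[-1] * self.pixel_size_um)

    def point_at(self, s_um) -> np.ndarray:
        """Pixel coordinates of the path point at arc length ``s_um``.

        Values are clamped to [0, arc_length_um]. Returns shape (2,) for a
        scalar input, (n, 2) for an array.
        """
        s_px = np.clip(np.asarray(s_um, dtype=float) / self.pixel_size_um,
                       0.0, self._cumlen_px[-1])
        rows = np.interp(s_px, self._cumlen_px, self.control_points_px[:, 0])
        cols = np.interp(s_px, self._cumlen_px, self.control_points_px[:, 1])
        return np.stack([rows, cols], axis=-1)

    def tangent_at(self, s_um) -> np.ndarray:
        """Unit tangent of the segment containing arc length ``s_um``."""
        s_px = np.clip(np.atleast_1d(np.asarray(s_um, dtype=float))
                       / self.pixel_size_um, 0.0, self._cumlen_px[-1])
        idx = np.clip(np.searchsorted(self._cumlen_px, s_px, side="right") - 1,
                      0, len(self._cumlen_px) - 2)
        seg = np.diff(self.control_points_px, axis=0)[idx]
        t = seg / np.hypot(seg[:, 0], seg[:, 1])[:, None]
        return t[0] if np.isscalar(s_um) else t

    def project(self, points_px) -> tuple[np.ndarray, np.ndarray]:
        """Project 2-D points onto the polyline.

        Each point is mapped to its nearest point on the path; per-segment
        orthogonal projection clamped to the segment ends, with distance ties
        broken toward the earlier segment.

        Returns
        -------
        s_um : arc-length positions of the foot points, micrometres.
        dist_um : orthogonal distances from each point to its foot point.
        """
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        A = self.control_points_px[:-1]               # (m, 2)
        V = np.diff(self.control_points_px, axis=0)   # (m, 2)
        L2 = np.sum(V * V, axis=1)                    # (m,)
        # (n, m) parametric foot point on each segment, clamped to [0, 1]
        t = np.clip(np.einsum("nmk,mk->nm", pts[:, None, :] - A[None], V) / L2,
                    0.0, 1.0)
        foot = A[None] + t[..., None] * V[None]
        d2 = np.sum((pts[:, None, :] - foot) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)  # first minimum -> earlier segment on ties
        n = np.arange(len(pts))
        s_px = self._cumlen_px[best] + t[n, best] * np.sqrt(L2[best])
        dist_px = np.sqrt(d2[n, best])
        return s_px * self.pixel_size_um, dist_px * self.pixel_size_um
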