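"""Rotated-rectangle region of interest (ROI) extraction.

A :class:`RoiSpec` describes a rectangle on the mesentery image, rotated so
that its long axis follows the vessel.  :func:`extract_roi` resamples the
source video inside that rectangle into a sub-video in which the vessel
runs vertically (top of the output = one end of the ROI axis).

The interactive drag-selection of the original workflow is replaced by the
parameterized spec plus a rendered preview image; the spec serializes to a
single ``cx,cy,length,width,angle`` string so any selection is exactly
reproducible from the logged parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .video_io import VideoClip

__all__ = ["RoiSpec", "RoiBoundsError", "extract_roi", "render_roi_preview"]


class RoiBoundsError(ValueError):
    """ROI rectangle extends beyond the frame."""


@dataclass(frozen=True)
class RoiSpec:
    """Rotated rectangle isolating one vessel segment.

    center : (row, col) pixel coordinate of the rectangle center.
    length_px : extent along the vessel axis (output height).
    width_px : extent across the vessel (output width).
    angle_deg : rotation of the vessel axis relative to image vertical,
        positive toward increasing column; normalized to (-180, 180].
    """

    center: tuple[float, float]
    length_px: int
    width_px: int
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.length_px < 1 or self.width_px < 1:
            raise ValueError("length_px and width_px must be >= 1")
        a = (float(self.angle_deg) + 180.0) % 360.0 - 180.0
        if a == -180.0:
            a = 180.0
        object.__setattr__(self, "angle_deg", a)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    # -- textual form: cx,cy,length,width,angle (cx = column, cy = row) -----

    def to_string(self) -> str:
        cy, cx = self.center
        return f"{cx:g},{cy:g},{self.length_px},{self.width_px},{self.angle_deg:g}"

    @classmethod
    def from_string(cls, text: str) -> "RoiSpec":
        parts = text.split(",")
        if len(parts) != 5:
            raise ValueError(
                f"ROI spec must be 'cx,cy,length,width,angle', got {text!r}"
            )
        cx, cy, length, width, angle = (float(p) for p in parts)
        return cls(center=(cy, cx), length_px=int(length), width_px=int(width),
                   angle_deg=angle)

    # -- geometry -----------------------------------------------------------

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (row, col) along the vessel axis and across it."""
        th = math.radians(self.angle_deg)
        axis = np.array([math.cos(th), math.sin(th)])
        cross = np.array([-math.sin(th), math.cos(th)])
        return axis, cross

    def corners(self) -> np.ndarray:
        """The four sampled corner coordinates, (row, col), shape (4, 2)."""
        axis, cross = self.axes()
        c = np.asarray(self.center)
        hu = (self.length_px - 1) / 2.0
        hv = (self.width_px - 1) / 2.0
        return np.array(
            [c + su * hu * axis + sv * hv * cross
             for su in (-1, 1) for sv in (-1, 1)]
        )

    def footprint(self, height: int, width: int) -> np.ndarray:
        """Boolean mask of source pixels whose center lies inside the ROI."""
        rr, cc = np.mgrid[0:height, 0:width]
        dy = rr - self.center[0]
        dx = cc - self.center[1]
        axis, cross = self.axes()
        u = dy * axis[0] + dx * axis[1]
        v = dy * cross[0] + dx * cross[1]
        return (np.abs(u) < self.length_px / 2.0) & (np.abs(v) < self.width_px / 2.0)


def _check_bounds(roi: RoiSpec, height: int, width: int) -> None:
    corners = roi.corners()
    bad = [
        (float(r), float(c))
        for r, c in corners
        if not (0 <= r <= height - 1 and 0 <= c <= width - 1)
    ]
    if bad:
        raise RoiBoundsError(
            f"ROI corners outside the {height}x{width} frame: {bad}"
        )


def extract_roi(clip: VideoClip, roi: RoiSpec) -> VideoClip:
    """Extract the ROI from every frame, vessel axis mapped to vertical.

    Output clip is ``length_px`` tall and ``width_px`` wide; content is the
    source sampled under rotation by ``-angle_deg`` about the ROI center
    (bilinear per channel).  With ``angle_deg == 0`` and an integer-aligned
    center the result is a plain crop, bit-identical to array slicing.
    """
    _check_bounds(roi, clip.height, clip.width)
    L, W = roi.length_px, roi.width_px
    cy, cx = roi.center
    r0 = cy - (L - 1) / 2.0
    c0 = cx - (W - 1) / 2.0

    if roi.angle_deg == 0.0 and r0.is_integer() and c0.is_integer():
        r0i, c0i = int(r0), int(c0)
        frames = clip.frames[:, r0i : r0i + L, c0i : c0i + W, :].copy()
        return VideoClip(frames=frames, fps=clip.fps, bit_depth=clip.bit_depth)

    from scipy.ndimage import map_coordinates

    axis, cross = roi.axes()
    u = np.arange(L) - (L - 1) / 2.0
    v = np.arange(W) - (W - 1) / 2.0
    rows = cy + u[:, None] * axis[0] + v[None, :] * cross[0]
    cols = cx + u[:, None] * axis[1] + v[None, :] * cross[1]
    coords = np.stack([rows, cols])

    out = np.empty((clip.frame_count, L, W, 3), dtype=np.float64)
    for t in range(clip.frame_count):
        for ch in range(3):
            out[t, :, :, ch] = map_coordinates(
                clip.frames[t, :, :, ch].astype(np.float64),
                coords, order=1, mode="nearest",
            )
    out = np.clip(np.rint(out), 0, clip.max_intensity)
    dtype = clip.frames.dtype
    return VideoClip(frames=out.astype(dtype), fps=clip.fps, bit_depth=clip.bit_depth)


def render_roi_preview(frame: np.ndarray, roi: RoiSpec, path) -> np.ndarray:
    """Write the frame with the ROI footprint tinted green for confirmation.

    Returns the rendered image (also written to ``path`` when given).
    """
    import imageio.v3 as iio

    frame = np.asarray(frame)
    mask = roi.footprint(frame.shape[0], frame.shape[1])
    out = frame.astype(np.float64).copy()
    green = np.array([0.0, 255.0, 0.0])
    out[mask] = 0.5 * out[mask] + 0.5 * green
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if path is not None:
        iio.imwrite(path, out)
    return out


def shifted(roi: RoiSpec, d_along: float = 0.0, d_across: float = 0.0) -> RoiSpec:
    """A copy of the ROI translated along/across its own axes (helper for
    scanning several parallel vessel segments)."""
    axis, cross = roi.axes()
    c = np.asarray(roi.center) + d_along * axis + d_across * cross
    return replace(roi, center=(float(c[0]), float(c[1])))
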