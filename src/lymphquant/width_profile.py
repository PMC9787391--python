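"""The width profile (kymograph): vessel width at every position and frame.

With the ROI oriented so the vessel runs vertically, the width at position
``y`` of frame ``t`` is the number of vessel pixels in pixel-row ``y``.  A
row is *missing* (excluded) in a frame when any of its vessel pixels falls
inside the saturation-exclusion zone — a glare spot would otherwise make
the vessel appear narrower than it is.  An empty row is width 0, not
missing: absence of vessel is a measurement, glare is not.

Widths are stored as a float matrix [frame, position] with NaN marking
excluded cells, plus the frame rate and pixel calibration needed to report
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import SegmentedFrame
from .video_io import Calibration

__all__ = [
    "WidthProfile",
    "row_widths",
    "build_profile",
    "mean_width_series",
    "max_change_profile",
    "render_heatmap",
]


@dataclass(frozen=True)
class WidthProfile:
    """frames x positions matrix of vessel widths in pixels.

    widths : (n_frames, n_positions) float array; NaN = excluded cell.
    fps : frames per second (None in single-image mode).
    mm_per_px : pixel calibration (None when uncalibrated).
    """

    widths: np.ndarray
    fps: float | None = None
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        w = self.widths
        if w.ndim != 2 or w.shape[0] < 1 or w.shape[1] < 1:
            raise ValueError("widths must be a non-empty (frames, positions) matrix")
        present = w[~np.isnan(w)]
        if present.size and present.min() < 0:
            raise ValueError("widths must be >= 0 where present")

    @property
    def n_frames(self) -> int:
        return self.widths.shape[0]

    @property
    def n_positions(self) -> int:
        return self.widths.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.widths)

    def widths_mm(self) -> np.ndarray:
        if self.mm_per_px is None:
            raise ValueError("profile has no calibration")
        return self.widths * self.mm_per_px


def row_widths(seg: SegmentedFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-row vessel width (pixel count) and missing flags for one frame.

    A row is flagged missing when any vessel pixel in it intersects the
    exclusion mask; an empty row has width 0 and is not missing.
    """
    widths = seg.vessel_mask.sum(axis=1).astype(np.int64)
    missing = (seg.vessel_mask & seg.exclusion_mask).any(axis=1)
    return widths, missing


def build_profile(
    segs: Sequence[SegmentedFrame],
    fps: float | None = None,
    calib: Calibration | None = None,
) -> WidthProfile:
    """Stack per-frame row widths into the kymograph matrix."""
    if len(segs) < 1:
        raise ValueError("need at least one segmented frame")
    shape = segs[0].shape
    widths = np.empty((len(segs), shape[0]), dtype=np.float64)
    for t, seg in enumerate(segs):
        if seg.shape != shape:
            raise ValueError(
                f"frame {t} has shape {seg.shape}, expected {shape}"
            )
        w, miss = row_widths(seg)
        widths[t] = w
        widths[t, miss] = np.nan
    return WidthProfile(
        widths=widths, fps=fps,
        mm_per_px=None if calib is None else calib.mm_per_px,
    )


def mean_width_series(
    profile: WidthProfile, y_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Mean vessel width per frame over a position interval (default all).

    The mean ignores missing positions; a frame becomes NaN when more than
    half of the interval's positions are missing (majority-missing rule).
    """
    if y_range is None:
        lo, hi = 0, profile.n_positions
    else:
        lo, hi = y_range
        if not (0 <= lo < hi <= profile.n_positions):
            raise ValueError(
                f"y_range {y_range} outside [0, {profile.n_positions})"
            )
    sub = profile.widths[:, lo:hi]
    n = hi - lo
    present = ~np.isnan(sub)
    counts = present.sum(axis=1)
    sums = np.where(present, sub, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.full(len(sub), np.nan),
                      where=counts > 0)
    means[(n - counts) * 2 > n] = np.nan
    return means


def max_change_profile(profile: WidthProfile) -> np.ndarray:
    """Per-position peak - nadir over the whole recording, in mm.

    Positions missing in every frame yield NaN.  Needs >= 2 frames and a
    calibration.
    """
    if profile.n_frames < 2:
        raise ValueError("peak - nadir needs at least 2 frames")
    if profile.mm_per_px is None:
        raise ValueError("profile has no calibration; cannot report mm")
    w = profile.widths
    all_missing = np.isnan(w).all(axis=0)
    out = np.full(profile.n_positions, np.nan)
    if not all_missing.all():
        cols = ~all_missing
        out[cols] = (np.nanmax(w[:, cols], axis=0) - np.nanmin(w[:, cols], axis=0))
    return out * profile.mm_per_px


def render_heatmap(
    profile: WidthProfile,
    path=None,
    ax=None,
    section_boundaries: Sequence[int] | None = None,
):
    """Render the kymograph: time on x, position on y (row 0 at top),
    color = vessel width (mm when calibrated, else px)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = profile.widths.T  # positions x frames
    unit = "px"
    if profile.mm_per_px is not None:
        w = w * profile.mm_per_px
        unit = "mm"
    extent = None
    xlabel = "frame"
    if profile.fps is not None:
        extent = [0, profile.n_frames / profile.fps, profile.n_positions, 0]
        xlabel = "time (s)"
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(w, aspect="auto", origin="upper", extent=extent,
                   cmap="viridis", interpolation="nearest")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("position from image top"
                  + (" (px)" if extent is None else " (px rows)"))
    if section_boundaries is not None:
        xmax = ax.get_xlim()[1]
        for b in section_boundaries:
            ax.hlines(b, 0, xmax, colors="red", linewidth=0.6)
    ax.figure.colorbar(im, ax=ax, label=f"vessel width ({unit})")
    if own_fig:
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
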