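"""Video/image input-output, acquisition metadata, and pixel calibration.

The raw observable is a :class:`VideoClip`: an ordered stack of RGB frames
with a frame rate.  A still image is represented as a one-frame clip with
``fps=None`` so the spatial parts of the pipeline run unchanged; the
time-domain parts refuse such clips.  Physical scale is carried by a
:class:`Calibration` (mm per pixel edge), typically derived from a ruler
image via :func:`calibrate_from_points`.

Coordinate convention: 0-based (row, column), row 0 at the image top,
everywhere including CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from ._avi import AviFormatError, read_avi, write_avi

if TYPE_CHECKING:  # pragma: no cover
    from .width_profile import WidthProfile

__all__ = [
    "VideoClip",
    "Calibration",
    "VideoDecodeError",
    "read_video",
    "write_video",
    "write_overlay_video",
    "overlay_frame",
    "write_width_csv",
    "read_width_csv",
]

STILL_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}
TIFF_SUFFIXES = {".tif", ".tiff"}

# Overlay palette (RGB): vessel boundary and excluded-area tint
BOUNDARY_COLOR = (0, 255, 0)
EXCLUSION_COLOR = (200, 0, 200)
EXCLUSION_ALPHA = 0.5


class VideoDecodeError(ValueError):
    """A file could not be decoded as video or image."""


@dataclass(frozen=True)
class VideoClip:
    """Ordered RGB frames plus acquisition metadata.

    frames : (frame_count, height, width, 3) integer array.
    fps : frames per second; ``None`` marks single-image mode.
    bit_depth : bits per channel (8 for standard 24-bit color video).
    """

    frames: np.ndarray
    fps: float | None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        f = self.frames
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got shape {f.shape}")
        if f.shape[0] < 1:
            raise ValueError("clip must contain at least one frame")
        if self.fps is not None and self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not np.issubdtype(f.dtype, np.integer):
            raise ValueError("frame intensities must be integer")
        maxval = self.max_intensity
        if f.min() < 0 or f.max() > maxval:
            raise ValueError(f"intensities must lie in [0, {maxval}]")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def duration_s(self) -> float | None:
        return None if self.fps is None else self.frame_count / self.fps

    def require_time_axis(self) -> None:
        """Reject single-image clips in time-domain operations."""
        if self.frame_count < 2 or self.fps is None:
            raise ValueError(
                "time-domain analysis needs >= 2 frames and a frame rate; "
                "this clip is a still image (single-image mode)"
            )


@dataclass(frozen=True)
class Calibration:
    """Physical size of one pixel edge, in millimetres."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not (self.mm_per_px > 0):
            raise ValueError("mm_per_px must be > 0")

    def px_to_mm(self, px: float | np.ndarray) -> float | np.ndarray:
        return px * self.mm_per_px

    def mm_to_px(self, mm: float | np.ndarray) -> float | np.ndarray:
        return mm / self.mm_per_px

    @property
    def um_per_px(self) -> float:
        return self.mm_per_px * 1000.0


def calibrate_from_points(
    p1: Sequence[float], p2: Sequence[float], distance_mm: float
) -> Calibration:
    """Calibration from two pixel coordinates a known distance apart.

    Mirrors calibrating against an image of a ruler: click two graduation
    marks, state the physical distance between them.
    """
    if distance_mm <= 0:
        raise ValueError("distance_mm must be > 0")
    d = math.dist(tuple(map(float, p1)), tuple(map(float, p2)))
    if d == 0:
        raise ValueError("calibration points must not coincide")
    return Calibration(mm_per_px=distance_mm / d)


def read_video(path: str | Path) -> VideoClip:
    """Read an AVI/multi-page TIFF video or a still image as a VideoClip.

    A still image (PNG/JPEG/BMP, or single-page TIFF) yields a one-frame
    clip with ``fps=None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".avi":
            frames, fps = read_avi(path)
            return VideoClip(frames=frames, fps=fps)
        if suffix in TIFF_SUFFIXES:
            import tifffile

            arr = np.asarray(tifffile.imread(path))
            return _clip_from_array(arr, path)
        if suffix in STILL_SUFFIXES:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
            return _clip_from_array(arr, path)
        raise VideoDecodeError(f"unsupported file type {suffix!r}: {path}")
    except (AviFormatError, VideoDecodeError):
        raise
    except Exception as exc:  # decoding library failure
        raise VideoDecodeError(f"could not decode {path}: {exc}") from exc


def _clip_from_array(arr: np.ndarray, path: Path) -> VideoClip:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # single RGB(A) image
        arr = arr[None, ..., :3]
        fps = None
    elif arr.ndim == 4 and arr.shape[-1] in (3, 4):  # stack of RGB(A)
        arr = arr[..., :3]
        fps = None
    elif arr.ndim == 2:  # grayscale still -> replicate channels
        arr = np.repeat(arr[None, :, :, None], 3, axis=-1)
        fps = None
    elif arr.ndim == 3:  # grayscale stack
        arr = np.repeat(arr[..., None], 3, axis=-1)
        fps = None
    else:
        raise VideoDecodeError(f"unsupported image shape {arr.shape}: {path}")
    if arr.shape[0] < 1:
        raise VideoDecodeError(f"zero frames in {path}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return VideoClip(frames=arr.astype(np.uint16 if bit_depth == 16 else np.uint8),
                     fps=fps, bit_depth=bit_depth)


def write_video(clip: VideoClip, path: str | Path, fps: float | None = None) -> None:
    """Write a clip as uncompressed AVI or multi-page TIFF (by suffix)."""
    path = Path(path)
    rate = fps or clip.fps or 25.0
    frames = clip.frames.astype(np.uint8)
    if path.suffix.lower() == ".avi":
        write_avi(path, frames, rate)
    elif path.suffix.lower() in TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, frames)
    elif path.suffix.lower() in STILL_SUFFIXES and clip.frame_count == 1:
        import imageio.v3 as iio

        iio.imwrite(path, frames[0])
    else:
        raise ValueError(f"unsupported output type for {path}")


def overlay_frame(
    frame: np.ndarray,
    vessel_mask: np.ndarray | None,
    exclusion_mask: np.ndarray | None,
) -> np.ndarray:
    """Render one frame with the vessel boundary in green and the excluded
    area tinted purple (the visual-confirmation style of the workflow)."""
    from scipy.ndimage import binary_erosion

    out = frame.astype(np.float64).copy()
    if exclusion_mask is not None and exclusion_mask.any():
        tint = np.array(EXCLUSION_COLOR, dtype=np.float64)
        out[exclusion_mask] = (
            (1 - EXCLUSION_ALPHA) * out[exclusion_mask] + EXCLUSION_ALPHA * tint
        )
    if vessel_mask is not None and vessel_mask.any():
        interior = binary_erosion(
            vessel_mask, structure=np.ones((3, 3), bool), border_value=1
        )
        boundary = vessel_mask & ~interior
        out[boundary] = BOUNDARY_COLOR
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_overlay_video(
    clip: VideoClip,
    vessel_masks: Sequence[np.ndarray],
    exclusion_masks: Sequence[np.ndarray],
    path: str | Path,
) -> None:
    """Write the original frames overlaid with vessel boundaries (green)
    and saturation-exclusion zones (purple) for manual inspection."""
    if len(vessel_masks) != clip.frame_count or len(exclusion_masks) != clip.frame_count:
        raise ValueError(
            f"mask count ({len(vessel_masks)}/{len(exclusion_masks)}) does not "
            f"match frame count ({clip.frame_count})"
        )
    for i, (vm, em) in enumerate(zip(vessel_masks, exclusion_masks)):
        if vm.shape != (clip.height, clip.width) or em.shape != (clip.height, clip.width):
            raise ValueError(f"mask {i} shape does not match frame dimensions")
    frames = np.stack(
        [
            overlay_frame(clip.frames[t], vessel_masks[t], exclusion_masks[t])
            for t in range(clip.frame_count)
        ]
    )
    write_video(VideoClip(frames=frames, fps=clip.fps or 25.0), path)


# ---------------------------------------------------------------------------
# Width-profile CSV: long format, one record per (frame, position)
# ---------------------------------------------------------------------------

def write_width_csv(profile: "WidthProfile", path: str | Path) -> None:
    """Write the kymograph as a long-format CSV.

    Columns: frame_index, position_index, width_px, excluded_flag.  An
    excluded (missing) cell has excluded_flag=1 and an empty width field.
    Metadata (fps, mm_per_px) is preserved in leading comment lines so the
    matching reader round-trips losslessly.
    """
    import pandas as pd

    w = profile.widths
    t_idx, y_idx = np.meshgrid(
        np.arange(w.shape[0]), np.arange(w.shape[1]), indexing="ij"
    )
    missing = np.isnan(w)
    df = pd.DataFrame(
        {
            "frame_index": t_idx.ravel(),
            "position_index": y_idx.ravel(),
            "width_px": w.ravel(),
            "excluded_flag": missing.ravel().astype(int),
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fps={'' if profile.fps is None else repr(profile.fps)}\n")
        fh.write(
            f"# mm_per_px={'' if profile.mm_per_px is None else repr(profile.mm_per_px)}\n"
        )
        df.to_csv(fh, index=False, float_format="%.10g", na_rep="")


def read_width_csv(path: str | Path) -> "WidthProfile":
    """Read a width CSV written by :func:`write_width_csv`."""
    import pandas as pd

    from .width_profile import WidthProfile

    meta: dict[str, float | None] = {"fps": None, "mm_per_px": None}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() in meta:
                meta[key.strip()] = float(val) if val else None
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    n_frames = int(df["frame_index"].max()) + 1
    n_pos = int(df["position_index"].max()) + 1
    widths = np.full((n_frames, n_pos), np.nan)
    rows = df.loc[df["excluded_flag"] == 0]
    widths[rows["frame_index"], rows["position_index"]] = rows["width_px"]
    return WidthProfile(widths=widths, fps=meta["fps"], mm_per_px=meta["mm_per_px"])
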