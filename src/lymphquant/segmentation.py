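"""Vessel segmentation by red-channel thresholding.

The blue dye filling the vessel absorbs the wavelengths a standard camera
registers as red, so the vessel appears as a dark region in the red channel
of an otherwise bright mesentery.  Segmentation is a single intensity
threshold on that channel (vessel = strictly below), the same threshold for
every frame of a video:

1.  An automatic default is the mean of per-frame two-class splits (Otsu
    between-class-variance criterion) computed on a handful of equally
    spaced frames (default 6).
2.  Connected components smaller than ``min_component_px`` (default 10 px,
    8-connectivity) are removed as imaging artifacts.
3.  Specular glare saturates all three channels; every pixel within
    ``exclusion_radius_px`` (euclidean, inclusive, default 5) of a
    saturated pixel is recorded in an exclusion mask, applied downstream
    when widths are measured.

Every parameter of a run is echoed as a single machine-parseable log line
so an analysis can be reproduced exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .video_io import VideoClip, overlay_frame

__all__ = [
    "ThresholdConfig",
    "SegmentedFrame",
    "NoContrastError",
    "otsu_split",
    "auto_threshold",
    "sample_frame_indices",
    "segment_frame",
    "segment_video",
    "render_confirmation_montage",
    "repro_line",
]

logger = logging.getLogger("lymphquant")


class NoContrastError(ValueError):
    """All sampled frames have a constant red channel; no split exists."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the segmentation stage.

    threshold : red-channel cutoff; vessel = strictly below.  ``None``
        requests the automatic default.
    n_sample_frames : frames used to compute the automatic default.
    min_component_px : vessel components smaller than this are removed
        (strictly smaller; a 10 px component survives the default).
    saturation_fraction : fraction of the intensity range at and above
        which a channel counts as saturated.
    exclusion_radius_px : euclidean distance (inclusive) around saturated
        pixels excluded from width measurement.
    """

    threshold: float | None = None
    n_sample_frames: int = 6
    min_component_px: int = 10
    saturation_fraction: float = 0.99
    exclusion_radius_px: float = 5.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.threshold is not None and not (
            0 <= self.threshold <= 2**self.bit_depth - 1
        ):
            raise ValueError("threshold must lie inside the intensity range")
        if self.n_sample_frames < 1:
            raise ValueError("n_sample_frames must be >= 1")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")
        if not (0 < self.saturation_fraction <= 1):
            raise ValueError("saturation_fraction must be in (0, 1]")
        if self.exclusion_radius_px < 0:
            raise ValueError("exclusion_radius_px must be >= 0")

    @property
    def saturation_cutoff(self) -> int:
        """Absolute intensity at/above which a channel is saturated."""
        return int(np.ceil(self.saturation_fraction * (2**self.bit_depth - 1)))


@dataclass(frozen=True)
class SegmentedFrame:
    """Per-frame vessel mask, saturation-exclusion mask, and the threshold
    that produced them.  The two masks may intersect; exclusion is applied
    downstream, when row widths are measured."""

    vessel_mask: np.ndarray
    exclusion_mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        if self.vessel_mask.shape != self.exclusion_mask.shape:
            raise ValueError("vessel and exclusion masks must have equal shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel_mask.shape


def otsu_split(values: np.ndarray, bit_depth: int = 8) -> int | None:
    """Two-class intensity split maximizing between-class variance.

    Returns the smallest split ``s`` (1..max) maximizing
    ``w0 * w1 * (mu0 - mu1)^2`` for classes ``v < s`` and ``v >= s``, or
    ``None`` when the input is constant (no two-class split exists).
    Operating on the full integer histogram keeps the result exact and
    reproducible; tests hold it against a brute-force search over cutoffs.
    """
    nbins = 2**bit_depth
    hist = np.bincount(np.asarray(values, dtype=np.int64).ravel(), minlength=nbins)
    total = hist.sum()
    if total == 0 or np.count_nonzero(hist) < 2:
        return None
    bins = np.arange(nbins, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]  # count of v < s for s = 1..nbins-1
    w1 = total - w0
    sum0 = np.cumsum(hist * bins)[:-1]
    sum_all = (hist * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, sum0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(valid, (sum_all - sum0) / np.maximum(w1, 1), 0.0)
    bcv = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(bcv)) + 1


def sample_frame_indices(frame_count: int, n_sample_frames: int) -> np.ndarray:
    """Equally spaced frame indices; first and last included when n >= 2."""
    if n_sample_frames == 1:
        return np.array([0])
    return np.unique(
        np.linspace(0, frame_count - 1, n_sample_frames).round().astype(int)
    )


def auto_threshold(clip: VideoClip, n_sample_frames: int = 6) -> float:
    """Automatic threshold: mean of per-frame Otsu splits of the red
    channel over equally spaced sample frames.

    Frames with a constant red channel contribute no split; if every
    sampled frame is constant a :class:`NoContrastError` is raised.
    """
    if n_sample_frames < 1:
        raise ValueError("n_sample_frames must be >= 1")
    idx = sample_frame_indices(clip.frame_count, n_sample_frames)
    splits = [
        s
        for i in idx
        if (s := otsu_split(clip.frames[i, :, :, 0], clip.bit_depth)) is not None
    ]
    if not splits:
        raise NoContrastError(
            "no contrast: every sampled frame has a constant red channel"
        )
    return float(np.mean(splits))


def _remove_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with area strictly below ``min_px``."""
    if min_px <= 1 or not mask.any():
        return mask
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_px
    keep[0] = False
    return keep[labels]


def _exclusion_zone(saturated: np.ndarray, radius: float) -> np.ndarray:
    """Pixels within euclidean ``radius`` (inclusive) of a saturated pixel."""
    if not saturated.any():
        return np.zeros_like(saturated)
    from scipy.ndimage import distance_transform_edt

    dist = distance_transform_edt(~saturated)
    return dist <= radius


def segment_frame(frame: np.ndarray, cfg: ThresholdConfig) -> SegmentedFrame:
    """Segment one RGB frame.

    vessel_mask: red channel strictly below the threshold, then components
    with area < ``min_component_px`` removed (8-connectivity).
    exclusion_mask: all pixels within ``exclusion_radius_px`` of any pixel
    saturated in all three channels.
    """
    if cfg.threshold is None:
        raise ValueError("cfg.threshold is unset; call auto_threshold first")
    red = frame[:, :, 0]
    vessel = red < cfg.threshold
    vessel = _remove_small_components(vessel, cfg.min_component_px)
    saturated = (frame >= cfg.saturation_cutoff).all(axis=-1)
    exclusion = _exclusion_zone(saturated, cfg.exclusion_radius_px)
    return SegmentedFrame(
        vessel_mask=vessel, exclusion_mask=exclusion,
        threshold_used=float(cfg.threshold),
    )


def segment_video(
    clip: VideoClip,
    cfg: ThresholdConfig,
    *,
    video_path: str | None = None,
    roi_string: str | None = None,
) -> list[SegmentedFrame]:
    """Segment every frame with one shared threshold.

    When ``cfg.threshold`` is ``None`` the automatic default is computed
    first.  Emits the reproducibility log line recording every parameter.
    """
    if cfg.threshold is None:
        cfg = replace(cfg, threshold=auto_threshold(clip, cfg.n_sample_frames),
                      bit_depth=clip.bit_depth)
    logger.info(repro_line(cfg, video_path=video_path, roi_string=roi_string))
    out = []
    for t in range(clip.frame_count):
        try:
            out.append(segment_frame(clip.frames[t], cfg))
        except Exception as exc:
            raise RuntimeError(f"segmentation failed at frame {t}: {exc}") from exc
    return out


def repro_line(
    cfg: ThresholdConfig,
    *,
    video_path: str | None = None,
    roi_string: str | None = None,
) -> str:
    """One machine-parseable line with every parameter of the analysis,
    sufficient to rerun it exactly."""
    fields = {
        "video": video_path or "-",
        "roi": roi_string or "-",
        "threshold": cfg.threshold,
        "n_sample_frames": cfg.n_sample_frames,
        "min_component_px": cfg.min_component_px,
        "saturation_fraction": cfg.saturation_fraction,
        "exclusion_radius_px": cfg.exclusion_radius_px,
        "bit_depth": cfg.bit_depth,
        "split_criterion": "otsu",
    }
    return "REPRO " + " ".join(f"{k}={v}" for k, v in fields.items())


def render_confirmation_montage(
    clip: VideoClip,
    segmented: Sequence[SegmentedFrame],
    n_frames: int = 6,
    path=None,
) -> np.ndarray:
    """Tile ``min(n_frames, frame_count)`` equally spaced overlay frames
    into one image for human threshold verification.  Returns the montage
    (also written to ``path`` when given)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = min(n_frames, clip.frame_count)
    idx = sample_frame_indices(clip.frame_count, n)
    tiles = [
        overlay_frame(
            clip.frames[i], segmented[i].vessel_mask, segmented[i].exclusion_mask
        )
        for i in idx
    ]
    montage = np.concatenate(tiles, axis=1)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, montage)
    return montage
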