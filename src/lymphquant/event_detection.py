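"""Contraction event detection on the mean-width time series.

A contraction event is one cycle of contraction and re-filling: the vessel
narrows from its end-diastolic diameter (EDD) to the end-systolic diameter
(ESD) at the trough, then re-expands.  Detection runs on a smoothed copy of
the mean-width series:

smoothing
    A sliding centered window (default 20 frames).  Two smoothers are
    provided.  The 2-means window smoother splits each window into two
    clusters by exact 1-D 2-means and replaces the center value by the
    centroid of its cluster — it removes single-frame aberrations while
    preserving genuine level changes, but renders slopes as a staircase
    whose treads can outlast the minima rule's confirmation runs.  The
    detection pipeline therefore defaults to the plain moving average,
    which preserves limb monotonicity; the 2-means smoother remains
    selectable for aberration cleanup.

minima
    Frame ``t`` is a trough when the ``run_frames`` (default 10)
    differences before it are all decreasing and the ``run_frames``
    differences after all increasing.  Comparisons are plateau-tolerant:
    steps within ``flat_tol_px`` of zero count as flat and each run must
    contain at least one step beyond the tolerance.  This suits
    quantized widths and the small residual wobble of window smoothing;
    strict monotonicity is available behind a flag.  Within a flat trough
    plateau the earliest qualifying frame is reported.

expansion
    From each trough, scan forward until the curve flattens or begins to
    decrease (the event end), and backward likewise (the event start,
    whose width is the EDD).  "Flattened" is judged with the same
    tolerance and confirmed over the same run length as the minima rule:
    the walk continues as long as a value more than ``flat_tol_px``
    higher lies within the next ``run_frames`` frames, so it rides over
    smoothing wobble but stops at a sustained plateau.

filtering
    Events with amplitude below 1 px or lasting more than 110 frames (5 s
    at 22 FPS) are rejected as too small or too slow to be a genuine
    lymphatic contraction; each rejection is logged with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SmoothedSeries",
    "ContractionEvent",
    "DetectionConfig",
    "smooth_series",
    "find_minima",
    "expand_event",
    "filter_events",
    "detect_events",
]

logger = logging.getLogger("lymphquant")


@dataclass(frozen=True)
class SmoothedSeries:
    """Raw and smoothed mean-width series (px), with the smoothing window
    and frame rate used downstream for unit conversion."""

    raw: np.ndarray
    smoothed: np.ndarray
    window_frames: int
    fps: float | None = None

    def __post_init__(self) -> None:
        if self.raw.shape != self.smoothed.shape or self.raw.ndim != 1:
            raise ValueError("raw and smoothed must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.raw.size


@dataclass(frozen=True)
class ContractionEvent:
    """One contraction cycle on the smoothed series.

    start_frame carries the EDD (diameter immediately before contraction),
    trough_frame the ESD (diameter at maximal constriction); end_frame is
    the next flattening of the re-filling curve.
    """

    start_frame: int
    trough_frame: int
    end_frame: int
    edd_px: float
    esd_px: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.start_frame < self.trough_frame <= self.end_frame):
            raise ValueError("event must satisfy start < trough <= end")

    @property
    def amplitude_px(self) -> float:
        return self.edd_px - self.esd_px

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class DetectionConfig:
    """Event-detection parameters (defaults follow the 22 FPS workflow).

    ``flat_tol_px`` is the noise floor below which a frame-to-frame step
    counts as flat: 0.05 px, i.e. 5% of the minimum event amplitude,
    well above the residual wobble of the window smoother and well below
    any real contraction slope.
    """

    window_frames: int = 20
    minima_run_frames: int = 10
    min_amplitude_px: float = 1.0
    max_duration_frames: int = 110
    flat_tol_px: float = 0.05
    smoother: Literal["kmeans", "mean"] = "mean"
    strict_monotone: bool = False


def _fill_missing(raw: np.ndarray) -> np.ndarray:
    """Bridge NaN gaps by linear interpolation (edges: nearest valid)."""
    x = raw.astype(np.float64).copy()
    bad = np.isnan(x)
    if not bad.any():
        return x
    if bad.all():
        raise ValueError("series is entirely missing")
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def _kmeans2_centroid(values: np.ndarray, center_value: float) -> float:
    """Exact 1-D 2-means of ``values``; returns the smoothed replacement
    for ``center_value``.

    The optimal 2-clustering of scalars is contiguous in sorted order, so
    the search is over split points between distinct adjacent sorted
    values, minimizing within-cluster sum of squares; ties break toward
    the smallest split.  The center value is replaced by the centroid of
    its cluster — unless that cluster is a singleton (a one-sample
    aberration, which is exactly what the smoother exists to remove), in
    which case it snaps to the other cluster's centroid.  A constant
    window is left unchanged.
    """
    srt = np.sort(values)
    n = srt.size
    distinct = np.flatnonzero(np.diff(srt) > 0) + 1  # candidate split indices
    if distinct.size == 0:
        return float(srt[0])
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    csq = np.concatenate([[0.0], np.cumsum(srt**2)])

    k = distinct.astype(np.int64)
    lo_n, hi_n = k, n - k
    lo_sum, hi_sum = csum[k], csum[n] - csum[k]
    lo_sq, hi_sq = csq[k], csq[n] - csq[k]
    cost = (lo_sq - lo_sum**2 / lo_n) + (hi_sq - hi_sum**2 / hi_n)
    best = int(k[int(np.argmin(cost))])
    split_value = srt[best - 1]  # low cluster = values <= split_value
    lo_centroid = float(csum[best] / best)
    hi_centroid = float((csum[n] - csum[best]) / (n - best))
    in_low = center_value <= split_value
    own_size = best if in_low else n - best
    if own_size == 1 and n > 1:
        return hi_centroid if in_low else lo_centroid
    return lo_centroid if in_low else hi_centroid


def smooth_series(
    raw: np.ndarray,
    window_frames: int = 20,
    fps: float | None = None,
    method: Literal["kmeans", "mean"] = "kmeans",
) -> SmoothedSeries:
    """Smooth the mean-width series with a sliding centered window.

    Missing values are bridged by linear interpolation before smoothing and
    re-flagged as missing afterwards.  Near the series ends the window is
    clamped inside the series (it keeps its full length by shifting).
    ``window_frames=1`` is the identity.
    """
    raw = np.asarray(raw, dtype=np.float64)
    n = raw.size
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if n < window_frames:
        raise ValueError(
            f"series of {n} frames is shorter than the {window_frames}-frame "
            f"smoothing window; use a smaller window"
        )
    filled = _fill_missing(raw)
    if window_frames == 1:
        smoothed = filled.copy()
    else:
        smoothed = np.empty(n)
        half = (window_frames - 1) // 2
        for t in range(n):
            lo = min(max(t - half, 0), n - window_frames)
            vals = filled[lo : lo + window_frames]
            if method == "kmeans":
                smoothed[t] = _kmeans2_centroid(vals, filled[t])
            elif method == "mean":
                smoothed[t] = vals.mean()
            else:
                raise ValueError(f"unknown smoothing method {method!r}")
    smoothed[np.isnan(raw)] = np.nan
    logger.info(
        "SMOOTH method=%s window_frames=%d n_frames=%d", method, window_frames, n
    )
    return SmoothedSeries(raw=raw, smoothed=smoothed,
                          window_frames=window_frames, fps=fps)


def find_minima(
    s: SmoothedSeries,
    run_frames: int = 10,
    flat_tol_px: float = 0.05,
    strict: bool = False,
) -> list[int]:
    """Trough frames of the smoothed series.

    Frame ``t`` is a trough when the ``run_frames`` differences before it
    are all decreasing and the ``run_frames`` after all increasing.  By
    default the comparison is plateau-tolerant: steps within
    ``flat_tol_px`` of zero count as flat and each run must contain at
    least one step beyond the tolerance.  ``strict=True`` requires
    strictly monotone runs (and ignores the tolerance).  Qualifying
    frames within ``run_frames`` of each other are folded into a single
    trough, reported at the lowest smoothed value; ties break toward the
    earliest frame, so an exactly flat trough plateau reports its
    earliest frame.
    """
    if run_frames < 1:
        raise ValueError("run_frames must be >= 1")
    x = s.smoothed
    n = x.size
    if n <= 2 * run_frames:
        raise ValueError(
            f"series of {n} frames is too short for run_frames={run_frames}"
        )
    d = np.diff(x)
    tol = flat_tol_px
    candidates = []
    for t in range(run_frames, n - run_frames):
        before = d[t - run_frames : t]
        after = d[t : t + run_frames]
        if strict:
            ok = bool((before < 0).all() and (after > 0).all())
        else:
            ok = bool(
                (before <= tol).all() and (before < -tol).any()
                and (after >= -tol).all() and (after > tol).any()
            )
        if ok:
            candidates.append(t)
    groups: list[list[int]] = []
    for t in candidates:
        if groups and t - groups[-1][-1] <= run_frames:
            groups[-1].append(t)
        else:
            groups.append([t])
    return [min(g, key=lambda t: (x[t], t)) for g in groups]


def _walk_to_apex(
    x: np.ndarray, start: int, direction: int, flat_tol_px: float, confirm: int
) -> tuple[int, bool]:
    """Follow the curve away from a trough to the adjacent running maximum.

    Advances while a value more than ``flat_tol_px`` above the current one
    lies within the next ``confirm`` frames (jumping straight to it, which
    rides over small dips); stops when the curve has flattened or begun to
    decrease for a full confirmation window.  Returns (frame, truncated):
    truncated means the series ended while the curve was still rising.
    """
    n = x.size
    i = start
    while True:
        if direction > 0:
            seg = x[i + 1 : min(n, i + 1 + confirm)]
        else:
            seg = x[max(0, i - confirm) : i][::-1]
        if seg.size == 0:
            return i, True
        rising = seg > x[i] + flat_tol_px
        if not rising.any():
            return i, False
        i += direction * (int(np.argmax(rising)) + 1)


def expand_event(
    s: SmoothedSeries,
    trough: int,
    flat_tol_px: float = 0.05,
    confirm_frames: int = 10,
) -> ContractionEvent:
    """Expand a detected trough into a full contraction event.

    Forward from the trough, the event ends where the curve flattens or
    begins to decrease (the next running maximum, confirmed over
    ``confirm_frames``); backward likewise for the event start, which
    carries the EDD.  A walk that reaches the series boundary while still
    rising flags the event truncated.
    """
    x = s.smoothed
    n = x.size
    if not (0 < trough < n - 1):
        raise ValueError(f"trough {trough} must be interior to the series")

    end, truncated_end = _walk_to_apex(x, trough, +1, flat_tol_px, confirm_frames)
    start, truncated_start = _walk_to_apex(x, trough, -1, flat_tol_px, confirm_frames)
    if start == trough:  # flat right up against the trough
        start = trough - 1

    return ContractionEvent(
        start_frame=start,
        trough_frame=trough,
        end_frame=max(end, trough),
        edd_px=float(x[start]),
        esd_px=float(x[trough]),
        truncated=truncated_start or truncated_end,
    )


def filter_events(
    events: Sequence[ContractionEvent],
    min_amplitude_px: float = 1.0,
    max_duration_frames: int = 110,
) -> tuple[list[ContractionEvent], list[tuple[ContractionEvent, str]]]:
    """Apply the amplitude and duration exclusions.

    Keeps events with amplitude >= ``min_amplitude_px`` (a diameter change
    below one pixel is within quantization noise) and duration
    ``end - start`` <= ``max_duration_frames`` (both bounds inclusive).
    Returns (kept, rejected-with-reason).
    """
    kept, rejected = [], []
    for ev in events:
        if ev.amplitude_px < min_amplitude_px:
            rejected.append((ev, "amplitude"))
        elif ev.duration_frames > max_duration_frames:
            rejected.append((ev, "duration"))
        else:
            kept.append(ev)
    for ev, reason in rejected:
        logger.info(
            "REJECT event trough=%d reason=%s amplitude_px=%.3f duration_frames=%d",
            ev.trough_frame, reason, ev.amplitude_px, ev.duration_frames,
        )
    return kept, rejected


def detect_events(
    raw_series: np.ndarray,
    cfg: DetectionConfig = DetectionConfig(),
    fps: float | None = None,
) -> tuple[SmoothedSeries, list[ContractionEvent], list[tuple[ContractionEvent, str]]]:
    """Smooth, find troughs, expand, and filter, in one call."""
    s = smooth_series(raw_series, cfg.window_frames, fps=fps, method=cfg.smoother)
    troughs = find_minima(
        s, cfg.minima_run_frames, cfg.flat_tol_px, strict=cfg.strict_monotone
    )
    events = [
        expand_event(s, t, cfg.flat_tol_px, cfg.minima_run_frames) for t in troughs
    ]
    kept, rejected = filter_events(
        events, cfg.min_amplitude_px, cfg.max_duration_frames
    )
    logger.info(
        "EVENTS detected=%d kept=%d rejected=%d", len(events), len(kept), len(rejected)
    )
    return s, kept, rejected
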