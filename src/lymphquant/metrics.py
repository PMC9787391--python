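"""Contractile parameters derived from detected events.

Per contraction event (diameters in mm after calibration):

==========================  =================================================
end-diastolic diameter      EDD, diameter immediately before contraction
end-systolic diameter       ESD, diameter at the trough
contraction amplitude       CA = EDD - ESD
ejection fraction           EF = (EDD^2 - ESD^2) / EDD^2 x 100  [%]
contraction duration        time from EDD to ESD  [s]
muscle shortening speed     CA / contraction duration  [mm/s]
relaxation duration         time from previous ESD to this EDD  [s]
filling speed               (EDD - previous ESD) / relaxation duration [mm/s]
percent re-filling          (EDD - previous ESD) / previous CA x 100  [%]
==========================  =================================================

Aggregates over a recording: number of contractions; contraction frequency
CF = 1 / (mean trough-to-trough interval), in min^-1; fractional pump flow
FPF = EF x CF (% per minute), by default from the mean of per-event EFs;
peak and nadir are the extremes of the smoothed trace over the whole
recording, whether associated with a contraction or not.

The ejection fraction assumes a circular cross-section, so EF is the
fraction of luminal area expelled by one contraction; FPF is the
corresponding throughput index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .event_detection import ContractionEvent, SmoothedSeries
from .video_io import Calibration

__all__ = [
    "ContractileSummary",
    "summarize_events",
    "compare_sections",
    "contraction_amplitude",
    "ejection_fraction",
    "fractional_pump_flow",
    "contraction_frequency",
    "muscle_shortening_speed",
    "filling_speed",
    "percent_refilling",
    "frames_to_seconds",
]

#: Table-style column order of the per-event frame
EVENT_COLUMNS = [
    "event", "start_frame", "trough_frame", "end_frame",
    "start_s", "trough_s", "end_s",
    "edd_mm", "esd_mm", "ca_mm", "ef_pct",
    "contraction_duration_s", "shortening_speed_mm_s",
    "relaxation_duration_s", "filling_speed_mm_s", "refilling_pct",
    "truncated",
]


# -- per-event formulas (unit-agnostic; pass mm to obtain mm) ---------------

def contraction_amplitude(edd: float, esd: float) -> float:
    """CA = EDD - ESD."""
    return edd - esd


def ejection_fraction(edd: float, esd: float) -> float:
    """EF = (EDD^2 - ESD^2) / EDD^2 x 100, in percent; NaN when EDD = 0."""
    if edd == 0:
        return math.nan
    return (edd**2 - esd**2) / edd**2 * 100.0


def fractional_pump_flow(ef_pct: float, cf_per_min: float) -> float:
    """FPF = EF x CF, in percent per minute."""
    return ef_pct * cf_per_min


def contraction_frequency(trough_times_s: Sequence[float]) -> float:
    """CF = 1 / (mean interval between successive contractions), min^-1."""
    t = np.asarray(trough_times_s, dtype=float)
    if t.size < 2:
        return math.nan
    return 60.0 / float(np.diff(t).mean())


def muscle_shortening_speed(ca: float, contraction_duration_s: float) -> float:
    """CA / contraction duration."""
    return ca / contraction_duration_s


def filling_speed(edd: float, prev_esd: float, relaxation_duration_s: float) -> float:
    """(EDD - previous ESD) / relaxation duration."""
    return (edd - prev_esd) / relaxation_duration_s


def percent_refilling(edd: float, prev_esd: float, prev_ca: float) -> float:
    """(EDD - previous ESD) / previous CA x 100."""
    if prev_ca == 0:
        return math.nan
    return (edd - prev_esd) / prev_ca * 100.0


def frames_to_seconds(frames: float, fps: float) -> float:
    return frames / fps


@dataclass
class ContractileSummary:
    """Aggregate contractile parameters of one region (ROI or section).

    ``per_event`` holds one row per kept contraction with all per-event
    quantities (see :data:`EVENT_COLUMNS`); scalar fields are the
    recording-level aggregates.  Values are stored at full precision;
    round only for display.
    """

    n_contractions: int
    contraction_frequency_per_min: float
    fractional_pump_flow_pct_per_min: float
    peak_mm: float
    nadir_mm: float
    per_event: pd.DataFrame
    section_id: int | None = None
    section_interval: tuple[int, int] | None = None
    absent: bool = False  # section had no usable signal at all

    def mean(self, column: str) -> float:
        vals = self.per_event[column].dropna()
        return float(vals.mean()) if len(vals) else math.nan

    def sd(self, column: str) -> float:
        vals = self.per_event[column].dropna()
        return float(vals.std(ddof=1)) if len(vals) > 1 else math.nan

    def to_row(self) -> dict:
        """Flat summary row (means and SDs), for the summary CSV."""
        row: dict = {
            "section_id": self.section_id,
            "section_start": None if self.section_interval is None
            else self.section_interval[0],
            "section_end": None if self.section_interval is None
            else self.section_interval[1],
            "n_contractions": self.n_contractions,
            "cf_per_min": self.contraction_frequency_per_min,
            "fpf_pct_per_min": self.fractional_pump_flow_pct_per_min,
            "peak_mm": self.peak_mm,
            "nadir_mm": self.nadir_mm,
        }
        for col in [
            "edd_mm", "esd_mm", "ca_mm", "ef_pct", "contraction_duration_s",
            "shortening_speed_mm_s", "relaxation_duration_s",
            "filling_speed_mm_s", "refilling_pct",
        ]:
            row[f"{col}_mean"] = self.mean(col)
            row[f"{col}_sd"] = self.sd(col)
        return row


def summarize_events(
    events: Sequence[ContractionEvent],
    series: SmoothedSeries,
    calib: Calibration,
    fpf_mode: Literal["per_event", "aggregate"] = "per_event",
) -> ContractileSummary:
    """Derive the contractile parameter table from kept events.

    Predecessor-dependent quantities (relaxation duration, filling speed,
    percent re-filling) are NaN for the first event; CF (and hence FPF) is
    NaN with fewer than two events — absent, not zero.  ``fpf_mode``
    selects whether FPF uses the mean of per-event EFs (default, matching
    a per-contraction table) or the EF of the mean diameters.
    """
    if series.fps is None:
        raise ValueError("series has no frame rate; cannot derive timings")
    fps = series.fps
    mm = calib.mm_per_px
    events = sorted(events, key=lambda e: e.trough_frame)

    rows = []
    for i, ev in enumerate(events):
        edd_mm = ev.edd_px * mm
        esd_mm = ev.esd_px * mm
        ca_mm = contraction_amplitude(edd_mm, esd_mm)
        dur_s = frames_to_seconds(ev.trough_frame - ev.start_frame, fps)
        row = {
            "event": i,
            "start_frame": ev.start_frame,
            "trough_frame": ev.trough_frame,
            "end_frame": ev.end_frame,
            "start_s": frames_to_seconds(ev.start_frame, fps),
            "trough_s": frames_to_seconds(ev.trough_frame, fps),
            "end_s": frames_to_seconds(ev.end_frame, fps),
            "edd_mm": edd_mm,
            "esd_mm": esd_mm,
            "ca_mm": ca_mm,
            "ef_pct": ejection_fraction(edd_mm, esd_mm),
            "contraction_duration_s": dur_s,
            "shortening_speed_mm_s": muscle_shortening_speed(ca_mm, dur_s),
            "relaxation_duration_s": math.nan,
            "filling_speed_mm_s": math.nan,
            "refilling_pct": math.nan,
            "truncated": ev.truncated,
        }
        if i > 0:
            prev = events[i - 1]
            relax_s = frames_to_seconds(ev.start_frame - prev.trough_frame, fps)
            row["relaxation_duration_s"] = relax_s
            if relax_s > 0:
                row["filling_speed_mm_s"] = filling_speed(
                    edd_mm, prev.esd_px * mm, relax_s
                )
            row["refilling_pct"] = percent_refilling(
                edd_mm, prev.esd_px * mm,
                contraction_amplitude(prev.edd_px * mm, prev.esd_px * mm),
            )
        rows.append(row)

    per_event = pd.DataFrame(rows, columns=EVENT_COLUMNS)

    cf = contraction_frequency([r["trough_s"] for r in rows])
    if math.isnan(cf):
        fpf = math.nan
    elif fpf_mode == "per_event":
        fpf = fractional_pump_flow(float(per_event["ef_pct"].mean()), cf)
    elif fpf_mode == "aggregate":
        fpf = fractional_pump_flow(
            ejection_fraction(float(per_event["edd_mm"].mean()),
                              float(per_event["esd_mm"].mean())),
            cf,
        )
    else:
        raise ValueError(f"unknown fpf_mode {fpf_mode!r}")

    valid = series.smoothed[~np.isnan(series.smoothed)]
    peak = float(valid.max()) * mm if valid.size else math.nan
    nadir = float(valid.min()) * mm if valid.size else math.nan

    return ContractileSummary(
        n_contractions=len(events),
        contraction_frequency_per_min=cf,
        fractional_pump_flow_pct_per_min=fpf,
        peak_mm=peak,
        nadir_mm=nadir,
        per_event=per_event,
        absent=valid.size == 0,
    )


def compare_sections(summaries: Sequence[ContractileSummary]) -> pd.DataFrame:
    """Long-format table keyed by (section, event) with all per-event
    metrics, ready for amplitude-vs-duration and amplitude-over-time
    plots.  Sections with zero events appear with ``n_contractions`` 0 and
    absent (NaN) metrics."""
    frames = []
    for s in summaries:
        if len(s.per_event):
            df = s.per_event.copy()
        else:
            df = pd.DataFrame([{c: np.nan for c in EVENT_COLUMNS}])
            df["event"] = pd.array([pd.NA], dtype="Int64")
        df.insert(0, "section_id", s.section_id)
        df.insert(
            1, "section_start",
            None if s.section_interval is None else s.section_interval[0],
        )
        df.insert(
            2, "section_end",
            None if s.section_interval is None else s.section_interval[1],
        )
        df["n_contractions"] = s.n_contractions
        df["cf_per_min"] = s.contraction_frequency_per_min
        frames.append(df)
    if not frames:
        raise ValueError("need at least one section summary")
    return pd.concat(frames, ignore_index=True)
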