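"""Shared fixtures: the reference synthetic recording and small scenes.

The heavy paper-conditions scene (660 frames, 240x72 px) is rendered and
analyzed once per session; smaller scenes are built per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import lymphquant as lq
from lymphquant.segmentation import ThresholdConfig

MM_PER_PX = 0.0137


def run_pipeline(clip, mm_per_px=MM_PER_PX, threshold=None, det=None):
    """Full whole-ROI pipeline on a vertically oriented clip."""
    cfg = ThresholdConfig(
        threshold=lq.auto_threshold(clip) if threshold is None else threshold,
        bit_depth=clip.bit_depth,
    )
    segs = lq.segment_video(clip, cfg)
    profile = lq.build_profile(segs, fps=clip.fps,
                               calib=lq.Calibration(mm_per_px))
    series = lq.mean_width_series(profile)
    det = det or lq.DetectionConfig()
    smoothed, kept, rejected = lq.detect_events(series, det, fps=clip.fps)
    summary = lq.summarize_events(kept, smoothed, lq.Calibration(mm_per_px))
    return {
        "segs": segs,
        "profile": profile,
        "series": series,
        "smoothed": smoothed,
        "events": kept,
        "rejected": rejected,
        "summary": summary,
    }


def small_scene(
    n_frames=220,
    height=48,
    width=40,
    baseline=12.0,
    amplitude=6.0,
    onsets=(30, 130),
    contract_frames=25,
    relax_frames=20,
    noise_sd=0.0,
    glare=(),
    rng_seed=0,
    pulse=None,
    events=None,
):
    """A fast-rendering contracting-vessel scene for unit tests."""
    if pulse is None:
        pulse, events = lq.pulse_train(
            n_frames, list(onsets), contract_frames, relax_frames
        )
    return lq.VesselScene(
        n_frames=n_frames,
        fps=22.0,
        height=height,
        width=width,
        baseline_width_px=baseline,
        amplitude_px=amplitude,
        pulse=pulse,
        events=events or (),
        noise_sd=noise_sd,
        glare=glare,
        rng_seed=rng_seed,
        mm_per_px=MM_PER_PX,
    )


@pytest.fixture(scope="session")
def paper_scene():
    return lq.preset_paper_like(rng_seed=0)


@pytest.fixture(scope="session")
def paper_render(paper_scene):
    clip, truth, events = lq.render_scene(paper_scene)
    return {"clip": clip, "truth": truth, "truth_events": events}


@pytest.fixture(scope="session")
def paper_run(paper_scene, paper_render):
    out = run_pipeline(paper_render["clip"])
    out["scene"] = paper_scene
    out.update(paper_render)
    return out


@pytest.fixture(scope="session")
def paper_sections(paper_run):
    sections = lq.make_sections(paper_run["profile"].n_positions, 30)
    summaries = lq.per_section_pipeline(
        paper_run["profile"], sections, lq.DetectionConfig(),
        lq.Calibration(MM_PER_PX),
    )
    return sections, summaries


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
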