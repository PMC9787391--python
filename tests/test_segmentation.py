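"""Threshold segmentation: automatic split, component filter, glare zone."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lymphquant as lq
from lymphquant.segmentation import (
    NoContrastError,
    ThresholdConfig,
    otsu_split,
    sample_frame_indices,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def otsu_oracle(values: np.ndarray) -> int | None:
    """Brute force over every cutoff, computing class stats from the raw
    pixel values (no histogram)."""
    values = np.asarray(values, float).ravel()
    best_s, best_score = None, -1.0
    for s in range(1, 256):
        lo = values[values < s]
        hi = values[values >= s]
        if lo.size == 0 or hi.size == 0:
            continue
        score = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if score > best_score + 1e-9:
            best_score, best_s = score, s
    return best_s


def component_filter_oracle(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Flood-fill (BFS, 8-connectivity) component areas, then drop small."""
    mask = mask.copy()
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    h, w = mask.shape
    for sr in range(h):
        for sc in range(w):
            if not mask[sr, sc] or seen[sr, sc]:
                continue
            stack, comp = [(sr, sc)], []
            seen[sr, sc] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if len(comp) >= min_px:
                for r, c in comp:
                    out[r, c] = True
    return out


def exclusion_oracle(saturated: np.ndarray, radius: float) -> np.ndarray:
    """All pixels within euclidean radius (inclusive) of a saturated one."""
    out = np.zeros_like(saturated)
    pts = np.argwhere(saturated)
    h, w = saturated.shape
    for r in range(h):
        for c in range(w):
            for pr, pc in pts:
                if (r - pr) ** 2 + (c - pc) ** 2 <= radius**2:
                    out[r, c] = True
                    break
    return out


def _rgb(red: np.ndarray) -> np.ndarray:
    """Frame with the given red channel and neutral green/blue."""
    red = np.asarray(red, np.uint8)
    return np.stack([red, np.full_like(red, 128), np.full_like(red, 128)],
                    axis=-1)


# ---------------------------------------------------------------------------
# automatic threshold
# ---------------------------------------------------------------------------

class TestAutoThreshold:
    def test_mean_of_identical_splits(self):
        red = np.zeros((10, 10), np.uint8)
        red[:, 5:] = 200
        red[:, :5] = 10
        clip = lq.VideoClip(frames=np.stack([_rgb(red)] * 6), fps=22.0)
        t = lq.auto_threshold(clip, 6)
        assert t == otsu_oracle(red)

    def test_mean_of_per_frame_oracle_splits(self, rng):
        frames = rng.integers(0, 256, size=(3, 12, 12, 3), dtype=np.uint8)
        clip = lq.VideoClip(frames=frames, fps=22.0)
        expected = np.mean(
            [otsu_oracle(frames[i, :, :, 0]) for i in range(3)]
        )
        assert lq.auto_threshold(clip, 3) == pytest.approx(expected)

    def test_constant_clip_raises_no_contrast(self):
        clip = lq.VideoClip(
            frames=np.full((4, 8, 8, 3), 77, np.uint8), fps=22.0
        )
        with pytest.raises(NoContrastError, match="no contrast"):
            lq.auto_threshold(clip)

    def test_constant_frames_skipped_not_counted(self, rng):
        red = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        flat = np.full((8, 8), 50, np.uint8)
        frames = np.stack([_rgb(red), _rgb(flat), _rgb(red)])
        clip = lq.VideoClip(frames=frames, fps=22.0)
        assert lq.auto_threshold(clip, 3) == otsu_oracle(red)

    def test_sample_indices_equally_spaced_with_endpoints(self):
        np.testing.assert_array_equal(
            sample_frame_indices(11, 6), [0, 2, 4, 6, 8, 10]
        )
        np.testing.assert_array_equal(sample_frame_indices(100, 2), [0, 99])
        np.testing.assert_array_equal(sample_frame_indices(100, 1), [0])

    @given(
        pixels=hnp.arrays(np.uint8, st.tuples(st.integers(2, 8),
                                              st.integers(2, 8))),
    )
    @settings(max_examples=60, deadline=None)
    def test_otsu_split_equals_exhaustive_oracle(self, pixels):
        got = otsu_split(pixels)
        want = otsu_oracle(pixels)
        assert got == want


# ---------------------------------------------------------------------------
# per-frame segmentation
# ---------------------------------------------------------------------------

class TestSegmentFrame:
    def test_uniformly_dark_frame_is_all_vessel(self):
        frame = _rgb(np.zeros((20, 20)))
        seg = lq.segment_frame(frame, ThresholdConfig(threshold=100))
        assert seg.vessel_mask.all()
        assert not seg.exclusion_mask.any()

    def test_strict_ten_pixel_component_rule(self):
        red = np.full((20, 40), 200, np.uint8)
        red[2, 2:11] = 10          # 9-px blob: removed
        red[10, 2:12] = 10         # 10-px blob: kept
        seg = lq.segment_frame(_rgb(red), ThresholdConfig(threshold=100))
        assert not seg.vessel_mask[2].any()
        assert seg.vessel_mask[10, 2:12].all()

    def test_exclusion_zone_matches_bruteforce_distance(self):
        frame = _rgb(np.full((40, 40), 100))
        frame[20, 20] = (255, 255, 255)
        seg = lq.segment_frame(frame, ThresholdConfig(threshold=50))
        saturated = np.zeros((40, 40), bool)
        saturated[20, 20] = True
        np.testing.assert_array_equal(
            seg.exclusion_mask, exclusion_oracle(saturated, 5.0)
        )
        # boundary case: distance exactly 5 is excluded (inclusive)
        assert seg.exclusion_mask[20, 25]
        assert not seg.exclusion_mask[20, 26]

    def test_saturation_requires_all_three_channels(self):
        frame = _rgb(np.full((10, 10), 100))
        frame[5, 5] = (255, 255, 100)  # bright but blue not saturated
        seg = lq.segment_frame(frame, ThresholdConfig(threshold=50))
        assert not seg.exclusion_mask.any()

    def test_threshold_zero_yields_empty_mask(self):
        frame = _rgb(np.full((10, 10), 5))
        seg = lq.segment_frame(frame, ThresholdConfig(threshold=0))
        assert not seg.vessel_mask.any()

    @given(
        red=hnp.arrays(np.uint8, (16, 16)),
        t1=st.integers(0, 255),
        t2=st.integers(0, 255),
    )
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotonicity(self, red, t1, t2):
        lo, hi = sorted([t1, t2])
        cfg_lo = ThresholdConfig(threshold=lo, min_component_px=0)
        cfg_hi = ThresholdConfig(threshold=hi, min_component_px=0)
        m_lo = lq.segment_frame(_rgb(red), cfg_lo).vessel_mask
        m_hi = lq.segment_frame(_rgb(red), cfg_hi).vessel_mask
        assert (m_hi | m_lo).sum() == m_hi.sum()  # m_lo subset of m_hi

    @given(
        mask=hnp.arrays(bool, st.tuples(st.integers(1, 32),
                                        st.integers(1, 32))),
        min_px=st.integers(0, 12),
    )
    @settings(max_examples=60, deadline=None)
    def test_component_filter_matches_floodfill_oracle(self, mask, min_px):
        red = np.where(mask, 10, 200).astype(np.uint8)
        cfg = ThresholdConfig(threshold=100, min_component_px=min_px)
        got = lq.segment_frame(_rgb(red), cfg).vessel_mask
        np.testing.assert_array_equal(
            got, component_filter_oracle(mask, max(min_px, 1))
        )


# ---------------------------------------------------------------------------
# whole-video segmentation
# ---------------------------------------------------------------------------

class TestSegmentVideo:
    def test_identical_frames_give_identical_masks(self, rng):
        frame = _rgb(rng.integers(0, 256, size=(12, 12), dtype=np.uint8))
        clip = lq.VideoClip(frames=np.stack([frame] * 5), fps=22.0)
        segs = lq.segment_video(clip, ThresholdConfig(threshold=100))
        for s in segs[1:]:
            np.testing.assert_array_equal(s.vessel_mask, segs[0].vessel_mask)
        assert all(s.threshold_used == 100 for s in segs)

    def test_noise_free_scene_recovers_row_widths(self):
        from conftest import small_scene

        scene = small_scene(noise_sd=0.0)
        clip, truth, _ = lq.render_scene(scene)
        # threshold at mid-intensity: coverage cutoff 0.5, minimal bias
        segs = lq.segment_video(clip, ThresholdConfig(threshold=120))
        for t in range(0, clip.frame_count, 37):
            widths, missing = lq.row_widths(segs[t])
            assert not missing.any()
            np.testing.assert_allclose(
                widths, truth.widths[t], atol=2.0
            )

    def test_repro_line_records_all_parameters(self, caplog):
        import logging

        frame = _rgb(np.where(np.arange(100).reshape(10, 10) < 50, 10, 200))
        clip = lq.VideoClip(frames=frame[None].repeat(3, 0), fps=22.0)
        with caplog.at_level(logging.INFO, logger="lymphquant"):
            lq.segment_video(clip, ThresholdConfig(), video_path="v.avi",
                             roi_string="1,2,3,4,5")
        line = next(r.message for r in caplog.records
                    if r.message.startswith("REPRO"))
        for token in ["video=v.avi", "roi=1,2,3,4,5", "threshold=",
                      "min_component_px=10", "exclusion_radius_px=5.0",
                      "saturation_fraction=0.99", "n_sample_frames=6"]:
            assert token in line


class TestMontage:
    @pytest.mark.parametrize("frame_count, n, expected_tiles",
                             [(6, 6, 6), (1, 6, 1), (10, 4, 4), (3, 6, 3)])
    def test_tile_count_is_min_of_requested_and_available(
        self, frame_count, n, expected_tiles, rng
    ):
        frames = rng.integers(0, 256, size=(frame_count, 8, 9, 3),
                              dtype=np.uint8)
        clip = lq.VideoClip(frames=frames, fps=22.0)
        segs = lq.segment_video(clip, ThresholdConfig(threshold=100))
        montage = lq.render_confirmation_montage(clip, segs, n)
        assert montage.shape == (8, 9 * expected_tiles, 3)
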