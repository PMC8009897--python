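"""Curve detection, apex localization and vertebra-band labeling."""
import numpy as np
import pytest

from spinaxis.axes import DisplacementSeries
from spinaxis.errors import ValidationError
from spinaxis.landmarks import (
    CurveSegment,
    LandmarkSet,
    VERTEBRA_NAMES,
    apical_vertebra,
    detect_curves,
    full_extent_segment,
    label_vertebrae,
)
from spinaxis.phantom import epsilon_crossing_rows


def series(d, csl_x=237.0, start=0):
    d = np.asarray(d, dtype=float)
    return DisplacementSeries(np.arange(start, start + len(d), 1.0), d, csl_x)


class TestDetectCurves:
    def test_zero_displacement_gives_no_segments(self):
        assert detect_curves(series(np.zeros(200)), epsilon=2.0) == []

    def test_single_bump_bounds_match_epsilon_crossings(self, bump_report,
                                                        bump_case):
        # oracle: the pipeline smooths the MA at a quarter vertebra pitch,
        # so the detector sees the smoothed bump; compute its epsilon
        # crossings from the analytic midline under the same smoothing
        from scipy import ndimage

        segs = detect_curves(bump_report.disp, epsilon=2.0)
        assert len(segs) == 1
        ma = bump_report.ma
        pitch = (ma.bottom_row - ma.top_row + 1) / 17
        true_d = bump_case.true_midline - 237.0
        smooth_d = ndimage.gaussian_filter1d(true_d, 0.25 * pitch)
        above = np.flatnonzero(np.abs(smooth_d) > 2.0)
        # |d| crosses epsilon where its gradient is shallow, so extraction
        # ripple moves the crossing rows by up to ~half a vertebra pitch
        assert segs[0].start_row == pytest.approx(above[0] - 1, abs=25)
        assert segs[0].end_row == pytest.approx(above[-1] + 1, abs=25)
        assert segs[0].apex_row == pytest.approx(462.5, abs=10)
        assert segs[0].direction == 1
        # the analytic (unsmoothed) crossings bound the detected span
        lo, hi = epsilon_crossing_rows(bump_case.spec.curves[0], 2.0)
        assert segs[0].start_row <= lo + 10
        assert segs[0].end_row >= hi - 10

    def test_s_curve_gives_two_opposite_segments(self, s_report):
        segs = [sr.segment for sr in s_report.segments]
        assert len(segs) == 2
        assert segs[0].direction == 1 and segs[1].direction == -1
        assert segs[0].end_row <= segs[1].start_row

    def test_abrupt_sign_flip_splits_segments(self):
        d = np.concatenate([np.full(100, 10.0), np.full(100, -10.0)])
        segs = detect_curves(series(d), epsilon=2.0, min_span=30)
        assert len(segs) == 2
        assert [s.direction for s in segs] == [1, -1]

    def test_short_blips_discarded(self):
        d = np.zeros(300)
        d[100:110] = 10.0  # 10-row blip < min_span
        assert detect_curves(series(d), epsilon=2.0, min_span=30) == []

    def test_open_curve_at_bottom_flagged_truncated(self):
        d = np.concatenate([np.zeros(100), np.linspace(0, 40, 100)])
        segs = detect_curves(series(d), epsilon=2.0)
        assert len(segs) == 1
        assert segs[0].truncated
        assert segs[0].end_row == 199.0

    def test_shrinking_epsilon_never_loses_segments(self, s_report):
        counts = [
            len(detect_curves(s_report.disp, epsilon=e))
            for e in (8.0, 4.0, 2.0, 1.0, 0.5)
        ]
        assert counts == sorted(counts)

    def test_sign_flip_of_signal_flips_directions_only(self, s_report):
        disp = s_report.disp
        flipped = DisplacementSeries(disp.rows, -disp.d, disp.csl_x)
        a = detect_curves(disp, 2.0)
        b = detect_curves(flipped, 2.0)
        assert [s.start_row for s in a] == [s.start_row for s in b]
        assert [s.end_row for s in a] == [s.end_row for s in b]
        assert [s.direction for s in a] == [-s.direction for s in b]

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            detect_curves(series(np.zeros(50)), epsilon=0.0)


class TestApicalVertebra:
    def test_monotone_ramp_apex_at_boundary(self):
        d = np.linspace(0, 30, 120)
        seg = CurveSegment(10.0, 60.0, 110.0, 1, 30.0)
        row, x = apical_vertebra(series(d), seg)
        assert row == 110.0
        assert x == pytest.approx(237.0 + d[110])

    def test_plateau_ties_take_smallest_row(self):
        d = np.zeros(100)
        d[40:60] = 5.0
        seg = CurveSegment(20.0, 50.0, 80.0, 1, 5.0)
        row, _ = apical_vertebra(series(d), seg)
        assert row == 40.0

    def test_refined_apex_matches_true_center_despite_ripple(self):
        rows = np.arange(400.0)
        bump = 30.0 * np.clip(1 + np.cos(np.pi * (rows - 200) / 150), 0, None) / 2
        ripple = 1.5 * np.sin(2 * np.pi * rows / 52 + 1.0)
        disp = DisplacementSeries(rows, bump + ripple, 237.0)
        seg = CurveSegment(60.0, 210.0, 340.0, 1, 30.0)
        raw_row, _ = apical_vertebra(disp, seg)
        ref_row, _ = apical_vertebra(disp, seg, refine=True)
        assert abs(ref_row - 200.0) <= 5
        assert abs(ref_row - 200.0) <= abs(raw_row - 200.0) + 1e-9

    def test_segment_outside_series_rejected(self):
        seg = CurveSegment(500.0, 550.0, 600.0, 1, 5.0)
        with pytest.raises(ValidationError):
            apical_vertebra(series(np.zeros(100)), seg)


class TestFullExtentSegment:
    def test_spans_extent_with_interior_apex(self):
        d = np.zeros(400)
        seg = full_extent_segment(series(d))
        assert seg.start_row == 0.0 and seg.end_row == 399.0
        assert 100.0 <= seg.apex_row <= 300.0


class TestLabelVertebrae:
    def make_landmarks(self, sev_row, av_row, iev_row):
        return LandmarkSet(
            sev=(sev_row, 237.0), av=(av_row, 237.0), iev=(iev_row, 237.0)
        )

    def test_midpoint_of_extent_is_t9(self):
        lms = label_vertebrae(self.make_landmarks(0, 462, 924), (0, 924))
        assert lms.vertebra_labels["av"] == "T9"

    def test_extent_ends_are_t1_and_l5(self):
        lms = label_vertebrae(self.make_landmarks(0, 462, 924), (0, 924))
        assert lms.vertebra_labels["sev"] == "T1"
        assert lms.vertebra_labels["iev"] == "L5"

    def test_row_outside_extent_rejected(self):
        with pytest.raises(ValidationError):
            label_vertebrae(self.make_landmarks(0, 462, 930), (0, 924))

    def test_band_names_cover_thoracolumbar(self):
        assert len(VERTEBRA_NAMES) == 17
        assert VERTEBRA_NAMES[0] == "T1"
        assert VERTEBRA_NAMES[11] == "T12"
        assert VERTEBRA_NAMES[12] == "L1"
        assert VERTEBRA_NAMES[-1] == "L5"

    def test_phantom_centroids_get_consistent_bands(self, bump_case,
                                                    bump_report):
        extent = (bump_report.ma.top_row, bump_report.ma.bottom_row)
        hits = 0
        for i, (row, x) in enumerate(bump_case.true_centroids):
            lms = label_vertebrae(
                LandmarkSet(sev=(row, x), av=(row, x), iev=(row, x)), extent
            )
            if lms.vertebra_labels["av"] == VERTEBRA_NAMES[i]:
                hits += 1
        assert hits >= 15
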