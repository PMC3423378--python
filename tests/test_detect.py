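"""Test-line sampling, peak detection, density, and the edit/audit loop."""

import numpy as np
import pytest

from fibrinet.detect import (
    DetectionAudit,
    Fiber,
    FiberEdit,
    TestLine,
    detect_fibers,
    detect_fibers_on_line,
    edit_fibers,
    extract_profile,
    fiber_density,
    make_test_lines,
)
from fibrinet.errors import ParameterError, UnknownFiberError
from fibrinet.image import ClotImage, preprocess
from fibrinet.synth import SceneSpec, render_scene


def _img(h=1024, w=1024):
    return ClotImage(np.zeros((h, w)) + 1.0)


class TestMakeTestLines:
    def test_standard_five_lines_match_published_rows(self):
        rows = [l.row_index for l in make_test_lines(_img(), 5)]
        # the classic LN171/341/512/682/853 sampling pattern, within 1 px
        for got, ln in zip(rows, (171, 341, 512, 682, 853)):
            assert abs(got - ln) <= 1

    def test_single_line_is_the_midline(self):
        assert [l.row_index for l in make_test_lines(_img(), 1)] == [512]

    def test_equal_spacing_small_image(self):
        rows = [l.row_index for l in make_test_lines(_img(100, 100), 4)]
        assert rows == [20, 40, 60, 80]

    def test_physical_length_follows_calibration(self):
        line = make_test_lines(_img(), 1)[0]
        assert line.length_um == pytest.approx(1024 * 57.6 / 1000.0)

    @pytest.mark.parametrize("n", [0, 2000])
    def test_out_of_range_line_count(self, n):
        with pytest.raises(ParameterError):
            make_test_lines(_img(), n)


class TestExtractProfile:
    def test_constant_image_constant_profile(self):
        img = ClotImage(np.full((64, 64), 7.0))
        line = make_test_lines(img, 1)[0]
        assert (extract_profile(img, line) == 7.0).all()

    def test_profile_equals_image_row(self):
        rng = np.random.default_rng(5)
        img = ClotImage(rng.uniform(0, 100, (64, 64)))
        line = make_test_lines(img, 1)[0]
        np.testing.assert_array_equal(extract_profile(img, line), img.pixels[32])
        transposed = ClotImage(img.pixels.T)
        line_t = TestLine(row_index=10, length_px=64, length_um=1.0)
        np.testing.assert_array_equal(
            extract_profile(transposed, line_t), img.pixels[:, 10]
        )


def _gaussian_bump(x, centre, peak, sigma=4.0):
    return peak * np.exp(-((x - centre) ** 2) / (2 * sigma**2))


class TestPeakDetection:
    def test_flat_profile_no_fibers(self):
        assert detect_fibers_on_line(np.zeros(200)) == []

    def test_three_separated_bumps_found_at_centres(self):
        x = np.arange(300, dtype=float)
        profile = (
            _gaussian_bump(x, 60, 100) + _gaussian_bump(x, 150, 150) + _gaussian_bump(x, 240, 200)
        )
        fibers = detect_fibers_on_line(profile, min_peak_au=27)
        assert [f.id for f in fibers] == [1, 2, 3]
        for f, c in zip(fibers, (60, 150, 240)):
            assert abs(f.peak_col_px - c) <= 1
        assert fibers[0].peak_intensity_au == pytest.approx(100, abs=2)

    def test_close_bumps_merge_to_higher_peak(self):
        x = np.arange(120, dtype=float)
        profile = _gaussian_bump(x, 60, 80, 1.5) + _gaussian_bump(x, 63, 120, 1.5)
        fibers = detect_fibers_on_line(profile, min_peak_au=27, min_separation_px=5)
        assert len(fibers) == 1
        assert abs(fibers[0].peak_col_px - 63) <= 1

    def test_subthreshold_peaks_ignored(self):
        x = np.arange(100, dtype=float)
        fibers = detect_fibers_on_line(_gaussian_bump(x, 50, 20), min_peak_au=27)
        assert fibers == []

    def test_empty_profile_rejected(self):
        with pytest.raises(ParameterError):
            detect_fibers_on_line(np.array([]))


class TestFiberDensity:
    def _line(self, um):
        return TestLine(row_index=0, length_px=1024, length_um=um)

    def test_zero_fibers_zero_density(self):
        assert fiber_density([], [self._line(59.0)]) == 0.0

    def test_single_line_arithmetic(self):
        fibers = [
            Fiber(id=i, line=self._line(59.0), peak_col_px=0, peak_intensity_au=50)
            for i in range(17)
        ]
        assert fiber_density(fibers, [self._line(59.0)]) == pytest.approx(28.8, abs=0.05)

    def test_five_line_arithmetic(self):
        lines = [self._line(59.0) for _ in range(5)]
        fibers = [
            Fiber(id=i, line=lines[0], peak_col_px=0, peak_intensity_au=50)
            for i in range(15)
        ]
        assert fiber_density(fibers, lines) == pytest.approx(5.08, abs=0.01)

    def test_no_lines_rejected(self):
        with pytest.raises(ParameterError):
            fiber_density([], [])


class TestEditAudit:
    def _fibers(self, n):
        line = TestLine(row_index=0, length_px=1024, length_um=59.0)
        return [
            Fiber(id=i + 1, line=line, peak_col_px=10 * i, peak_intensity_au=50)
            for i in range(n)
        ]

    def test_ppv_for_one_rejection_in_ninety(self):
        fibers = self._fibers(90)
        edits = [FiberEdit("confirm", fiber_id=i) for i in range(1, 90)]
        edits.append(FiberEdit("reject", fiber_id=90))
        kept, audit = edit_fibers(fibers, edits)
        assert audit.true_pos == 89 and audit.false_pos == 1
        assert audit.ppv_percent == pytest.approx(98.9, abs=0.05)
        assert len(kept) == 89

    def test_all_confirmed_is_perfect_ppv(self):
        fibers = self._fibers(10)
        _, audit = edit_fibers(fibers, [FiberEdit("confirm", fiber_id=i) for i in range(1, 11)])
        assert audit.ppv_percent == 100.0

    def test_additions_with_no_detections_leave_ppv_undefined(self):
        kept, audit = edit_fibers(
            [],
            [FiberEdit("add", line_row=10, col_px=5), FiberEdit("add", line_row=10, col_px=50)],
        )
        assert audit.ppv_percent is None
        assert audit.false_neg == 2
        assert len(kept) == 2 and all(f.status == "added" for f in kept)

    def test_unknown_id_rejected(self):
        with pytest.raises(UnknownFiberError):
            edit_fibers(self._fibers(2), [FiberEdit("reject", fiber_id=99)])

    def test_rejected_fibers_excluded_from_density(self):
        fibers = self._fibers(10)
        line = fibers[0].line
        kept, _ = edit_fibers(fibers, [FiberEdit("reject", fiber_id=1)])
        assert fiber_density(kept, [line]) == pytest.approx(100 * 9 / 59.0)


class TestDetectionOnGroundTruth:
    def test_per_line_counts_within_one_of_truth(self, default_scene):
        img, truth = default_scene
        pre = preprocess(img)
        fibers, lines = detect_fibers(pre)
        for line in lines:
            got = sum(1 for f in fibers if f.line.row_index == line.row_index)
            want = len(truth.line_crossings[line.row_index])
            assert abs(got - want) <= 1

    def test_density_insensitive_to_constant_background(self, default_scene):
        img, _ = default_scene
        shifted = img.with_pixels(np.clip(img.pixels * 0.9 + 15.0, 0, 255))
        f0, l0 = detect_fibers(preprocess(img))
        f1, l1 = detect_fibers(preprocess(shifted))
        d0, d1 = fiber_density(f0, l0), fiber_density(f1, l1)
        assert d1 == pytest.approx(d0, rel=0.1)

    def test_density_scales_linearly_with_fiber_count(self):
        # expectation over placements is linear; average a few seeds
        def mean_density(n_fibers):
            out = []
            for seed in (31, 32, 33, 34):
                img, _ = render_scene(SceneSpec(seed=seed, n_fibers=n_fibers))
                fibers, lines = detect_fibers(preprocess(img))
                out.append(fiber_density(fibers, lines))
            return np.mean(out)

        assert mean_density(20) == pytest.approx(2 * mean_density(10), rel=0.10)
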