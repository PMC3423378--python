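"""Fiber measurement: local maxima, FWHM diameters, MLE fits, TTR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fibrinet.detect import Fiber, TestLine, detect_fibers
from fibrinet.errors import (
    BoundaryError,
    FitError,
    ParameterError,
    WidthMeasurementError,
)
from fibrinet.image import ClotImage, preprocess
from fibrinet.metrics import (
    compute_ttr,
    diameter_intensity_relation,
    fit_distribution,
    local_max_intensity,
    measure_diameter,
    measure_fibers,
    mixture_local_minimum,
    percent_change,
)
from fibrinet.synth import FWHM_TO_SIGMA, SceneSpec, _render_segment, render_scene


def _line(row):
    return TestLine(row_index=row, length_px=128, length_um=7.4)


def _fiber_image(angle_deg=90.0, fwhm_nm=700.0, peak=120.0, size=128, px_nm=57.6):
    """A single straight fiber through the image centre."""
    canvas = np.zeros((size, size))
    sigma = fwhm_nm * FWHM_TO_SIGMA / px_nm
    c = size / 2
    dr, dc = math.sin(math.radians(angle_deg)), math.cos(math.radians(angle_deg))
    p0 = (c - 60 * dr, c - 60 * dc)
    p1 = (c + 60 * dr, c + 60 * dc)
    _render_segment(canvas, p0, p1, sigma, peak)
    return ClotImage(canvas, pixel_size_nm=px_nm)


class TestLocalMaxIntensity:
    def test_finds_off_line_maximum(self):
        img = _fiber_image()
        # brighten a spot on the fiber 4 px below the test line
        img.pixels[68, 64] += 40.0
        f = Fiber(id=1, line=_line(64), peak_col_px=64, peak_intensity_au=120)
        (r, c), val = local_max_intensity(img, f, search_radius_px=5)
        assert (r, c) == (68, 64)
        assert val == pytest.approx(img.pixels[68, 64])

    def test_uniform_fiber_tie_breaks_to_crossing(self):
        img = ClotImage(np.full((128, 128), 80.0))
        f = Fiber(id=1, line=_line(64), peak_col_px=64, peak_intensity_au=80)
        (r, c), _ = local_max_intensity(img, f, search_radius_px=4)
        assert (r, c) == (64, 64)

    def test_radius_zero_returns_crossing_value(self):
        img = _fiber_image()
        f = Fiber(id=1, line=_line(64), peak_col_px=60, peak_intensity_au=0)
        (r, c), val = local_max_intensity(img, f, search_radius_px=0)
        assert (r, c) == (64, 60)
        assert val == pytest.approx(img.pixels[64, 60])

    def test_window_outside_image_is_boundary_error(self):
        img = _fiber_image()
        f = Fiber(id=1, line=_line(2), peak_col_px=64, peak_intensity_au=0)
        with pytest.raises(BoundaryError):
            local_max_intensity(img, f, search_radius_px=5)


class TestMeasureDiameter:
    @pytest.mark.parametrize("angle", [90.0, 45.0, 120.0])
    def test_recovers_rendered_fwhm(self, angle):
        img = _fiber_image(angle_deg=angle, fwhm_nm=700.0)
        d = measure_diameter(img, (64.0, 64.0))
        assert d == pytest.approx(700.0, abs=30.0)

    def test_two_parallel_unresolved_fibers_flagged(self):
        size, px = 128, 57.6
        canvas = np.zeros((size, size))
        sigma = 400.0 * FWHM_TO_SIGMA / px
        gap = 400.0 / px  # centres 400 nm apart
        for off in (-gap / 2, gap / 2):
            _render_segment(canvas, (4, 64 + off), (124, 64 + off), sigma, 100.0)
        img = ClotImage(canvas, pixel_size_nm=px)
        try:
            d = measure_diameter(img, (64.0, 64.0))
        except WidthMeasurementError as err:
            assert err.kind in ("merged", "unresolved")
        else:
            # if a width is returned it must reflect the merged envelope,
            # never a silently doubled single-fiber reading
            assert d > 500.0

    def test_profile_that_never_falls_is_unresolved(self):
        img = ClotImage(np.full((128, 128), 90.0))
        with pytest.raises(WidthMeasurementError):
            measure_diameter(img, (64.0, 64.0), orientation_rad=0.0)


class TestDiameterIntensityRelation:
    def test_generator_linear_relation_detected(self, default_scene):
        img, _ = default_scene
        pre = preprocess(img)
        fibers, _ = detect_fibers(pre)
        measure_fibers(pre, fibers)
        slope, _, r, p = diameter_intensity_relation(fibers)
        assert slope > 0
        assert p < 0.001

    def test_uninformative_intensities_give_null_slope(self):
        rng = np.random.default_rng(7)
        line = _line(64)
        fibers = []
        for i in range(40):
            f = Fiber(id=i, line=line, peak_col_px=i, peak_intensity_au=0)
            f.local_max_intensity_au = float(rng.uniform(30, 200))
            f.diameter_nm = 700.0 + float(rng.normal(0, 5))
            fibers.append(f)
        slope, _, r, p = diameter_intensity_relation(fibers)
        # slope CI contains zero -> no significant relation
        assert p > 0.05

    def test_too_few_fibers_rejected(self):
        with pytest.raises(ParameterError):
            diameter_intensity_relation([])


class TestFitDistribution:
    def test_normal_sample_recovered(self):
        rng = np.random.default_rng(42)
        x = rng.normal(800, 50, 500)
        fit = fit_distribution(x)
        assert fit.fit_kind == "normal"
        assert fit.params["mu"] == pytest.approx(800, abs=7)

    def test_bimodal_local_minimum_matches_brute_force(self):
        # brute-force interior minimum of the true mixture density
        true = (0.6, 650.0, 50.0, 880.0, 50.0)
        grid = np.arange(650.0, 880.0, 0.1)
        dens = 0.6 * stats.norm.pdf(grid, 650, 50) + 0.4 * stats.norm.pdf(grid, 880, 50)
        true_min = grid[np.argmin(dens)]
        hits = 0
        rng = np.random.default_rng(123)
        for k in range(20):
            n1 = rng.binomial(500, 0.6)
            x = np.concatenate(
                [rng.normal(650, 50, n1), rng.normal(880, 50, 500 - n1)]
            )
            fit = fit_distribution(x, random_state=k)
            if fit.fit_kind == "bimodal" and abs(fit.local_min_nm - true_min) <= 25:
                hits += 1
        assert hits >= 18

    def test_degenerate_sample_fails(self):
        with pytest.raises(FitError):
            fit_distribution(np.full(50, 700.0))

    def test_mixture_minimum_grid_search_matches_calculus(self):
        # symmetric equal mixture: interior minimum is exactly midway
        m = mixture_local_minimum(0.5, 600.0, 40.0, 800.0, 40.0)
        assert m == pytest.approx(700.0, abs=0.2)


class TestTTR:
    def test_paper_style_count_ratios(self):
        thin = np.full(27, 700.0)
        thick = np.full(10, 800.0)
        r = compute_ttr(np.concatenate([thin, thick]), threshold_nm=761.9)
        assert (r.n_thin, r.n_thick) == (27, 10)
        assert r.ttr == pytest.approx(2.7)

    def test_equal_counts_give_unity(self):
        x = np.array([700.0, 700.0, 800.0, 800.0])
        assert compute_ttr(x, 761.9).ttr == 1.0

    def test_inverted_ratio(self):
        x = np.concatenate([np.full(7, 700.0), np.full(10, 800.0)])
        assert compute_ttr(x, 761.9).ttr == pytest.approx(0.7)

    def test_no_thick_fibers_is_flagged_infinite(self):
        r = compute_ttr(np.full(5, 400.0), 761.9)
        assert r.infinite and math.isinf(r.ttr)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            compute_ttr([])

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_free(self, c):
        rng = np.random.default_rng(9)
        x = rng.uniform(300, 1200, 50)
        base = compute_ttr(x, 761.9)
        scaled = compute_ttr(x * c, 761.9 * c)
        assert scaled.ttr == base.ttr

    @given(t1=st.floats(300, 1200), t2=st.floats(300, 1200))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(10)
        x = rng.uniform(300, 1200, 50)
        lo, hi = sorted((t1, t2))
        a, b = compute_ttr(x, lo), compute_ttr(x, hi)
        assert b.ttr >= a.ttr


class TestPercentChange:
    def test_ttr_decrease_worked_example(self):
        assert round(percent_change(2.7, 0.7)) == -74

    def test_no_change(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_increase_unrounded(self):
        assert percent_change(0.7, 1.3) == pytest.approx(85.7, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            percent_change(0.0, 1.0)
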