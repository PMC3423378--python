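"""Void porosity arithmetic and cluster/agglomerate morphometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrinet.errors import ModeError, ParameterError
from fibrinet.image import ClotImage, binarize, preprocess
from fibrinet.synth import SceneSpec, render_scene, render_stack
from fibrinet.voids import (
    Agglomerate,
    agglomerate_summary,
    detect_agglomerates,
    detect_clusters,
    fiber_area,
    has_spanning_network,
    projected_void,
    void_area,
    void_volume,
)


class TestVoidArea:
    def test_all_black_is_total_void(self):
        assert void_area(np.zeros((64, 64), bool)) == 100.0

    def test_checkerboard_is_half(self):
        mask = np.indices((64, 64)).sum(axis=0) % 2 == 0
        assert void_area(mask) == 50.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_void_plus_fiber_is_exactly_100(self, seed):
        mask = np.random.default_rng(seed).random((32, 32)) > 0.5
        assert void_area(mask) + fiber_area(mask) == 100.0

    def test_tracks_generator_footprint(self, default_scene):
        img, truth = default_scene
        mask = binarize(img, 27.0)
        assert void_area(mask) == pytest.approx(
            100.0 * (1 - truth.footprint_fraction), abs=2.0
        )


class TestProjection:
    def test_identical_masks_project_to_themselves(self):
        m = np.random.default_rng(1).random((64, 64)) > 0.7
        _, pct = projected_void([m, m, m])
        assert pct == void_area(m)

    def test_disjoint_fiber_sets_add(self):
        masks = []
        for k in range(3):
            m = np.zeros((100, 100), bool)
            m[k * 10 : k * 10 + 10] = True  # each slice 10% fiber
            masks.append(m)
        _, pct = projected_void(masks)
        assert pct == pytest.approx(70.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_projection_never_exceeds_any_slice_void(self, seed):
        rng = np.random.default_rng(seed)
        masks = [rng.random((32, 32)) > 0.6 for _ in range(3)]
        _, pct = projected_void(masks)
        assert pct <= min(void_area(m) for m in masks) + 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            projected_void([np.zeros((10, 10), bool), np.zeros((12, 12), bool)])


class TestVoidVolume:
    def test_mean_of_slices(self):
        masks = []
        for pct in (60, 70, 80):
            m = np.zeros((100, 100), bool)
            m[: 100 - pct] = True
            masks.append(m)
        assert void_volume(masks) == pytest.approx(70.0)

    def test_all_black_stack_is_fully_void(self):
        assert void_volume([np.zeros((64, 64), bool)] * 3) == 100.0

    def test_single_slice_rejected(self):
        with pytest.raises(ParameterError):
            void_volume([np.zeros((64, 64), bool)])

    def test_matches_truth_footprint_arithmetic(self):
        spec = SceneSpec(seed=41, noise_sd_au=0.0)
        stack, truths = render_stack(spec, n_slices=3)
        masks = [binarize(s, 27.0) for s in stack.slices]
        oracle = 100.0 * (1 - np.mean([t.footprint_fraction for t in truths]))
        assert void_volume(masks) == pytest.approx(oracle, abs=1.0)


class TestDetectClusters:
    def test_cluster_scene_finds_the_cluster(self):
        spec = SceneSpec(
            seed=91, n_fibers=12, diameter_dist=("normal", 735.0, 45.0), n_clusters=1
        )
        img, truth = render_scene(spec)
        found = detect_clusters(preprocess(img))
        assert len(found) == 1
        c = found[0]
        t = truth.clusters[0]
        assert np.hypot(
            c.core_centroid[0] - t.centroid[0], c.core_centroid[1] - t.centroid[1]
        ) < 25
        assert abs(c.n_protruding_fibers - t.n_protrusions) <= 2

    def test_normal_networks_have_no_clusters(self):
        for seed in (2000, 2001, 2002, 2003, 2004):
            img, _ = render_scene(SceneSpec(seed=seed, n_branches=7, n_crossings=9))
            assert detect_clusters(preprocess(img)) == []

    def test_smooth_bright_bead_fails_protrusion_rule(self):
        px = np.zeros((512, 512))
        rr, cc = np.ogrid[:512, :512]
        px[(rr - 256) ** 2 + (cc - 256) ** 2 < 20**2] = 240.0
        img = ClotImage(px)
        assert detect_clusters(img) == []


class TestDetectAgglomerates:
    def test_blob_field_counts_and_long_axes(self):
        spec = SceneSpec(seed=101, n_fibers=0, n_agglomerates=40)
        img, truth = render_scene(spec)
        aggs = detect_agglomerates(preprocess(img))
        assert abs(len(aggs) - 40) <= 2
        # match each detection to the nearest truth blob
        errs = []
        for a in aggs:
            d = [
                np.hypot(a.centroid[0] - t.centroid[0], a.centroid[1] - t.centroid[1])
                for t in truth.agglomerates
            ]
            t = truth.agglomerates[int(np.argmin(d))]
            errs.append(abs(a.long_axis_um - t.long_axis_um))
        assert np.mean(errs) <= 0.2

    def test_empty_image_has_none(self):
        img = ClotImage(np.zeros((512, 512)))
        assert detect_agglomerates(img) == []

    def test_single_ellipse_major_axis(self):
        px_um = 57.6 / 1000.0
        px = np.zeros((512, 512))
        rr, cc = np.ogrid[:512, :512]
        a = 4.0 / px_um  # semi-major 4 um -> long axis 8 um
        b = 1.0 / px_um
        px[((rr - 256) / b) ** 2 + ((cc - 256) / a) ** 2 <= 1] = 200.0
        img = ClotImage(px)
        aggs = detect_agglomerates(img)
        assert len(aggs) == 1
        assert aggs[0].long_axis_um == pytest.approx(8.0, abs=0.2)
        assert aggs[0].shape_class == "irregular"

    def test_network_image_raises_mode_error(self, default_scene):
        img, _ = default_scene
        pre = preprocess(img)
        assert has_spanning_network(pre)
        with pytest.raises(ModeError):
            detect_agglomerates(pre)

    def test_count_invariant_under_rotation(self):
        spec = SceneSpec(seed=103, n_fibers=0, n_agglomerates=20)
        img, _ = render_scene(spec)
        pre = preprocess(img)
        n0 = len(detect_agglomerates(pre))
        rot = ClotImage(np.rot90(pre.pixels).copy(), pixel_size_nm=pre.pixel_size_nm)
        assert len(detect_agglomerates(rot)) == n0


class TestAgglomerateSummary:
    def _aggs(self, axes):
        return [
            Agglomerate(centroid=(0, 0), long_axis_um=x, area_um2=1.0, shape_class="spherical")
            for x in axes
        ]

    def test_mean_and_fraction(self):
        mean, _, frac = agglomerate_summary(self._aggs([2, 3, 4]), capillary_diameter_um=5)
        assert mean == pytest.approx(3.0)
        assert frac == 0.0

    def test_fraction_above_capillary(self):
        _, _, frac = agglomerate_summary(self._aggs([1, 6]), capillary_diameter_um=5)
        assert frac == 50.0

    def test_matches_truth_list_arithmetic(self):
        spec = SceneSpec(seed=104, n_fibers=0, n_agglomerates=30)
        img, truth = render_scene(spec)
        aggs = detect_agglomerates(preprocess(img))
        mean, _, frac = agglomerate_summary(aggs)
        truth_axes = np.array([t.long_axis_um for t in truth.agglomerates])
        assert mean == pytest.approx(float(truth_axes.mean()), abs=0.2)
        assert frac == pytest.approx(100.0 * float((truth_axes > 5).mean()), abs=8.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            agglomerate_summary([])
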