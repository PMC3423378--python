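"""Ground-truth validation suites.

Each function renders seeded synthetic scenes, runs the corresponding
measurement operators, and scores them against the generator's ground
truth.  These suites are what the package's accuracy claims rest on: the
synthetic fields emulate the imaging phenotypes (Gaussian-profile fibers,
additive crossings, width-conserving junctions, cluster and agglomerate
structures) but not every property of real multiphoton data, so the scores
certify the operators, not any particular biological result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from . import detect as _detect
from . import metrics as _metrics
from . import voids as _voids
from .errors import WidthMeasurementError
from .image import binarize, preprocess
from .synth import (
    DEFAULT_DOSE_TREND,
    SceneSpec,
    render_scene,
    render_stack,
)
from .topology import classify_branch, classify_crossing


def detection_recovery(seed: int = 0, n_scenes: int = 20) -> dict:
    """Per-line fiber-count and density recovery on seeded network scenes.

    Scenes carry 15-35 fibers in the standard 59 um field at SNR >> 10.
    Returns the worst per-line count error (fibers), and the mean and worst
    relative density error (%) against truth-crossing arithmetic.
    """
    rng = np.random.default_rng(seed)
    max_line_err = 0
    density_errs = []
    for k in range(n_scenes):
        n_fibers = int(rng.integers(15, 36))
        spec = SceneSpec(seed=int(rng.integers(0, 2**31 - 1)), n_fibers=n_fibers)
        img, truth = render_scene(spec)
        pre = preprocess(img)
        fibers, lines = _detect.detect_fibers(pre)
        for line in lines:
            got = sum(1 for f in fibers if f.line.row_index == line.row_index)
            want = len(truth.line_crossings[line.row_index])
            max_line_err = max(max_line_err, abs(got - want))
        total_um = sum(l.length_um for l in lines)
        truth_density = 100.0 * sum(
            len(v) for v in truth.line_crossings.values()
        ) / total_um
        measured = _detect.fiber_density(fibers, lines)
        density_errs.append(100.0 * abs(measured - truth_density) / truth_density)
    return {
        "n_scenes": n_scenes,
        "max_per_line_count_error": int(max_line_err),
        "mean_density_error_pct": float(np.mean(density_errs)),
        "max_density_error_pct": float(np.max(density_errs)),
    }


def diameter_recovery(seed: int = 0, n_fibers: int = 50) -> dict:
    """FWHM diameter recovery on noise-free fibers spanning 400-1000 nm."""
    rng = np.random.default_rng(seed)
    errs = []
    while len(errs) < n_fibers:
        spec = SceneSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_fibers=8,
            noise_sd_au=0.0,
            diameter_dist=("uniform", 400.0, 1000.0),
        )
        img, truth = render_scene(spec)
        by_id = {f.id: f for f in truth.fibers}
        for row, crossings in truth.line_crossings.items():
            for col, fid in crossings:
                f = by_id[fid]
                line = _detect.TestLine(row, img.width_px, 59.0)
                fib = _detect.Fiber(
                    id=fid, line=line, peak_col_px=int(round(col)),
                    peak_intensity_au=f.peak_au,
                )
                try:
                    (r, c), _ = _metrics.local_max_intensity(img, fib)
                    d = _metrics.measure_diameter(img, (r, c))
                except (WidthMeasurementError, Exception):
                    continue
                errs.append(abs(d - f.diameter_nm))
                if len(errs) >= n_fibers:
                    break
            if len(errs) >= n_fibers:
                break
    return {"n_fibers": len(errs), "mae_nm": float(np.mean(errs))}


TRUE_MIXTURE = (0.6, 650.0, 50.0, 880.0, 50.0)


def true_mixture_minimum(mix=TRUE_MIXTURE, step_nm: float = 0.1) -> float:
    """Brute-force interior minimum of the true mixture density."""
    w, m1, s1, m2, s2 = mix
    grid = np.arange(m1, m2, step_nm)
    dens = w * stats.norm.pdf(grid, m1, s1) + (1 - w) * stats.norm.pdf(grid, m2, s2)
    return float(grid[np.argmin(dens)])


def bimodal_minimum_recovery(
    seed: int = 0, n_runs: int = 20, n_sample: int = 300, tol_nm: float = 25.0
) -> dict:
    """How often MLE mixture fitting recovers the thin/thick split point.

    Each run draws ``n_sample`` diameters from the stated mixture, fits by
    EM, and compares the fitted density's interior minimum against the
    brute-force minimum of the *true* density.
    """
    target = true_mixture_minimum()
    w, m1, s1, m2, s2 = TRUE_MIXTURE
    rng = np.random.default_rng(seed)
    hits = 0
    for k in range(n_runs):
        n1 = rng.binomial(n_sample, w)
        x = np.concatenate(
            [rng.normal(m1, s1, n1), rng.normal(m2, s2, n_sample - n1)]
        )
        try:
            fit = _metrics.fit_distribution(x, random_state=int(rng.integers(0, 2**31 - 1)))
        except Exception:
            continue
        if fit.fit_kind == "bimodal" and abs(fit.local_min_nm - target) <= tol_nm:
            hits += 1
    return {"n_runs": n_runs, "hits": hits, "true_minimum_nm": target}


def branch_classification(seed: int = 0, n_events: int = 30) -> dict:
    """Accuracy of the width-conservation rule on rendered junctions.

    Widths of the three arms are measured from the image (FWHM ~1.7 um out
    from the junction along each arm's known axis) and fed to the
    classifier; every rendered junction conserves width exactly in truth.
    The two daughter arms lie on the same side of the junction, so their
    perpendicular profiles use a short window that cannot reach the
    neighbouring arm.  Events are rendered without a background network so
    each measured width is attributable to its own junction.
    """
    rng = np.random.default_rng(seed)
    correct = total = 0
    while total < n_events:
        spec = SceneSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_fibers=0,
            n_branches=6,
            noise_sd_au=2.0,
        )
        img, truth = render_scene(spec)
        offsets_px = [nm / img.pixel_size_nm for nm in (1300.0, 1700.0, 2100.0)]
        for b in truth.branches:
            widths = []
            for k, ang in enumerate(b.arm_angles):
                # trunk arm can be ~1 um wide: use a long window so the
                # background sits clear of its tails; daughters use a short
                # window that cannot reach the neighbouring arm
                halfwidth = 30 if k == 0 else 12
                cuts = []
                for off in offsets_px:
                    pos = (
                        b.position[0] + off * math.sin(ang),
                        b.position[1] + off * math.cos(ang),
                    )
                    try:
                        cuts.append(
                            _metrics.measure_diameter(
                                img, pos, orientation_rad=ang, halfwidth_px=halfwidth
                            )
                        )
                    except WidthMeasurementError:
                        continue
                if not cuts:
                    widths = None
                    break
                widths.append(float(np.median(cuts)))
            total += 1
            if widths is not None and classify_branch(widths) == "branch":
                correct += 1
            if total >= n_events:
                break
    return {"n_events": total, "accuracy_pct": 100.0 * correct / total}


def crossing_classification(seed: int = 0, n_events: int = 30) -> dict:
    """Accuracy of the proportional-increase rule on rendered events.

    Positive events are additive crossings (expected "contact"); negative
    events are isolated fibers probed at a random point on their axis
    (expected "pass_over" on the partner-free profile pairing).
    """
    rng = np.random.default_rng(seed)
    correct = total = 0
    while total < n_events:
        spec = SceneSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_fibers=4,
            n_crossings=6,
            noise_sd_au=2.0,
        )
        img, truth = render_scene(spec)
        for cross in truth.crossings:
            profs = []
            for p0, p1 in cross.segments:
                t = np.linspace(0, 1, 81)
                rows = p0[0] + t * (p1[0] - p0[0])
                cols = p0[1] + t * (p1[1] - p0[1])
                profs.append(
                    map_coordinates(img.pixels, [rows, cols], order=1, mode="nearest")
                )
            c = classify_crossing(profs[0], profs[1], 40)
            total += 1
            correct += c.kind == "contact"
            if total >= n_events:
                break
    return {"n_events": total, "accuracy_pct": 100.0 * correct / total}


def void_checks(seed: int = 0, n_stacks: int = 5) -> dict:
    """Void arithmetic oracles on random stacks.

    Checks the exact complement identity, the projection-containment
    property, and truth-footprint agreement of void volume on noise-free
    stacks.
    """
    rng = np.random.default_rng(seed)
    identity_err = 0.0
    containment_viol = 0
    volume_err = 0.0
    for k in range(n_stacks):
        spec = SceneSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_fibers=int(rng.integers(10, 25)),
            noise_sd_au=0.0,
        )
        stack, truths = render_stack(spec, n_slices=3)
        masks = [binarize(s, 27.0) for s in stack.slices]
        for m in masks:
            identity_err = max(
                identity_err, abs(_voids.void_area(m) + _voids.fiber_area(m) - 100.0)
            )
        _, proj = _voids.projected_void(masks)
        if proj > min(_voids.void_area(m) for m in masks) + 1e-9:
            containment_viol += 1
        oracle = 100.0 * (1 - np.mean([t.footprint_fraction for t in truths]))
        volume_err = max(volume_err, abs(_voids.void_volume(masks) - oracle))
    return {
        "n_stacks": n_stacks,
        "identity_max_abs_error": float(identity_err),
        "containment_violations": int(containment_viol),
        "void_volume_max_abs_error": float(volume_err),
    }


@dataclass
class DoseSeriesResult:
    labels: list[str]
    density: list[float]
    mean_diameter_nm: list[float | None]
    void_percent: list[float]
    clusters_detected: list[int]
    agglomerates_detected: list[int]

    @property
    def density_strictly_decreasing(self) -> bool:
        return all(a > b for a, b in zip(self.density, self.density[1:]))

    @property
    def diameter_max_is_interior(self) -> bool:
        diam = [d for d in self.mean_diameter_nm if d is not None]
        k = int(np.argmax(diam))
        return 0 < k < len(diam) - 1

    @property
    def cluster_onset_index(self) -> int | None:
        # a dose counts as cluster-positive when detections are not a
        # one-off (>= 2 across replicates)
        idx = [i for i, n in enumerate(self.clusters_detected) if n >= 2]
        return min(idx) if idx else None

    @property
    def agglomerate_onset_index(self) -> int | None:
        idx = [i for i, n in enumerate(self.agglomerates_detected) if n >= 2]
        return min(idx) if idx else None

    @property
    def void_flat_before_onset(self) -> bool:
        k = self.cluster_onset_index
        if k is None:
            return False
        pre = self.void_percent[:k]
        return (max(pre) - min(pre)) <= 5.0

    @property
    def void_rises_after_onset(self) -> bool:
        k = self.cluster_onset_index
        if k is None or k == 0:
            return False
        return all(
            b > a for a, b in zip(self.void_percent[k - 1 :], self.void_percent[k:])
        )


def dose_series_summary(seed: int = 0, replicates: int = 3) -> DoseSeriesResult:
    """Run the full pipeline over the default virtual dose series.

    Each dose is rendered and measured in ``replicates`` independent scenes
    (the imaging protocol this emulates ran triplicates) and the replicate
    means are reported.
    """
    labels, density, diameter, void = [], [], [], []
    clusters, aggs = [], []
    for k, (label, overrides) in enumerate(DEFAULT_DOSE_TREND):
        dens_r, diam_r, void_r = [], [], []
        n_cl = n_ag = 0
        for rep in range(replicates):
            spec = SceneSpec(
                seed=(seed * 100 + k) * 10 + rep, label=label, **overrides
            )
            img, truth = render_scene(spec)
            pre = preprocess(img)
            void_r.append(_voids.void_area(binarize(pre, 27.0)))
            if spec.n_fibers > 0:
                fibers, lines = _detect.detect_fibers(pre)
                dens_r.append(_detect.fiber_density(fibers, lines))
                _metrics.measure_fibers(pre, fibers)
                ds = [f.diameter_nm for f in fibers if f.diameter_nm is not None]
                if ds:
                    diam_r.append(float(np.mean(ds)))
                n_cl += len(_voids.detect_clusters(pre))
            else:
                dens_r.append(0.0)
                n_ag += len(_voids.detect_agglomerates(pre))
        labels.append(label)
        density.append(float(np.mean(dens_r)))
        diameter.append(float(np.mean(diam_r)) if diam_r else None)
        void.append(float(np.mean(void_r)))
        clusters.append(n_cl)
        aggs.append(n_ag)
    return DoseSeriesResult(labels, density, diameter, void, clusters, aggs)
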