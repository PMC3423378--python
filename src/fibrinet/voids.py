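"""Void area/volume and abnormal-structure morphometry.

Binarized clot images (white = fiber, black = void) support three simple
porosity measures: per-slice void area, projected void area over a short
z-stack (pixelwise OR of the fiber masks), and void volume as the equal-slab
mean of per-slice void fractions.  The same binary/intensity machinery also
detects two abnormal phenotypes of inhibited polymerization: *fibrin
clusters* (irregular high-intensity cores with >= 8 thin fibers protruding
from the periphery, embedded in a network) and *fibrin agglomerates*
(isolated 0.5-8 um particles suspended in plasma once no network spans the
field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label, regionprops

from .errors import ModeError, ParameterError
from .image import DEFAULT_BINARIZE_THRESHOLD_AU, ClotImage, binarize
from .detect import standard_rows
from .metrics import DEFAULT_THIN_THICK_NM


def void_area(mask: np.ndarray) -> float:
    """Percent of black (void) pixels in a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    return 100.0 * float((~mask).mean())


def fiber_area(mask: np.ndarray) -> float:
    """Percent of white (fiber) pixels; complements :func:`void_area`."""
    return 100.0 * float(np.asarray(mask, dtype=bool).mean())


def projected_void(stack_masks: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    """OR-combine fiber masks across slices; return (projection, void %)."""
    masks = [np.asarray(m, dtype=bool) for m in stack_masks]
    if len(masks) < 2:
        raise ParameterError("projection needs >= 2 masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ParameterError("masks must share dimensions")
    proj = np.logical_or.reduce(masks)
    return proj, void_area(proj)


def void_volume(stack_masks: Sequence[np.ndarray]) -> float:
    """Stack void volume (%): unweighted mean of per-slice void areas.

    Slab model -- each slice stands for an equal-thickness slab.
    """
    masks = list(stack_masks)
    if len(masks) < 2:
        raise ParameterError("void volume needs >= 2 slices")
    return float(np.mean([void_area(m) for m in masks]))


@dataclass
class VoidResult:
    void_area_percent_per_slice: list[float]
    void_volume_percent: float
    projected_void_percent: float


def analyze_voids(
    stack_masks: Sequence[np.ndarray],
) -> VoidResult:
    per_slice = [void_area(m) for m in stack_masks]
    _, proj = projected_void(stack_masks)
    return VoidResult(
        void_area_percent_per_slice=per_slice,
        void_volume_percent=void_volume(stack_masks),
        projected_void_percent=proj,
    )


@dataclass
class FibrinCluster:
    core_centroid: tuple[float, float]
    core_area_um2: float
    n_protruding_fibers: int
    mean_protrusion_diameter_nm: float | None


@dataclass
class Agglomerate:
    centroid: tuple[float, float]
    long_axis_um: float
    area_um2: float
    shape_class: str  # "spherical" | "irregular"
    has_blunted_fibers: bool = False


@dataclass
class StructureCatalog:
    clusters: list[FibrinCluster]
    agglomerates: list[Agglomerate]
    field_area_um2: float

    @property
    def cluster_density_per_mm2(self) -> float:
        return len(self.clusters) / self.field_area_um2 * 1e6

    @property
    def agglomerate_density_per_mm2(self) -> float:
        return len(self.agglomerates) / self.field_area_um2 * 1e6


def _radial_protrusions(
    pixels: np.ndarray,
    core_mask: np.ndarray,
    centroid: tuple[float, float],
    pixel_size_nm: float,
    min_au: float,
    n_bins: int,
    thin_threshold_nm: float,
    ray_start_px: int = 4,
    ray_length_px: int = 20,
) -> tuple[int, float | None]:
    """Count thin fibers radiating outward from a core.

    For each angular bin about the core centroid a radial ray is cast from
    just outside the core boundary over ``ray_length_px``; a bin is "hot"
    when the ray stays bright (its minimum intensity >= ``min_au``) along
    its whole length.  A genuine protrusion is a radial ridge and keeps the
    whole ray bright; a fiber merely passing near the core lights a ray
    only briefly and fails the minimum test.  Contiguous hot runs are one
    protrusion each; only runs with arc width below the thin-fiber
    threshold count.  Returns ``(count, mean_width_nm)``.
    """
    from scipy.ndimage import map_coordinates

    rr, cc = np.nonzero(core_mask)
    ang = np.arctan2(rr - centroid[0], cc - centroid[1])
    radius = np.hypot(rr - centroid[0], cc - centroid[1])
    bins = ((ang + math.pi) / (2 * math.pi) * n_bins).astype(int) % n_bins
    r_edge = np.zeros(n_bins)
    for b, r in zip(bins, radius):
        r_edge[b] = max(r_edge[b], r)
    r_edge[r_edge == 0] = radius.max() if radius.size else 1.0
    theta = (np.arange(n_bins) + 0.5) / n_bins * 2 * math.pi - math.pi
    hot = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        t = np.arange(r_edge[b] + ray_start_px, r_edge[b] + ray_start_px + ray_length_px)
        rows = centroid[0] + t * np.sin(theta[b])
        cols = centroid[1] + t * np.cos(theta[b])
        vals = map_coordinates(pixels, [rows, cols], order=1, mode="constant")
        hot[b] = bool(vals.min() >= min_au)
    # circular closing: a single cold bin inside a run is sampling noise,
    # not a real gap -- fill it so a thick arm cannot splinter into
    # several spuriously thin runs
    hot = hot | (np.roll(hot, 1) & np.roll(hot, -1))
    if not hot.any():
        return 0, None
    if hot.all():
        return 1, None
    start = int(np.argmin(hot))
    hot_r = np.roll(hot, -start)
    edge_r = np.roll(r_edge, -start)
    widths_nm: list[float] = []
    k = 0
    while k < n_bins:
        if not hot_r[k]:
            k += 1
            continue
        j = k
        while j < n_bins and hot_r[j]:
            j += 1
        r_mid = float(np.mean(edge_r[k:j])) + ray_start_px + ray_length_px / 2.0
        arc_nm = (j - k) * (2 * math.pi / n_bins) * r_mid * pixel_size_nm
        if j - k >= 2 and arc_nm < thin_threshold_nm:
            widths_nm.append(arc_nm)
        k = j
    if not widths_nm:
        return 0, None
    return len(widths_nm), float(np.mean(widths_nm))


def detect_clusters(
    img: ClotImage,
    thin_threshold_nm: float = DEFAULT_THIN_THICK_NM,
    core_percentile: float = 99.0,
    min_core_area_um2: float = 0.5,
    max_core_axis_um: float = 8.0,
    max_solidity: float = 0.9,
    min_protrusions: int = 9,
    protrusion_min_au: float = DEFAULT_BINARIZE_THRESHOLD_AU,
    n_angle_bins: int = 120,
) -> list[FibrinCluster]:
    """Detect fibrin clusters: irregular bright cores with >= 8 thin
    protruding fibers.

    Cores are connected components above the ``core_percentile`` intensity
    cut with area >= ``min_core_area_um2``, long axis <= ``max_core_axis_um``
    (a whole bright fiber ridge is not a core) and solidity <
    ``max_solidity`` (irregular outline); protruding fibers are counted as
    sustained radial intensity ridges just outside the core boundary, each
    thinner than the thin-fiber threshold.  The count must strictly exceed
    8 (the defining ">8-10 thin fibers" phenotype); ordinary junctions,
    crossings and multi-fiber nexuses have at most ~8 radial arms, and
    theirs are thick, so they fail the rule.
    """
    px_um = img.pixel_size_nm / 1000.0
    min_area_px = min_core_area_um2 / (px_um * px_um)
    cut = np.percentile(img.pixels, core_percentile)
    cores = label(img.pixels >= cut)
    out: list[FibrinCluster] = []
    for region in regionprops(cores):
        if (
            region.area < min_area_px
            or region.axis_major_length * px_um > max_core_axis_um
            or region.solidity >= max_solidity
        ):
            continue
        core_mask = cores == region.label
        count, mean_width = _radial_protrusions(
            img.pixels,
            core_mask,
            region.centroid,
            img.pixel_size_nm,
            protrusion_min_au,
            n_angle_bins,
            thin_threshold_nm,
        )
        if count >= min_protrusions:
            out.append(
                FibrinCluster(
                    core_centroid=tuple(region.centroid),
                    core_area_um2=float(region.area) * px_um * px_um,
                    n_protruding_fibers=count,
                    mean_protrusion_diameter_nm=mean_width,
                )
            )
    return out


def has_spanning_network(
    img: ClotImage,
    threshold_au: float = DEFAULT_BINARIZE_THRESHOLD_AU,
) -> bool:
    """True when some connected fibrin component crosses >= 2 standard
    test-line rows -- i.e. an extended fiber, not an isolated particle.

    An isolated agglomerate (<= 8 um) is far smaller than the spacing of
    the standard test lines, so only a network-scale fiber can register on
    two of them.
    """
    mask = binarize(img, threshold_au)
    if not mask.any():
        return False
    rows = standard_rows(img.height_px)
    labels = label(mask)
    hits = [np.unique(labels[r]) for r in rows]
    seen: dict[int, int] = {}
    for row_labels in hits:
        for lab in row_labels:
            if lab == 0:
                continue
            seen[lab] = seen.get(lab, 0) + 1
            if seen[lab] >= 2:
                return True
    return False


def detect_agglomerates(
    img: ClotImage,
    threshold_au: float = DEFAULT_BINARIZE_THRESHOLD_AU,
    min_equiv_diameter_um: float = 0.3,
    max_long_axis_um: float = 20.0,
    spherical_aspect: float = 1.3,
) -> list[Agglomerate]:
    """Detect isolated fibrin agglomerates in a network-free field.

    Connected components of the binarized image with equivalent diameter
    >= 0.3 um become agglomerates; the long axis is the component's
    major-axis length, and shape class is by aspect ratio (< 1.3 spherical).
    Raises :class:`ModeError` when a spanning fibrin network is present --
    such images belong to the network analysis path.
    """
    if has_spanning_network(img, threshold_au):
        raise ModeError(
            "image contains a spanning fibrin network; run the network "
            "analysis pipeline instead of agglomerate morphometry"
        )
    px_um = img.pixel_size_nm / 1000.0
    mask = binarize(img, threshold_au)
    out: list[Agglomerate] = []
    for region in regionprops(label(mask)):
        equiv_um = region.equivalent_diameter_area * px_um
        if equiv_um < min_equiv_diameter_um:
            continue
        long_axis = region.axis_major_length * px_um
        if not (min_equiv_diameter_um <= long_axis <= max_long_axis_um):
            continue
        minor = region.axis_minor_length * px_um
        aspect = long_axis / minor if minor > 0 else math.inf
        out.append(
            Agglomerate(
                centroid=tuple(region.centroid),
                long_axis_um=float(long_axis),
                area_um2=float(region.area) * px_um * px_um,
                shape_class="spherical" if aspect < spherical_aspect else "irregular",
            )
        )
    return out


def agglomerate_summary(
    aggs: Sequence[Agglomerate],
    capillary_diameter_um: float = 5.0,
    bin_width_um: float = 0.5,
    hist_max_um: float = 10.0,
) -> tuple[float, tuple[np.ndarray, np.ndarray], float]:
    """Mean long axis, histogram, and percent larger than a capillary.

    Returns ``(mean_long_axis_um, (counts, bin_edges), fraction_above_pct)``.
    """
    if not aggs:
        raise ParameterError("no agglomerates to summarize")
    axes = np.array([a.long_axis_um for a in aggs])
    edges = np.arange(0.0, hist_max_um + bin_width_um, bin_width_um)
    counts, edges = np.histogram(axes, bins=edges)
    frac_above = 100.0 * float(np.mean(axes > capillary_diameter_um))
    return float(axes.mean()), (counts, edges), frac_above
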