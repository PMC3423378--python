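"""Synthetic fibrin-network image generator with complete ground truth.

Emulates the phenotypes seen in multiphoton images of plasma fibrin clots:
randomly oriented bright fibers with Gaussian cross-sections (FWHM =
diameter, 400-1000 nm scale) on a dark background, peak intensity linear in
diameter, additive intensity where fibers overlap, trifunctional branch
junctions obeying width conservation (F1 = F2 + F3), irregular
high-intensity cluster cores with thin radiating fibers, isolated
agglomerate blobs, and additive Gaussian detector noise.  Every rendered
object is recorded once in the ground truth, so each measurement operator
can be validated without real data.

Generator design choices (see the methods note for rationale):

* fibers are straight chords of the field with orientations *stratified*
  over [10 deg, 170 deg] -- isotropic in expectation but with low sampling
  variance, and excluding fibers nearly parallel to the horizontal test
  lines, for which line stereology is degenerate;
* fibers are placed by rejection sampling so that their crossings on the
  standard test lines stay at least ``min_line_separation_px`` apart
  (resolvable, non-overlapping crossings);
* branch/crossing/cluster structures are kept clear of the standard
  test-line rows so the stereological fiber counts remain interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import PackingError, ParameterError
from .image import ClotImage, ClotStack
from .detect import standard_rows

DEFAULT_FIELD_UM = 59.0
DEFAULT_PIXEL_SIZE_NM = 57.6
DEFAULT_INTENSITY_PER_NM = 0.12  # au of peak intensity per nm of diameter
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SceneSpec:
    """Parameters of one synthetic clot field.

    ``diameter_dist`` is ``("normal", mu, sigma)``, ``("uniform", lo, hi)``
    or ``("bimodal", w, mu1, sigma1, mu2, sigma2)`` in nm; sampled diameters
    are truncated to (250, 1450) nm.  Peak intensity is
    ``intensity_per_nm * diameter`` (the diameter-fluorescence relation is
    exactly linear in truth).  A fixed seed gives a bit-identical scene.
    """

    n_fibers: int = 26
    diameter_dist: tuple = ("normal", 670.0, 45.0)
    field_um: float = DEFAULT_FIELD_UM
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    intensity_per_nm: float = DEFAULT_INTENSITY_PER_NM
    n_branches: int = 0
    n_crossings: int = 0
    n_clusters: int = 0
    n_agglomerates: int = 0
    noise_sd_au: float = 3.0
    seed: int = 0
    min_angle_deg: float = 10.0
    min_line_separation_px: int = 24
    line_clearance_px: int = 50
    label: str = ""

    def __post_init__(self):
        for name in ("n_fibers", "n_branches", "n_crossings", "n_clusters",
                     "n_agglomerates"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.field_um <= 0 or self.pixel_size_nm <= 0:
            raise ParameterError("field and pixel size must be positive")

    @property
    def size_px(self) -> int:
        return int(round(self.field_um * 1000.0 / self.pixel_size_nm))


@dataclass
class FiberTruth:
    id: int
    p0: tuple[float, float]  # (row, col) px
    p1: tuple[float, float]
    diameter_nm: float
    peak_au: float
    angle_deg: float


@dataclass
class BranchTruth:
    position: tuple[float, float]
    widths_nm: tuple[float, float, float]  # (F1, F2, F3), F1 = F2 + F3
    arm_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians


@dataclass
class CrossingTruth:
    position: tuple[float, float]
    segment_ids: tuple[int, int]
    segments: tuple[tuple, tuple]  # ((p0, p1), (p0, p1)) in px
    diameters_nm: tuple[float, float]
    peaks_au: tuple[float, float]


@dataclass
class ClusterTruth:
    centroid: tuple[float, float]
    core_radius_px: float
    n_protrusions: int
    protrusion_diameter_nm: float


@dataclass
class AgglomerateTruth:
    centroid: tuple[float, float]
    long_axis_um: float
    aspect: float


@dataclass
class GroundTruth:
    fibers: list[FiberTruth] = field(default_factory=list)
    branches: list[BranchTruth] = field(default_factory=list)
    crossings: list[CrossingTruth] = field(default_factory=list)
    clusters: list[ClusterTruth] = field(default_factory=list)
    agglomerates: list[AgglomerateTruth] = field(default_factory=list)
    # per standard test line row -> list of (col, fiber_id)
    line_crossings: dict[int, list[tuple[float, int]]] = field(default_factory=dict)
    footprint_fraction: float = 0.0  # noise-free pixels >= 27 au


def _render_segment(canvas, p0, p1, sigma_px, peak):
    """Add one Gaussian-profile segment to the canvas (additive)."""
    h, w = canvas.shape
    pad = int(math.ceil(3.5 * sigma_px + 2))
    r_lo = max(0, int(math.floor(min(p0[0], p1[0]))) - pad)
    r_hi = min(h, int(math.ceil(max(p0[0], p1[0]))) + pad + 1)
    c_lo = max(0, int(math.floor(min(p0[1], p1[1]))) - pad)
    c_hi = min(w, int(math.ceil(max(p0[1], p1[1]))) + pad + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij"
    )
    vr, vc = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vr * vr + vc * vc
    if L2 == 0:
        d2 = (rr - p0[0]) ** 2 + (cc - p0[1]) ** 2
    else:
        t = np.clip(((rr - p0[0]) * vr + (cc - p0[1]) * vc) / L2, 0.0, 1.0)
        d2 = (rr - (p0[0] + t * vr)) ** 2 + (cc - (p0[1] + t * vc)) ** 2
    canvas[r_lo:r_hi, c_lo:c_hi] += peak * np.exp(-d2 / (2.0 * sigma_px * sigma_px))


def _chord_through(point, angle_deg, size):
    """Endpoints of the full chord through ``point`` at ``angle_deg``.

    Angle measured from the +column axis; direction (row, col) =
    (sin, cos).  Returns None when the chord misses the field.
    """
    dr = math.sin(math.radians(angle_deg))
    dc = math.cos(math.radians(angle_deg))
    ts = []
    for d, p in ((dr, point[0]), (dc, point[1])):
        if abs(d) < 1e-12:
            if not (0 <= p <= size - 1):
                return None
            continue
        t0 = (0 - p) / d
        t1 = (size - 1 - p) / d
        ts.append(tuple(sorted((t0, t1))))
    t_min = max(t[0] for t in ts)
    t_max = min(t[1] for t in ts)
    if t_min >= t_max:
        return None
    p0 = (point[0] + t_min * dr, point[1] + t_min * dc)
    p1 = (point[0] + t_max * dr, point[1] + t_max * dc)
    return p0, p1


def _segment_intersection(a0, a1, b0, b1):
    """Intersection point of two segments, or None."""
    d1r, d1c = a1[0] - a0[0], a1[1] - a0[1]
    d2r, d2c = b1[0] - b0[0], b1[1] - b0[1]
    den = d1r * d2c - d1c * d2r
    if abs(den) < 1e-12:
        return None
    s = ((b0[0] - a0[0]) * d2c - (b0[1] - a0[1]) * d2r) / den
    u = ((b0[0] - a0[0]) * d1c - (b0[1] - a0[1]) * d1r) / den
    if 0 <= s <= 1 and 0 <= u <= 1:
        return (a0[0] + s * d1r, a0[1] + s * d1c)
    return None


def _segment_row_crossing(p0, p1, row):
    """Column where segment p0-p1 crosses a given row, or None."""
    r0, r1 = p0[0], p1[0]
    if (r0 - row) * (r1 - row) > 0 or r0 == r1:
        return None
    t = (row - r0) / (r1 - r0)
    return p0[1] + t * (p1[1] - p0[1])


def _sample_diameter(rng, dist) -> float:
    kind = dist[0]
    for _ in range(1000):
        if kind == "normal":
            d = rng.normal(dist[1], dist[2])
        elif kind == "uniform":
            d = rng.uniform(dist[1], dist[2])
        elif kind == "bimodal":
            w, m1, s1, m2, s2 = dist[1:]
            if rng.random() < w:
                d = rng.normal(m1, s1)
            else:
                d = rng.normal(m2, s2)
        else:
            raise ParameterError(f"unknown diameter distribution {kind!r}")
        if 250.0 < d < 1450.0:
            return float(d)
    raise ParameterError("diameter distribution yields no value in (250, 1450) nm")


def _star_polygon(rng, centre, r_outer_px, r_inner_px, n_spikes=8):
    """Vertex arrays (rows, cols) of a spiky star polygon (low solidity)."""
    angles = np.linspace(0, 2 * math.pi, 2 * n_spikes, endpoint=False)
    angles = angles + rng.uniform(0, 2 * math.pi)
    radii = np.where(
        np.arange(2 * n_spikes) % 2 == 0,
        r_outer_px * rng.uniform(0.85, 1.15, 2 * n_spikes),
        r_inner_px * rng.uniform(0.85, 1.15, 2 * n_spikes),
    )
    return centre[0] + radii * np.sin(angles), centre[1] + radii * np.cos(angles)


def render_scene(spec: SceneSpec) -> tuple[ClotImage, GroundTruth]:
    """Render one synthetic clot field and its ground truth.

    Overlapping objects sum their intensities (fluorophore additivity), so
    a crossing of two equal fibers shows a ~100% local increase.  The final
    image is clipped to 0-255 au; the recorded footprint fraction is the
    noise-free area at or above the 27 au binarization cut.
    """
    from skimage.draw import polygon as draw_polygon

    rng = np.random.default_rng(spec.seed)
    size = spec.size_px
    if size < 64:
        raise ParameterError("field too small to render (needs >= 64 px)")
    canvas = np.zeros((size, size), dtype=float)
    truth = GroundTruth()
    rows = standard_rows(size)
    truth.line_crossings = {r: [] for r in rows}

    # ---- network fibers: stratified-orientation chords -------------------
    span = 180.0 - 2.0 * spec.min_angle_deg
    # per row: list of (col, along-line halfwidth px) of existing crossings
    crossing_cols: dict[int, list[tuple[float, float]]] = {r: [] for r in rows}
    for i in range(spec.n_fibers):
        stratum = spec.min_angle_deg + span * (i + rng.random()) / max(1, spec.n_fibers)
        d = _sample_diameter(rng, spec.diameter_dist)
        placed = False
        for _attempt in range(4000):
            point = (rng.uniform(0, size - 1), rng.uniform(0, size - 1))
            angle = stratum
            if _attempt >= 2000:
                # crowded field: give up on the stratum, try any angle
                angle = spec.min_angle_deg + span * rng.random()
            chord = _chord_through(point, angle, size)
            if chord is None:
                continue
            p0, p1 = chord
            # network fibers span the field: prefer long chords over short
            # corner cuts (relaxed only if the field gets crowded)
            min_len = 0.7 * size if _attempt < 1000 else 0.3 * size
            if math.hypot(p1[0] - p0[0], p1[1] - p0[1]) < min_len:
                continue
            # a shallow fiber's footprint along a row is FWHM / sin(angle):
            # neighbouring crossings must clear each other's footprints
            halfwidth = (
                d / spec.pixel_size_nm / max(math.sin(math.radians(angle)), 0.1)
            )
            cols = {r: _segment_row_crossing(p0, p1, r) for r in rows}
            ok = True
            for r, c in cols.items():
                if c is None:
                    continue
                # keep crossings resolvable: clear of borders and neighbours
                if not (20 <= c <= size - 21):
                    ok = False
                    break
                pad = 8 if _attempt < 3000 else 4
                if any(
                    abs(c - c0) < max(spec.min_line_separation_px,
                                      0.5 * (halfwidth + w0) + pad)
                    for c0, w0 in crossing_cols[r]
                ):
                    ok = False
                    break
            if ok:
                # a fiber-fiber intersection next to a test line bridges two
                # peaks into one; keep intersections off the line rows
                for other in truth.fibers:
                    x = _segment_intersection(p0, p1, other.p0, other.p1)
                    if x is not None and any(abs(x[0] - r) < 12 for r in rows):
                        ok = False
                        break
            if not ok:
                continue
            peak = spec.intensity_per_nm * d
            sigma_px = d * FWHM_TO_SIGMA / spec.pixel_size_nm
            _render_segment(canvas, p0, p1, sigma_px, peak)
            fid = len(truth.fibers) + 1
            truth.fibers.append(
                FiberTruth(fid, p0, p1, d, peak, angle)
            )
            for r, c in cols.items():
                if c is not None:
                    crossing_cols[r].append((c, halfwidth))
                    truth.line_crossings[r].append((c, fid))
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place fiber {i + 1}/{spec.n_fibers} with the "
                "required test-line separation"
            )

    # ---- structure placement helper: clear of test lines and margins ----
    margin = 60
    occupied: list[tuple[float, float]] = []

    def _free_centre(min_dist=90.0, tries=400):
        for _ in range(tries):
            r = rng.uniform(margin, size - 1 - margin)
            c = rng.uniform(margin, size - 1 - margin)
            if any(abs(r - lr) < spec.line_clearance_px for lr in rows):
                continue
            if any(math.hypot(r - orr, c - occ) < min_dist for orr, occ in occupied):
                continue
            occupied.append((r, c))
            return r, c
        raise PackingError("no room left for a structure centre")

    arm_px = 2500.0 / spec.pixel_size_nm  # 2.5 um structure arms
    # two structures' arms must not touch, or event labels are corrupted
    structure_spacing = 2 * arm_px + 30

    # ---- trifunctional branch junctions (F1 = F2 + F3 exactly) ----------
    for _ in range(spec.n_branches):
        r, c = _free_centre(min_dist=structure_spacing)
        phi = rng.uniform(0, 2 * math.pi)
        d2 = rng.uniform(350.0, 550.0)
        d3 = rng.uniform(350.0, 550.0)
        d1 = d2 + d3
        dirs = [phi, phi + math.pi - 0.55, phi + math.pi + 0.55]
        widths = (d1, d2, d3)
        for ang, d in zip(dirs, widths):
            p1 = (r + arm_px * math.sin(ang), c + arm_px * math.cos(ang))
            sigma_px = d * FWHM_TO_SIGMA / spec.pixel_size_nm
            _render_segment(canvas, (r, c), p1, sigma_px, spec.intensity_per_nm * d)
        truth.branches.append(BranchTruth((r, c), widths, tuple(dirs)))

    # ---- crossing fibers (two segments through one point, additive) -----
    for k in range(spec.n_crossings):
        r, c = _free_centre(min_dist=structure_spacing)
        a1 = rng.uniform(0, math.pi)
        a2 = a1 + rng.uniform(math.radians(40), math.radians(140))
        segs = []
        ds = []
        pks = []
        for ang in (a1, a2):
            d = _sample_diameter(rng, spec.diameter_dist)
            peak = spec.intensity_per_nm * d
            p0 = (r - arm_px * math.sin(ang), c - arm_px * math.cos(ang))
            p1 = (r + arm_px * math.sin(ang), c + arm_px * math.cos(ang))
            sigma_px = d * FWHM_TO_SIGMA / spec.pixel_size_nm
            _render_segment(canvas, p0, p1, sigma_px, peak)
            segs.append((p0, p1))
            ds.append(d)
            pks.append(peak)
        base_id = 10000 + 2 * k
        truth.crossings.append(
            CrossingTruth(
                (r, c), (base_id, base_id + 1), tuple(segs), tuple(ds), tuple(pks)
            )
        )

    def _point_to_chord_px(point, fiber: FiberTruth) -> float:
        p0, p1 = np.array(fiber.p0), np.array(fiber.p1)
        v = p1 - p0
        t = float(np.clip(np.dot(np.array(point) - p0, v) / np.dot(v, v), 0, 1))
        return float(np.hypot(*(np.array(point) - (p0 + t * v))))

    # ---- fibrin clusters: spiky bright core + thin radiating fibers -----
    for _ in range(spec.n_clusters):
        # keep the core clear of network fiber paths so the bright core
        # stays a single compact component
        for _try in range(200):
            r, c = _free_centre(min_dist=140.0)
            if all(_point_to_chord_px((r, c), f) > 55.0 for f in truth.fibers):
                break
            occupied.pop()
        else:
            raise PackingError("no fiber-free room for a cluster core")
        r_core = 1000.0 / spec.pixel_size_nm  # ~1 um core radius
        pr, pc = _star_polygon(rng, (r, c), 1.35 * r_core, 0.6 * r_core)
        rr_poly, cc_poly = draw_polygon(pr, pc, shape=canvas.shape)
        canvas[rr_poly, cc_poly] += 235.0
        k = int(rng.integers(10, 14))
        d_thin = rng.uniform(400.0, 500.0)
        length = 2200.0 / spec.pixel_size_nm
        ang0 = rng.uniform(0, 2 * math.pi)
        for j in range(k):
            ang = ang0 + 2 * math.pi * j / k + rng.uniform(-0.08, 0.08)
            p0 = (r + 0.5 * r_core * math.sin(ang), c + 0.5 * r_core * math.cos(ang))
            p1 = (r + (r_core + length) * math.sin(ang), c + (r_core + length) * math.cos(ang))
            sigma_px = d_thin * FWHM_TO_SIGMA / spec.pixel_size_nm
            _render_segment(canvas, p0, p1, sigma_px, spec.intensity_per_nm * d_thin)
        truth.clusters.append(ClusterTruth((r, c), r_core, k, d_thin))

    # ---- agglomerates: isolated ellipse blobs ----------------------------
    for _ in range(spec.n_agglomerates):
        r, c = _free_centre(min_dist=0.0)  # may sit on test lines; isolated anyway
        occupied.pop()  # agglomerates manage their own spacing below
        long_um = float(np.exp(rng.normal(0.8052, 0.670)))
        long_um = min(max(long_um, 0.5), 8.0)
        aspect = float(rng.uniform(1.05, 2.5))
        a = long_um * 1000.0 / spec.pixel_size_nm / 2.0
        b = a / aspect
        # rejection: keep blobs separated so components stay isolated
        placed = False
        for _try in range(400):
            r = rng.uniform(margin, size - 1 - margin)
            c = rng.uniform(margin, size - 1 - margin)
            if all(
                math.hypot(r - t.centroid[0], c - t.centroid[1])
                > (a + t.long_axis_um * 1000 / spec.pixel_size_nm / 2 + 8)
                for t in truth.agglomerates
            ):
                placed = True
                break
        if not placed:
            raise PackingError("could not place agglomerate without contact")
        theta = rng.uniform(0, math.pi)
        rr_grid, cc_grid = np.meshgrid(
            np.arange(max(0, int(r - a - 3)), min(size, int(r + a + 4))),
            np.arange(max(0, int(c - a - 3)), min(size, int(c + a + 4))),
            indexing="ij",
        )
        u = (rr_grid - r) * math.cos(theta) + (cc_grid - c) * math.sin(theta)
        v = -(rr_grid - r) * math.sin(theta) + (cc_grid - c) * math.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        canvas[rr_grid[inside], cc_grid[inside]] += float(rng.uniform(140, 220))
        truth.agglomerates.append(AgglomerateTruth((r, c), long_um, aspect))

    truth.footprint_fraction = float((np.clip(canvas, 0, 255) >= 27.0).mean())
    if spec.noise_sd_au > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd_au, canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)
    img = ClotImage(canvas, pixel_size_nm=spec.pixel_size_nm, label=spec.label)
    return img, truth


def render_stack(
    spec: SceneSpec, n_slices: int = 3, z_start_um: float = 40.0,
    slice_spacing_um: float = 10.0,
) -> tuple[ClotStack, list[GroundTruth]]:
    """Render a z-stack of independently placed fiber fields.

    Slices share the spec; per-slice footprint fractions feed the
    void-volume oracles.
    """
    if n_slices < 2:
        raise ParameterError("a stack needs >= 2 slices")
    slices = []
    truths = []
    for k in range(n_slices):
        sub = replace(spec, seed=spec.seed * 1000 + k)
        img, truth = render_scene(sub)
        img.z_position_um = z_start_um + k * slice_spacing_um
        slices.append(img)
        truths.append(truth)
    return ClotStack(slices, slice_spacing_um=slice_spacing_um), truths


# --------------------------------------------------------------------------
# Default virtual dose series
#
# Fiber count falls monotonically while the mean diameter rises to an
# interior maximum at the 1 mM dose and then falls; diameters are calibrated
# so the binarized footprint (hence void) stays roughly constant until
# cluster onset at 2.5 mM; at the final dose no network forms and only
# agglomerates remain.
DEFAULT_DOSE_TREND: list[tuple[str, dict]] = [
    ("0 mM", dict(n_fibers=24, diameter_dist=("normal", 670.0, 45.0),
                  n_branches=7, n_crossings=9)),
    ("0.01 mM", dict(n_fibers=22, diameter_dist=("normal", 705.0, 45.0),
                     n_branches=6, n_crossings=8)),
    ("0.1 mM", dict(n_fibers=20, diameter_dist=("normal", 760.0, 45.0),
                    n_branches=6, n_crossings=7)),
    ("1 mM", dict(n_fibers=18, diameter_dist=("normal", 850.0, 45.0),
                  n_branches=5, n_crossings=5)),
    ("1.75 mM", dict(n_fibers=16, diameter_dist=("normal", 845.0, 45.0),
                     n_branches=4, n_crossings=4)),
    ("2.5 mM", dict(n_fibers=11, diameter_dist=("normal", 735.0, 45.0),
                    n_branches=2, n_crossings=2, n_clusters=3)),
    ("3.75 mM", dict(n_fibers=0, n_branches=0, n_crossings=0,
                     n_agglomerates=40)),
]


def render_dose_series(
    seed: int = 0,
    trend: Sequence[tuple[str, dict]] | None = None,
    base_spec: SceneSpec | None = None,
) -> list[tuple[ClotImage, GroundTruth, SceneSpec]]:
    """Render the virtual dose-response series (one scene per dose)."""
    trend = list(trend) if trend is not None else DEFAULT_DOSE_TREND
    if not trend:
        raise ParameterError("empty dose list")
    base = base_spec or SceneSpec()
    out = []
    for k, (dose_label, overrides) in enumerate(trend):
        spec = replace(base, seed=seed * 100 + k, label=dose_label, **overrides)
        img, truth = render_scene(spec)
        out.append((img, truth, spec))
    return out
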