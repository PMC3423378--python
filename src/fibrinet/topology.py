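"""Branch-junction vs crossing-fiber classification and topology rates.

Two fibers meeting at a point in a 2D projection can be a true
trifunctional branch junction, a physical fiber-fiber contact, or simply
one fiber passing above or below the other.  The discriminating rules:

* **Branch junction** -- exactly three fiber segments meet and the width of
  the widest approximately equals the sum of the other two (F1 = F2 + F3,
  width conservation from protofibril bookkeeping).
* **Crossing contact** -- both fibers show a proportional fluorescence
  increase > 40% at the meeting point relative to their own baselines
  (fluorophore additivity: two fibers in contact sum their signals).
  If only one fiber brightens, it is a pass-over, not a contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .detect import Fiber
from .errors import DegenerateImageError, ParameterError
from .image import ClotImage
from .metrics import estimate_orientation

DEFAULT_WIDTH_TOLERANCE = 0.15
DEFAULT_REL_INCREASE = 0.40
DEFAULT_BASELINE_EXCLUSION_PX = 7
DEFAULT_PAIR_DISTANCE_PX = 3.0


@dataclass
class BranchJunction:
    position: tuple[float, float]
    widths_nm: tuple[float, float, float]  # F1 widest

    @property
    def residual(self) -> float:
        f1, f2, f3 = self.widths_nm
        return abs(f1 - (f2 + f3)) / f1


@dataclass
class CrossingContact:
    position: tuple[float, float]
    fibers: tuple[int, int]
    rel_increase: tuple[float, float]
    kind: str  # "contact" | "pass_over"


def classify_branch(
    widths_nm: Sequence[float], tolerance: float = DEFAULT_WIDTH_TOLERANCE
) -> str:
    """Width-conservation test for a trifunctional junction.

    ``branch`` iff |max - (sum of the other two)| / max <= tolerance.
    Permutation-invariant in its three arguments.
    """
    if len(widths_nm) != 3:
        raise ParameterError("exactly three widths required")
    w = sorted(float(v) for v in widths_nm)
    if w[0] <= 0:
        raise ParameterError("widths must be positive")
    residual = abs(w[2] - (w[0] + w[1])) / w[2]
    return "branch" if residual <= tolerance else "not_branch"


def classify_crossing(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    meeting_index: int,
    threshold: float = DEFAULT_REL_INCREASE,
    exclusion_px: int = DEFAULT_BASELINE_EXCLUSION_PX,
    position: tuple[float, float] = (0.0, 0.0),
    fiber_ids: tuple[int, int] = (0, 1),
) -> CrossingContact:
    """Apply the proportional-intensity rule to two along-fiber profiles.

    Each fiber's baseline is the median of its profile excluding a
    ``exclusion_px``-wide window around the meeting point; the relative
    increase is (meeting - baseline) / baseline.  Contact requires a strict
    > ``threshold`` increase on *both* fibers (the rule is proportional, so
    it is invariant to rescaling either profile).
    """
    increases = []
    half = exclusion_px // 2
    for prof in (profile_a, profile_b):
        prof = np.asarray(prof, dtype=float)
        if not (0 <= meeting_index < prof.size):
            raise ParameterError("meeting index outside profile")
        keep = np.ones(prof.size, dtype=bool)
        keep[max(0, meeting_index - half) : meeting_index + half + 1] = False
        if keep.sum() < 10:
            raise ParameterError("need >= 10 px of off-meeting baseline")
        baseline = float(np.median(prof[keep]))
        if baseline <= 0:
            raise DegenerateImageError("non-positive baseline intensity")
        lo = max(0, meeting_index - 1)
        meeting = float(prof[lo : meeting_index + 2].max())
        increases.append((meeting - baseline) / baseline)
    da, db = increases
    kind = "contact" if (da > threshold and db > threshold) else "pass_over"
    return CrossingContact(
        position=position, fibers=fiber_ids, rel_increase=(da, db), kind=kind
    )


def trace_ridge(
    img: ClotImage,
    start: tuple[float, float],
    stop_au: float = 27.0,
    max_steps: int = 200,
    recenter_px: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Follow a fiber ridge from a starting point in both directions.

    Steps 1 px along the locally estimated fiber axis, re-centring on the
    perpendicular intensity maximum within ``recenter_px`` at each step, and
    stops when intensity drops below ``stop_au``, the path leaves the image,
    or ``max_steps`` is reached per direction.  Returns ``(positions,
    intensities)`` ordered along the fiber with the start point included.
    """

    def walk(sign: float) -> list[tuple[float, float, float]]:
        out = []
        pos = np.array(start, dtype=float)
        prev_dir = None
        for _ in range(max_steps):
            r, c = pos
            if not (1 <= r < img.height_px - 1 and 1 <= c < img.width_px - 1):
                break
            theta = estimate_orientation(img, (int(round(r)), int(round(c))))
            d = np.array([math.sin(theta), math.cos(theta)])
            if prev_dir is not None and float(np.dot(d, prev_dir)) < 0:
                d = -d
            elif prev_dir is None:
                d = sign * d
            pos = pos + d
            prev_dir = d
            # re-centre perpendicular to the step direction
            n = np.array([d[1], -d[0]])
            offs = np.arange(-recenter_px, recenter_px + 1)
            rows = pos[0] + offs * n[0]
            cols = pos[1] + offs * n[1]
            vals = map_coordinates(img.pixels, [rows, cols], order=1, mode="nearest")
            k = int(np.argmax(vals))
            pos = pos + offs[k] * n
            val = float(
                map_coordinates(img.pixels, [[pos[0]], [pos[1]]], order=1, mode="nearest")[0]
            )
            if val < stop_au:
                break
            out.append((pos[0], pos[1], val))
        return out

    fwd = walk(+1.0)
    bwd = walk(-1.0)
    v0 = float(
        map_coordinates(img.pixels, [[start[0]], [start[1]]], order=1, mode="nearest")[0]
    )
    pts = [p for p in reversed(bwd)] + [(start[0], start[1], v0)] + fwd
    arr = np.array(pts, dtype=float).reshape(-1, 3)
    return arr[:, :2], arr[:, 2]


@dataclass
class Meeting:
    """A candidate fiber-fiber meeting emitted by the local-increase scan."""

    position: tuple[float, float]
    fiber_id: int
    partner_id: int | None
    rel_increase: float


def candidate_meetings(
    img: ClotImage,
    fibers: Sequence[Fiber],
    rel_threshold: float = DEFAULT_REL_INCREASE,
    pair_distance_px: float = DEFAULT_PAIR_DISTANCE_PX,
    **trace_kwargs,
) -> list[Meeting]:
    """Scan traced fibers for local intensity increases > threshold.

    Each fiber is traced from its test-line crossing; positions whose
    intensity exceeds the fiber's own baseline (trace median) by more than
    ``rel_threshold`` become candidates, paired with any other fiber whose
    trace passes within ``pair_distance_px``.  Unpaired candidates (e.g. a
    bright cluster core sitting on the fiber) are still emitted for
    downstream classification.
    """
    traces = {}
    for f in fibers:
        start = (float(f.line.row_index), float(f.peak_col_px))
        traces[f.id] = trace_ridge(img, start, **trace_kwargs)
    meetings: list[Meeting] = []
    for f in fibers:
        path, prof = traces[f.id]
        if len(prof) < 10:
            continue
        baseline = float(np.median(prof))
        if baseline <= 0:
            continue
        rel = (prof - baseline) / baseline
        hot = rel > rel_threshold
        # contiguous hot runs -> one candidate each, at the run maximum
        k = 0
        while k < len(hot):
            if not hot[k]:
                k += 1
                continue
            j = k
            while j < len(hot) and hot[j]:
                j += 1
            seg = slice(k, j)
            m = k + int(np.argmax(prof[seg]))
            pos = (float(path[m, 0]), float(path[m, 1]))
            partner = None
            for g in fibers:
                if g.id == f.id:
                    continue
                other_path, _ = traces[g.id]
                if len(other_path) == 0:
                    continue
                d = np.hypot(other_path[:, 0] - pos[0], other_path[:, 1] - pos[1])
                if float(d.min()) <= pair_distance_px:
                    partner = g.id
                    break
            meetings.append(
                Meeting(
                    position=pos,
                    fiber_id=f.id,
                    partner_id=partner,
                    rel_increase=float(rel[m]),
                )
            )
            k = j
    return meetings


@dataclass
class TopologyStats:
    """Per-area and per-fiber junction/contact rates."""

    n_junctions: int
    n_contacts: int
    n_fibers: int
    field_area_um2: float

    @property
    def xbranch_per_area(self) -> float:
        return self.n_junctions  # per field by convention; see per_mm2

    @property
    def xfiber_per_area(self) -> float:
        return self.n_contacts

    @property
    def xbranch_per_mm2(self) -> float:
        return self.n_junctions / self.field_area_um2 * 1e6

    @property
    def xfiber_per_mm2(self) -> float:
        return self.n_contacts / self.field_area_um2 * 1e6

    @property
    def xbranch_per_fiber(self) -> float | None:
        return self.n_junctions / self.n_fibers if self.n_fibers else None

    @property
    def xfiber_per_fiber(self) -> float | None:
        return self.n_contacts / self.n_fibers if self.n_fibers else None

    @property
    def density_branch_ratio(self) -> float | None:
        """Fiber count over junction count (density/branch-point density)."""
        return self.n_fibers / self.n_junctions if self.n_junctions else None

    @property
    def density_crossing_ratio(self) -> float | None:
        return self.n_fibers / self.n_contacts if self.n_contacts else None


def topology_stats(
    junctions: Sequence[BranchJunction],
    contacts: Sequence[CrossingContact],
    fibers: Sequence[Fiber],
    field_area_um2: float,
) -> TopologyStats:
    if not field_area_um2 > 0:
        raise ParameterError("field area must be positive")
    n_contacts = sum(1 for c in contacts if c.kind == "contact")
    return TopologyStats(
        n_junctions=len(junctions),
        n_contacts=n_contacts,
        n_fibers=sum(1 for f in fibers if f.status != "rejected"),
        field_area_um2=field_area_um2,
    )
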