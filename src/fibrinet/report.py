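"""Per-clot read-out assembly, dose-series tables, and the full pipeline.

The read-out consolidates every measured parameter of one clot field --
fiber count, density (fibers/100 um), intensity, diameter, thin-to-thick
ratio, void area, branching and crossing rates, and cluster/agglomerate
densities -- with explicit nulls (plus reason codes) for analyses that do
not apply.  A dose-series table stacks read-outs across treatment doses and
supports percent changes against the control row and the density-diameter
regression with outlier flagging.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import detect as _detect
from . import metrics as _metrics
from . import voids as _voids
from .errors import DependencyError, ModeError, ParameterError
from .image import ClotImage, PreprocessConfig, binarize, preprocess


@dataclass
class ClotReadout:
    """Consolidated parameter report for one clot image."""

    label: str = ""
    n_fibers: int | None = None
    fiber_density_per_100um: float | None = None
    fiber_intensity_au: float | None = None
    fiber_intensity_cv: float | None = None
    diameter_nm: float | None = None
    diameter_cv: float | None = None
    diameter_fit_kind: str | None = None
    ttr: float | None = None
    ttr_vs_control: float | None = None
    void_area_percent: float | None = None
    xfibers_per_fiber: float | None = None
    xbranching_per_fiber: float | None = None
    clusters_per_mm2: float | None = None
    agglomerates_per_mm2: float | None = None
    null_reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _cv(values: np.ndarray) -> float | None:
    m = float(np.mean(values))
    if m == 0:
        return None
    return float(np.std(values) / m)


def build_readout(
    fibers: Sequence[_detect.Fiber] | None,
    lines: Sequence[_detect.TestLine] | None,
    field_area_um2: float,
    label: str = "",
    topology=None,
    void_percent: float | None = None,
    clusters=None,
    agglomerates=None,
    ttr_threshold_nm: float = _metrics.DEFAULT_THIN_THICK_NM,
    control_ttr: float | None = None,
) -> ClotReadout:
    """Assemble the read-out from module outputs.

    Detection is mandatory (``fibers`` may be an empty list but not None);
    topology, void and structure analyses are optional and reported as null
    with a reason when absent.
    """
    if fibers is None or lines is None:
        raise DependencyError("fiber detection results are required")
    r = ClotReadout(label=label)
    active = [f for f in fibers if f.status != "rejected"]
    r.n_fibers = len(active)
    r.fiber_density_per_100um = _detect.fiber_density(active, lines) if lines else None

    intensities = np.array(
        [f.local_max_intensity_au for f in active if f.local_max_intensity_au is not None]
    )
    if intensities.size:
        r.fiber_intensity_au = float(np.mean(intensities))
        r.fiber_intensity_cv = _cv(intensities)
    else:
        r.null_reasons["fiber_intensity_au"] = "no measured intensities"

    diameters = np.array([f.diameter_nm for f in active if f.diameter_nm is not None])
    if diameters.size >= 3 and np.ptp(diameters) > 0:
        try:
            dist = _metrics.fit_distribution(diameters)
            r.diameter_nm = dist.summary_nm
            r.diameter_fit_kind = dist.fit_kind
        except Exception:
            r.diameter_nm = float(np.mean(diameters))
            r.diameter_fit_kind = "normal"
        r.diameter_cv = _cv(diameters)
        ttr = _metrics.compute_ttr(diameters, ttr_threshold_nm)
        r.ttr = None if ttr.infinite else ttr.ttr
        if ttr.infinite:
            r.null_reasons["ttr"] = "no thick fibers"
        if control_ttr and r.ttr is not None:
            r.ttr_vs_control = r.ttr / control_ttr
    elif diameters.size:
        r.diameter_nm = float(np.mean(diameters))
        r.diameter_cv = _cv(diameters) if diameters.size > 1 else None
    else:
        r.null_reasons["diameter_nm"] = "no measured diameters"

    if topology is not None:
        r.xbranching_per_fiber = topology.xbranch_per_fiber
        r.xfibers_per_fiber = topology.xfiber_per_fiber
    else:
        r.null_reasons["topology"] = "topology analysis not run"
    if void_percent is not None:
        r.void_area_percent = void_percent
    else:
        r.null_reasons["void_area_percent"] = "void analysis not run"
    if clusters is not None:
        r.clusters_per_mm2 = len(clusters) / field_area_um2 * 1e6
    if agglomerates is not None:
        r.agglomerates_per_mm2 = len(agglomerates) / field_area_um2 * 1e6
    return r


def analyze_image(
    img: ClotImage,
    cfg: PreprocessConfig | None = None,
    label: str = "",
    control_ttr: float | None = None,
    run_clusters: bool = True,
) -> ClotReadout:
    """Run the standard per-image pipeline: preprocess, detect, measure,
    void, structures, read-out.

    If no spanning network is present the image is analyzed in agglomerate
    mode: fiber fields are null/zero and agglomerate morphometry runs
    instead.
    """
    cfg = cfg or PreprocessConfig()
    pre = preprocess(img, cfg)
    threshold = cfg.binarize_threshold_au
    if not _voids.has_spanning_network(pre, threshold):
        aggs = _voids.detect_agglomerates(pre, threshold)
        mask = binarize(pre, threshold)
        lines = _detect.make_test_lines(pre)
        r = ClotReadout(label=label)
        r.n_fibers = 0
        r.fiber_density_per_100um = 0.0
        r.void_area_percent = _voids.void_area(mask)
        r.agglomerates_per_mm2 = len(aggs) / pre.field_area_um2 * 1e6
        r.null_reasons["fibers"] = "no spanning network: agglomerate mode"
        return r
    fibers, lines = _detect.detect_fibers(pre, min_peak_au=threshold)
    _metrics.measure_fibers(pre, fibers)
    mask = binarize(pre, threshold)
    clusters = _voids.detect_clusters(pre) if run_clusters else None
    return build_readout(
        fibers,
        lines,
        pre.field_area_um2,
        label=label,
        void_percent=_voids.void_area(mask),
        clusters=clusters,
        agglomerates=[],
        control_ttr=control_ttr,
    )


def readouts_to_table(readouts: Sequence[ClotReadout]) -> pd.DataFrame:
    """Dose-series table: one row per read-out, keyed by label."""
    rows = []
    for r in readouts:
        d = r.to_dict()
        d.pop("null_reasons", None)
        rows.append(d)
    return pd.DataFrame(rows).set_index("label")


def density_diameter_regression(
    table: pd.DataFrame,
    density_col: str = "fiber_density_per_100um",
    diameter_col: str = "diameter_nm",
    flag_sd: float = 2.0,
):
    """Least-squares line of density on diameter with outlier flagging.

    Returns ``(slope, intercept, r, p, residuals)`` where ``residuals`` is a
    Series of standardized residuals; rows with |z| > ``flag_sd`` are the
    doses that fall off the expected density-diameter line (the abnormal-
    cluster signature).
    """
    sub = table[[diameter_col, density_col]].dropna()
    if len(sub) < 3:
        raise ParameterError("regression needs >= 3 rows with both fields")
    x = sub[diameter_col].to_numpy(dtype=float)
    y = sub[density_col].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    sd = float(np.std(resid, ddof=2)) if len(sub) > 2 else 0.0
    z = resid / sd if sd > 0 else np.zeros_like(resid)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
        pd.Series(z, index=sub.index, name="std_residual"),
    )


def percent_change_vs_control(table: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Signed percent change of every numeric column against the control row."""
    if control_label not in table.index:
        raise ParameterError(f"control row {control_label!r} missing")
    ctrl = table.loc[control_label]
    num = table.select_dtypes("number")
    return 100.0 * (num - ctrl[num.columns]) / ctrl[num.columns]
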