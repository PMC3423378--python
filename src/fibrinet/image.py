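"""Calibrated clot images, TIFF I/O and the uniform preprocessing chain.

Every multiphoton acquisition enters the pipeline through :class:`ClotImage`
(a 2D intensity raster in arbitrary units with a physical pixel size) or
:class:`ClotStack` (an ordered set of slices at known heights above the clot
surface).  All images receive the same preprocessing: a background estimate
is subtracted, intensities are rescaled to a fixed 0-255 au range, and a
single global threshold (default 27 au) turns the image into a fiber/void
binary mask.  Coordinates are row-major, 0-based; physical position is
``index * pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

from .errors import DegenerateImageError, FormatError, ParameterError

DEFAULT_PIXEL_SIZE_NM = 57.6
DEFAULT_BINARIZE_THRESHOLD_AU = 27.0
MIN_DIM_PX = 64


@dataclass
class ClotImage:
    """A calibrated 2D fluorescence image of a fibrin network.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities in arbitrary units (au); finite and >= 0.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres.
    z_position_um : float, optional
        Slice height above the clot surface, for stack members.
    label : str
        Free-text identifier (e.g. a GSNO dose).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_position_um: float | None = None
    label: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"expected a single-channel 2D raster, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape
        if h < MIN_DIM_PX or w < MIN_DIM_PX:
            raise FormatError(f"image {w}x{h} smaller than minimum {MIN_DIM_PX} px")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise FormatError("intensities must be finite and >= 0")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def field_area_um2(self) -> float:
        """Physical field area in square micrometres."""
        px_um = self.pixel_size_nm / 1000.0
        return self.height_px * self.width_px * px_um * px_um

    def with_pixels(self, pixels: np.ndarray) -> "ClotImage":
        return replace(self, pixels=pixels)


@dataclass
class ClotStack:
    """An ordered z-stack of :class:`ClotImage` slices with common geometry."""

    slices: list[ClotImage]
    slice_spacing_um: float = 10.0

    def __post_init__(self):
        if len(self.slices) < 2:
            raise ParameterError("a stack needs at least 2 slices")
        first = self.slices[0]
        for s in self.slices[1:]:
            if s.pixels.shape != first.pixels.shape:
                raise FormatError("stack slices must share dimensions")
            if s.pixel_size_nm != first.pixel_size_nm:
                raise FormatError("stack slices must share pixel size")
        zs = [s.z_position_um for s in self.slices]
        if any(z is None for z in zs) or not all(a < b for a, b in zip(zs, zs[1:])):
            raise FormatError("slice z positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class PreprocessConfig:
    """Settings for the uniform background/normalization/threshold chain.

    background_mode
        ``"constant"`` subtracts a single background level estimated as the
        modal intensity (fibrin images are mostly dark void);
        ``"rolling-percentile"`` subtracts a local low-percentile surface,
        for uneven illumination.
    normalize_to
        Target maximum intensity after rescaling (au); the default 255 keeps
        the 8-bit convention so the 27 au threshold is meaningful everywhere.
    binarize_threshold_au
        Global fiber/void cut applied by :func:`binarize`.
    """

    background_mode: Literal["constant", "rolling-percentile"] = "constant"
    normalize_to: float = 255.0
    binarize_threshold_au: float = DEFAULT_BINARIZE_THRESHOLD_AU
    rolling_window_px: int = 64
    rolling_percentile: float = 10.0

    def __post_init__(self):
        if not (0 < self.binarize_threshold_au < self.normalize_to):
            raise ParameterError(
                "binarize_threshold_au must lie in (0, normalize_to)"
            )


def load_image(
    path: str | Path,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    slice_spacing_um: float = 10.0,
    z_start_um: float = 0.0,
    label: str = "",
) -> ClotImage | ClotStack:
    """Read a single- or multi-page grayscale TIFF.

    A single page yields a :class:`ClotImage`; a multi-page file yields a
    :class:`ClotStack` with slices at ``z_start_um + k * slice_spacing_um``.
    RGB/multi-channel input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise FormatError(
            f"expected single-channel input, got {data.shape[-1]} channels (RGB?)"
        )
    if data.ndim == 2:
        return ClotImage(data, pixel_size_nm=pixel_size_nm, label=label)
    if data.ndim == 3:
        slices = [
            ClotImage(
                page,
                pixel_size_nm=pixel_size_nm,
                z_position_um=z_start_um + k * slice_spacing_um,
                label=label,
            )
            for k, page in enumerate(data)
        ]
        return ClotStack(slices, slice_spacing_um=slice_spacing_um)
    raise FormatError(f"cannot interpret TIFF with shape {data.shape}")


def save_image(img: ClotImage | np.ndarray, path: str | Path) -> None:
    """Write an image (or a boolean mask, as 0/255) to an 8-bit TIFF."""
    arr = img.pixels if isinstance(img, ClotImage) else np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(Path(path)), arr)


def save_stack(stack: ClotStack, path: str | Path) -> None:
    pages = np.stack(
        [np.clip(np.round(s.pixels), 0, 255).astype(np.uint8) for s in stack.slices]
    )
    tifffile.imwrite(str(Path(path)), pages, photometric="minisblack")


def _modal_background(pixels: np.ndarray) -> float:
    # Histogram mode of the rounded intensities; robust because void
    # dominates fibrin fields.
    vals = np.round(pixels).astype(int).ravel()
    counts = np.bincount(vals - vals.min())
    return float(np.argmax(counts) + vals.min())


def preprocess(img: ClotImage, cfg: PreprocessConfig | None = None) -> ClotImage:
    """Background-subtract and normalize an image.

    The background estimate is subtracted (clipped at 0) and the result is
    rescaled so its maximum equals ``cfg.normalize_to``.  Deterministic for a
    fixed configuration; dimensions never change.
    """
    cfg = cfg or PreprocessConfig()
    px = img.pixels
    if cfg.background_mode == "constant":
        bg = _modal_background(px)
        out = np.clip(px - bg, 0.0, None)
    elif cfg.background_mode == "rolling-percentile":
        from scipy.ndimage import percentile_filter

        surface = percentile_filter(
            px, cfg.rolling_percentile, size=cfg.rolling_window_px
        )
        out = np.clip(px - surface, 0.0, None)
    else:  # pragma: no cover - guarded by the Literal type
        raise ParameterError(f"unknown background_mode {cfg.background_mode!r}")
    peak = out.max()
    if peak <= 0:
        raise DegenerateImageError("image is empty after background subtraction")
    out = out * (cfg.normalize_to / peak)
    return img.with_pixels(out)


def binarize(
    img: ClotImage | np.ndarray,
    threshold_au: float = DEFAULT_BINARIZE_THRESHOLD_AU,
) -> np.ndarray:
    """Threshold an image into a fiber (True/white) vs void (False/black) mask.

    The comparison is inclusive: a pixel exactly at the threshold is fiber.
    """
    px = img.pixels if isinstance(img, ClotImage) else np.asarray(img, dtype=float)
    return px >= threshold_au


def binarize_stack(
    stack: ClotStack, threshold_au: float = DEFAULT_BINARIZE_THRESHOLD_AU
) -> list[np.ndarray]:
    return [binarize(s, threshold_au) for s in stack.slices]
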