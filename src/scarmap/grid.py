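"""Raster grid model, calendar-month arithmetic, and GeoTIFF I/O.

The whole chain works on a single fixed grid (no reprojection or
resampling between CRSs): row/col indexing, 0-based, origin at the
top-left corner, pixel centres at ``(x0 + (c+0.5)*px, y0 - (r+0.5)*px)``.
Nodata never enters a computation as a sentinel value; it is carried as
an explicit boolean validity mask alongside every grid.

GeoTIFFs are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) so that any GIS can open
them; reading parses the same tags back.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

# Sentinel-2 bands used by the chain. The 60-m bands B1, B9, B10 are
# excluded throughout (too coarse for 20-m burn-scar mapping).
BAND_SET = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridAlignmentError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the processing grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions, each >= 1.
    pixel_size : float
        Pixel edge length in metres (20 m for the Sentinel-2 chain).
    origin : tuple of float
        Map coordinates (x, y) of the top-left corner.
    crs_label : str
        Opaque CRS identifier carried through to file metadata.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 20.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centres(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of pixel centres for row/col index arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(cols) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(rows) + 0.5) * self.pixel_size
        return x, y

    def contains_point(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        return (
            x0 <= x <= x0 + self.n_cols * self.pixel_size
            and y0 - self.n_rows * self.pixel_size <= y <= y0
        )

    def point_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the pixels containing map points (may fall outside)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col


def pixel_area_ha(grid: GridSpec) -> float:
    """Area of one pixel in hectares: ``pixel_size**2 / 10_000`` (0.04 ha at 20 m)."""
    return grid.pixel_size**2 / 10_000.0


def mmu_pixels(min_patch_ha: float, grid: GridSpec) -> int:
    """Minimum-mapping-unit patch size in pixels: floor(area / pixel area).

    6.25 ha on a 20-m grid gives 156 pixels, the Indonesian official
    minimum burn-scar size expressed in classification pixels.
    """
    return int(np.floor(min_patch_ha / pixel_area_ha(grid)))


@functools.total_ordering
@dataclass(frozen=True)
class MonthKey:
    """A calendar month (the chain's unit of time).

    The month being processed is the *reference month*; all compositing
    and filtering windows are whole calendar months anchored to it.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    @property
    def ordinal(self) -> int:
        """Months since year 0; supports distance arithmetic across years."""
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_ordinal(cls, n: int) -> "MonthKey":
        return cls(n // 12, n % 12 + 1)

    @classmethod
    def parse(cls, text: str) -> "MonthKey":
        """Parse ``YYYY-MM``."""
        y, m = text.split("-")
        return cls(int(y), int(m))

    def shift(self, months: int) -> "MonthKey":
        return MonthKey.from_ordinal(self.ordinal + months)

    def __lt__(self, other: "MonthKey") -> bool:
        return self.ordinal < other.ordinal

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_window(ref: MonthKey, offset_back: int, length: int) -> list[MonthKey]:
    """``length`` consecutive months ending ``offset_back`` months before ``ref``.

    ``offset_back=0`` means the window ends at the reference month itself.
    The pre-fire compositing window is ``month_window(ref, 1, 3)`` (e.g.
    June–August for a September reference month); the hotspot window under
    the 4-month reading is ``month_window(ref, 0, 4)``.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    end = ref.shift(-offset_back)
    return [end.shift(-(length - 1 - i)) for i in range(length)]


@dataclass
class Observation:
    """One acquisition date: per-band reflectance plus a validity mask."""

    date: str  # ISO YYYY-MM-DD
    bands: dict[str, np.ndarray]  # band name -> (rows, cols) reflectance
    valid: np.ndarray  # bool (rows, cols); False = cloud/shadow/nodata

    @property
    def month(self) -> MonthKey:
        y, m = self.date.split("-")[:2]
        return MonthKey(int(y), int(m))


@dataclass
class SceneStack:
    """Time-indexed multiband reflectance grids sharing one GridSpec."""

    grid: GridSpec
    observations: list[Observation]
    band_set: tuple[str, ...] = BAND_SET

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.valid.shape != self.grid.shape:
                raise GridAlignmentError(
                    f"observation {obs.date} mask shape {obs.valid.shape} "
                    f"!= grid {self.grid.shape}"
                )
            missing = set(self.band_set) - set(obs.bands)
            if missing:
                raise ValueError(f"observation {obs.date} missing bands {sorted(missing)}")

    def in_months(self, months: list[MonthKey]) -> list[Observation]:
        wanted = {m.ordinal for m in months}
        return [o for o in self.observations if o.month.ordinal in wanted]


@dataclass
class ZoneMask:
    """Per-pixel boolean membership mask (e.g. primary forest, peatland)."""

    grid: GridSpec
    member: np.ndarray

    def __post_init__(self) -> None:
        if self.member.shape != self.grid.shape:
            raise GridAlignmentError(
                f"zone mask shape {self.member.shape} != grid {self.grid.shape}"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(
    path: str | Path,
    data: np.ndarray,
    grid: GridSpec,
    nodata: float | int | None = None,
) -> None:
    """Write a single- or multi-band grid as a georeferenced GeoTIFF.

    ``data`` is (rows, cols) or (bands, rows, cols). Georeferencing is
    stored in the standard GeoTIFF tags; ``nodata`` in GDAL's tag so that
    ``read_raster`` (and any GIS) recovers the validity mask.
    """
    data = np.asarray(data)
    spatial = data.shape[-2:]
    if spatial != grid.shape:
        raise GridAlignmentError(f"data shape {spatial} != grid {grid.shape}")
    x0, y0 = grid.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if nodata is not None:
        nodata_ascii = repr(nodata).encode() + b"\x00"
        extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii))
    description = json.dumps({"crs_label": grid.crs_label})
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        extratags=extratags,
        description=description,
        metadata=None,
    )


def read_raster(
    path: str | Path, expected_grid: GridSpec | None = None
) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible).

    Returns ``(data, valid, grid)`` where ``valid`` is False exactly where
    the file's declared nodata value occurs (broadcast over bands).
    Raises :class:`GridAlignmentError` if the file's grid disagrees with
    ``expected_grid`` in shape, pixel size or origin.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        tags = page.tags
        pixel_size = 1.0
        origin = (0.0, 0.0)
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            pixel_size = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            if isinstance(raw, bytes):
                raw = raw.decode()
            nodata = float(raw.strip("\x00 "))
        crs_label = "local"
        desc = page.description
        if desc:
            try:
                crs_label = json.loads(desc).get("crs_label", "local")
            except (json.JSONDecodeError, AttributeError):
                pass
    n_rows, n_cols = data.shape[-2:]
    grid = GridSpec(n_rows, n_cols, pixel_size, origin, crs_label)
    if expected_grid is not None:
        same = (
            grid.shape == expected_grid.shape
            and grid.pixel_size == expected_grid.pixel_size
            and grid.origin == expected_grid.origin
        )
        if not same:
            raise GridAlignmentError(
                f"raster grid {grid} does not align with expected {expected_grid}"
            )
    if nodata is None:
        valid = np.ones(data.shape, dtype=bool)
    elif np.issubdtype(data.dtype, np.floating) and np.isnan(nodata):
        valid = ~np.isnan(data)
    else:
        valid = data != np.asarray(nodata).astype(data.dtype)
    return data, valid, grid


def grids_equal(a: GridSpec, b: GridSpec) -> bool:
    return a.shape == b.shape and a.pixel_size == b.pixel_size and a.origin == b.origin


def require_same_grid(a: GridSpec, b: GridSpec, context: str = "") -> None:
    if not grids_equal(a, b):
        raise GridAlignmentError(f"{context}: grids differ ({a} vs {b})")


def as_dict(spec: GridSpec) -> dict:
    return dataclasses.asdict(spec)
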