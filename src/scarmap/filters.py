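"""The four post-classification filters applied to each raw monthly map.

Applied in fixed order to the random-forest output for a reference month:

a) **Minimum mapping unit** — connected burned patches smaller than
   6.25 ha (156 pixels at 20 m, the Indonesian official minimum
   burn-scar size) are removed, including isolated pixels.
b) **Morphological refinement** — opening with a 3x3 square structuring
   element (removes pixel noise and weak connections) then closing with
   a 3x3 "circular" element, interpreted as the cross/plus element, the
   only 3x3 element distinguishable from the square (fills small gaps).
   An NBR floor follows: a pixel whose post-fire NBR is greater than
   -0.1 is kept unburned — still-vegetated land is unlikely to have
   burned.
c) **Hotspot masking** — each surviving burned patch is buffered by
   100 m; the whole patch is reclassified unburned unless at least one
   FIRMS-style active-fire hotspot dated within the hotspot window
   (default: the three months before the reference month plus the
   reference month) falls inside the patch or its buffer. Only scars
   with evidence of active fire survive.
d) **Repeat masking** — a pixel already detected as newly burned in any
   of the previous three months is flagged ``burned_repeat`` instead of
   ``burned_new``, so a scar that stays visible for months is counted
   once.

Patch connectivity is 8-connected by default (burn scars are
diagonal-contiguous in practice), configurable to 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridSpec, MonthKey, month_window

# BurnMap pixel codes
UNBURNED = 0
BURNED_NEW = 1
BURNED_REPEAT = 2
UNOBSERVED = 255

SQUARE_3x3 = np.ones((3, 3), dtype=bool)
# "circular" at 3x3: the cross/plus element
CROSS_3x3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return SQUARE_3x3
    if connectivity == 4:
        return CROSS_3x3
    raise ValueError("connectivity must be 4 or 8")


@dataclass
class BurnMap:
    """Final per-month classification: {unburned, burned_new,
    burned_repeat, unobserved} per pixel."""

    grid: GridSpec
    codes: np.ndarray  # uint8 of the module-level codes
    month: MonthKey

    def burned_new_mask(self) -> np.ndarray:
        return self.codes == BURNED_NEW

    def burned_any_mask(self) -> np.ndarray:
        return (self.codes == BURNED_NEW) | (self.codes == BURNED_REPEAT)

    def unobserved_mask(self) -> np.ndarray:
        return self.codes == UNOBSERVED


class BurnHistory:
    """Per-pixel memory of the months a pixel was detected burned_new.

    Backed by one boolean grid per month; per-pixel month lists are
    derived on demand. The history persists across calendar years, so
    lookback windows cross year boundaries transparently.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self._layers: dict[int, np.ndarray] = {}  # month ordinal -> bool grid

    def add(self, month: MonthKey, burned_new: np.ndarray) -> None:
        if burned_new.shape != self.shape:
            raise ValueError("history layer shape mismatch")
        if month.ordinal in self._layers:
            raise ValueError(f"history already holds {month}")
        self._layers[month.ordinal] = burned_new.astype(bool).copy()

    def recent_mask(self, ref: MonthKey, lookback: int) -> np.ndarray:
        """Pixels burned_new in the ``lookback`` months strictly before ref."""
        out = np.zeros(self.shape, dtype=bool)
        for k in range(1, lookback + 1):
            layer = self._layers.get(ref.shift(-k).ordinal)
            if layer is not None:
                out |= layer
        return out

    def months_at(self, row: int, col: int) -> list[MonthKey]:
        return [
            MonthKey.from_ordinal(o)
            for o in sorted(self._layers)
            if self._layers[o][row, col]
        ]

    def months(self) -> list[MonthKey]:
        return [MonthKey.from_ordinal(o) for o in sorted(self._layers)]

    def layer(self, month: MonthKey) -> np.ndarray | None:
        return self._layers.get(month.ordinal)


# ---------------------------------------------------------------------------
# (a) minimum mapping unit
# ---------------------------------------------------------------------------

def remove_small_patches(
    burned: np.ndarray, min_pixels: int = 156, connectivity: int = 8
) -> np.ndarray:
    """Drop connected burned components smaller than ``min_pixels``.

    156 pixels is 6.25 ha on the 20-m grid. Never adds pixels; isolated
    burned pixels always go.
    """
    burned = burned.astype(bool)
    labels, n = ndimage.label(burned, structure=_structure(connectivity))
    if n == 0:
        return burned.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_pixels
    keep[0] = False
    return keep[labels]


# ---------------------------------------------------------------------------
# (b) morphology + NBR floor
# ---------------------------------------------------------------------------

def morphological_refine(burned: np.ndarray) -> np.ndarray:
    """Open with the 3x3 square, then close with the 3x3 cross element."""
    burned = burned.astype(bool)
    opened = ndimage.binary_opening(burned, structure=SQUARE_3x3)
    closed = ndimage.binary_closing(opened, structure=CROSS_3x3)
    return closed


def apply_nbr_floor(
    burned: np.ndarray, post_nbr: np.ndarray, threshold: float = -0.1
) -> np.ndarray:
    """Reclassify burned pixels with post-fire NBR > threshold as unburned.

    The inequality is strict: a pixel exactly at the threshold stays
    burned.
    """
    if post_nbr.shape != burned.shape:
        raise ValueError("post NBR grid not aligned with map")
    return burned.astype(bool) & ~(post_nbr > threshold)


# ---------------------------------------------------------------------------
# (c) hotspot masking
# ---------------------------------------------------------------------------

def load_hotspots(path: str) -> pd.DataFrame:
    """Read a FIRMS-style hotspot table (CSV or point GeoJSON).

    Accepts ``acq_date``/``date`` for the date, ``x``/``longitude`` and
    ``y``/``latitude`` for coordinates (taken in the map CRS; no
    reprojection), and either ``sensor_resolution_m`` or an
    ``instrument`` column (MODIS -> 1000 m, VIIRS -> 375 m).
    """
    if str(path).endswith((".geojson", ".json")):
        payload = json.loads(Path(path).read_text())
        rows = []
        for feat in payload.get("features", []):
            rec = dict(feat.get("properties", {}))
            geom = feat.get("geometry") or {}
            if geom.get("type") == "Point":
                rec.setdefault("x", geom["coordinates"][0])
                rec.setdefault("y", geom["coordinates"][1])
            rows.append(rec)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out = pd.DataFrame()
    date_col = cols.get("acq_date") or cols.get("date")
    if date_col is None:
        raise ValueError("hotspot table needs an acq_date/date column")
    out["acq_date"] = df[date_col].astype(str)
    x_col = cols.get("x") or cols.get("longitude")
    y_col = cols.get("y") or cols.get("latitude")
    if x_col is None or y_col is None:
        raise ValueError("hotspot table needs x/y or longitude/latitude columns")
    out["x"] = pd.to_numeric(df[x_col])
    out["y"] = pd.to_numeric(df[y_col])
    if "sensor_resolution_m" in cols:
        out["sensor_resolution_m"] = pd.to_numeric(df[cols["sensor_resolution_m"]])
    elif "instrument" in cols:
        res = df[cols["instrument"]].astype(str).str.upper().map(
            {"MODIS": 1000.0, "VIIRS": 375.0}
        )
        out["sensor_resolution_m"] = res.fillna(1000.0)
    else:
        out["sensor_resolution_m"] = 1000.0
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise ValueError("hotspot coordinates must be finite")
    return out


def hotspots_in_window(
    hotspots: pd.DataFrame, ref: MonthKey, window_months: int
) -> pd.DataFrame:
    """Rows dated within the ``window_months`` calendar months ending at ref."""
    window = {str(m) for m in month_window(ref, 0, window_months)}
    ym = hotspots["acq_date"].astype(str).str.slice(0, 7)
    return hotspots[ym.isin(window)]


def mask_with_hotspots(
    burned: np.ndarray,
    hotspots: pd.DataFrame,
    grid: GridSpec,
    ref: MonthKey,
    buffer_m: float = 100.0,
    window_months: int = 4,
    connectivity: int = 8,
) -> np.ndarray:
    """Keep only burned patches with active-fire evidence.

    A connected component survives iff at least one hotspot dated within
    the window lies within ``buffer_m`` (Euclidean, point to nearest
    burned-pixel centre) of it; otherwise the whole component is
    reclassified unburned. The scar is buffered, not the hotspot: the
    sensor's positional uncertainty is not added to the buffer.
    """
    burned = burned.astype(bool)
    if not burned.any():
        return burned.copy()
    in_window = hotspots_in_window(hotspots, ref, window_months)
    if len(in_window) == 0:
        return np.zeros_like(burned)
    labels, n = ndimage.label(burned, structure=_structure(connectivity))
    rows, cols = np.nonzero(burned)
    px, py = grid.pixel_centres(rows, cols)
    tree = cKDTree(np.column_stack([px, py]))
    pts = in_window[["x", "y"]].to_numpy(dtype=float)
    surviving: set[int] = set()
    for matches in tree.query_ball_point(pts, r=buffer_m):
        for j in matches:
            surviving.add(int(labels[rows[j], cols[j]]))
    keep = np.zeros(n + 1, dtype=bool)
    for lab in surviving:
        keep[lab] = True
    return keep[labels]


# ---------------------------------------------------------------------------
# (d) repeat masking
# ---------------------------------------------------------------------------

def mask_repeats(
    burned: np.ndarray,
    history: BurnHistory,
    ref: MonthKey,
    lookback: int = 3,
    unobserved: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> BurnMap:
    """Split detections into first-time and repeated burns.

    Burned pixels already detected burned_new in any of the ``lookback``
    months before ``ref`` become ``burned_repeat`` (not counted again);
    the rest become ``burned_new`` and are appended to the history.
    """
    burned = burned.astype(bool)
    recent = history.recent_mask(ref, lookback)
    repeat = burned & recent
    new = burned & ~recent
    codes = np.full(burned.shape, UNBURNED, dtype=np.uint8)
    codes[repeat] = BURNED_REPEAT
    codes[new] = BURNED_NEW
    if unobserved is not None:
        codes[unobserved & ~burned] = UNOBSERVED
    history.add(ref, new)
    if grid is None:
        grid = GridSpec(*burned.shape)
    return BurnMap(grid=grid, codes=codes, month=ref)


@dataclass
class FilterParams:
    """All post-classification thresholds in one auditable place."""

    min_patch_ha: float = 6.25
    min_pixels: int = 156
    nbr_floor: float = -0.1
    buffer_m: float = 100.0
    hotspot_window_months: int = 4
    lookback: int = 3
    connectivity: int = 8


def apply_filters(
    raw_burned: np.ndarray,
    post_nbr: np.ndarray,
    hotspots: pd.DataFrame,
    history: BurnHistory,
    grid: GridSpec,
    ref: MonthKey,
    params: FilterParams | None = None,
    unobserved: np.ndarray | None = None,
    log: list[dict] | None = None,
) -> BurnMap:
    """Run the four filters in the chain's fixed order.

    ``log``, if given, collects one record per stage with the burned
    pixel count after it — the per-stage deltas used for auditing.
    """
    params = params or FilterParams()

    def note(stage: str, mask: np.ndarray) -> None:
        if log is not None:
            log.append({"month": str(ref), "stage": stage, "burned_px": int(mask.sum())})

    burned = raw_burned.astype(bool)
    note("raw", burned)
    burned = remove_small_patches(burned, params.min_pixels, params.connectivity)
    note("min_mapping_unit", burned)
    burned = morphological_refine(burned)
    note("morphology", burned)
    burned = apply_nbr_floor(burned, post_nbr, params.nbr_floor)
    note("nbr_floor", burned)
    burned = mask_with_hotspots(
        burned, hotspots, grid, ref,
        buffer_m=params.buffer_m,
        window_months=params.hotspot_window_months,
        connectivity=params.connectivity,
    )
    note("hotspot_mask", burned)
    bm = mask_repeats(burned, history, ref, params.lookback, unobserved, grid=grid)
    note("burned_new", bm.burned_new_mask())
    return bm
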