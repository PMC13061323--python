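"""Synthetic Sentinel-2-like scenes with known burn truth.

The generator emulates the observational structure the monthly
burned-area chain assumes, so every downstream stage is testable without
downloading imagery:

* unburned vegetation with NBR centred near +0.5;
* connected burn scars whose NBR drops below -0.2 in the burn month and
  recovers exponentially toward baseline with a configurable half-life
  (the classic post-fire regrowth trajectory);
* wet-soil "confuser" patches — mechanically cleared, water-saturated
  soils whose NBR is burn-like but which never host an active fire;
* blobby cloud cover that flips the per-observation validity mask;
* fire-hotspot points emitted inside each scar during its burn month,
  jittered within the thermal sensor's resolution (375 m VIIRS /
  1 km MODIS).

Reflectance is stored as uint16 digital numbers scaled by 10 000, the
Sentinel-2 L2A convention; downstream code converts to reflectance
fractions. One pseudo-random stream per run, seeded from
``SimConfig.seed``; draws happen in a fixed documented order (events,
confusers, per-observation noise and clouds in date order, hotspots per
event in event order) so a fixed seed reproduces the scene bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import (
    BAND_SET,
    GridSpec,
    MonthKey,
    Observation,
    SceneStack,
    pixel_area_ha,
    read_raster,
    write_raster,
)

REFLECTANCE_SCALE = 10_000  # uint16 DN per unit reflectance

# Per-class mean reflectance per band (fractions). The binding contract
# is the NBR behaviour: vegetation (B8A-B12)/(B8A+B12) = +0.5, burned
# -0.375, wet soil -0.24 (burn-like in NBR, but brighter in the visible
# bands, which is what lets a classifier with all 22 features separate
# it while an NBR-only rule cannot).
ENDMEMBERS = {
    "vegetation": {
        "B2": 0.03, "B3": 0.05, "B4": 0.04, "B5": 0.08, "B6": 0.20,
        "B7": 0.25, "B8": 0.28, "B8A": 0.30, "B11": 0.20, "B12": 0.10,
    },
    "burned": {
        "B2": 0.04, "B3": 0.05, "B4": 0.06, "B5": 0.07, "B6": 0.08,
        "B7": 0.09, "B8": 0.09, "B8A": 0.10, "B11": 0.25, "B12": 0.22,
    },
    "wet_soil": {
        "B2": 0.09, "B3": 0.11, "B4": 0.13, "B5": 0.14, "B6": 0.15,
        "B7": 0.16, "B8": 0.16, "B8A": 0.17, "B11": 0.30, "B12": 0.28,
    },
}

BAND_NOISE_SD = 0.012  # per-band per-observation Gaussian noise


class PlacementError(RuntimeError):
    """Raised when burn events cannot be placed without overlap."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults describe an Indonesian-style fire season on a 20-m grid:
    5-day revisit, moderate cloud, scars of 20-500 ha, 3-month NBR
    regrowth half-life, VIIRS-resolution hotspots with no missed events.
    """

    grid: GridSpec
    months: list[MonthKey] = field(default_factory=list)
    revisit_days: int = 5
    cloud_prob: float = 0.0
    n_burn_events: int = 0
    burn_size_range: tuple[float, float] = (20.0, 500.0)  # hectares
    burn_month_assignment: dict[int, MonthKey] | None = None
    event_months: list[MonthKey] | None = None  # candidate burn months (default: all)
    regrowth_halflife_months: float = 3.0
    n_confusers: int = 0
    confuser_size_range: tuple[float, float] = (10.0, 50.0)  # hectares
    hotspot_density: float = 2.0  # points per burned km^2
    hotspot_jitter_m: float = 375.0  # VIIRS; 1000 for MODIS
    hotspot_miss_prob: float = 0.0
    reburn_events: list[tuple[int, MonthKey]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.cloud_prob, self.hotspot_miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.burn_month_assignment:
            allowed = {m.ordinal for m in self.months}
            for mk in self.burn_month_assignment.values():
                if mk.ordinal not in allowed:
                    raise ValueError(f"burn month {mk} outside simulated months")


@dataclass
class BurnEvent:
    event_id: int
    rows: np.ndarray
    cols: np.ndarray
    burn_month: MonthKey

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.rows, self.cols] = True
        return mask


@dataclass
class TruthSet:
    """Ground truth for a simulated run: event footprints, burn months,
    per-pixel burn counts, confuser footprints and emitted hotspots."""

    grid: GridSpec
    events: list[BurnEvent]
    burn_count: np.ndarray  # int, number of events covering each pixel
    confuser_mask: np.ndarray  # bool
    hotspots: pd.DataFrame  # acq_date, x, y, sensor_resolution_m, event_id

    def ever_burned(self) -> np.ndarray:
        return self.burn_count > 0

    def total_event_pixels(self) -> int:
        return sum(ev.n_pixels for ev in self.events)

    def burn_months_at(self, row: int, col: int) -> list[MonthKey]:
        months = [
            ev.burn_month
            for ev in self.events
            if ((ev.rows == row) & (ev.cols == col)).any()
        ]
        return sorted(months)

    def first_burn_month(self) -> np.ndarray:
        """Grid of first burn month ordinals (-1 where never burned)."""
        first = np.full(self.grid.shape, -1, dtype=np.int64)
        for ev in sorted(self.events, key=lambda e: e.burn_month.ordinal, reverse=True):
            first[ev.rows, ev.cols] = ev.burn_month.ordinal
        return first


# ---------------------------------------------------------------------------
# Event placement: random region growing from a seed pixel
# ---------------------------------------------------------------------------

_NEIGHBOURS = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))


def _grow_patch(
    rng: np.random.Generator,
    blocked: np.ndarray,
    target_px: int,
    max_seed_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Grow a connected patch of ``target_px`` pixels by random dilation,
    avoiding ``blocked`` cells. Returns (rows, cols) or None on failure."""
    n_rows, n_cols = blocked.shape
    for _ in range(max_seed_tries):
        r0 = int(rng.integers(n_rows))
        c0 = int(rng.integers(n_cols))
        if blocked[r0, c0]:
            continue
        member = np.zeros_like(blocked)
        member[r0, c0] = True
        frontier: list[tuple[int, int]] = []
        in_frontier = np.zeros_like(blocked)

        def push_neighbours(r: int, c: int) -> None:
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    if not member[rr, cc] and not blocked[rr, cc] and not in_frontier[rr, cc]:
                        frontier.append((rr, cc))
                        in_frontier[rr, cc] = True

        push_neighbours(r0, c0)
        size = 1
        while size < target_px and frontier:
            idx = int(rng.integers(len(frontier)))
            r, c = frontier[idx]
            frontier[idx] = frontier[-1]
            frontier.pop()
            in_frontier[r, c] = False
            member[r, c] = True
            size += 1
            push_neighbours(r, c)
        if size >= target_px:
            rows, cols = np.nonzero(member)
            return rows, cols
    return None


def _smooth_patch(
    rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Regularise a grown patch's boundary (close then open, keep the
    largest component): burn scars are compact at 20 m, not dendritic."""
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    square = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_opening(ndimage.binary_closing(mask, square), square)
    labels, n = ndimage.label(mask, structure=square)
    if n == 0:
        return rows, cols  # degenerate tiny patch: keep the raw growth
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return np.nonzero(labels == sizes.argmax())


def _dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def _cloud_mask(rng: np.random.Generator, shape: tuple[int, int], prob: float) -> np.ndarray:
    """Blobby cloud mask covering ~``prob`` of the scene."""
    if prob <= 0:
        return np.zeros(shape, dtype=bool)
    if prob >= 1:
        return np.ones(shape, dtype=bool)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=8.0)
    thresh = np.quantile(smooth, 1.0 - prob)
    return smooth > thresh


def regrowth_weight(months_since_burn: np.ndarray | float, halflife: float) -> np.ndarray:
    """Burned-endmember mixing weight t months after burning: 0.5**(t/h).

    Weight 1 in the burn month (t=0) and halving every ``halflife``
    months; the reflectance of a recovering pixel is
    ``w * burned + (1 - w) * vegetation`` per band, which is the closed
    form tests check the generated time series against.
    """
    t = np.asarray(months_since_burn, dtype=float)
    w = np.where(t < 0, 0.0, 0.5 ** (t / halflife))
    return w


def expected_nbr(months_since_burn: float, halflife: float) -> float:
    """Closed-form NBR of the regrowth blend (B8A/B12 pair), noise-free."""
    w = float(regrowth_weight(months_since_burn, halflife))
    nir = (1 - w) * ENDMEMBERS["vegetation"]["B8A"] + w * ENDMEMBERS["burned"]["B8A"]
    swir = (1 - w) * ENDMEMBERS["vegetation"]["B12"] + w * ENDMEMBERS["burned"]["B12"]
    return (nir - swir) / (nir + swir)


def _observation_dates(months: list[MonthKey], revisit_days: int) -> list[str]:
    dates = []
    for mk in sorted(months, key=lambda m: m.ordinal):
        day = 1
        while day <= 28:  # stop at 28 so every month has the same cadence
            dates.append(f"{mk.year:04d}-{mk.month:02d}-{day:02d}")
            day += revisit_days
    return dates


def simulate_stack(config: SimConfig) -> tuple[SceneStack, pd.DataFrame, TruthSet]:
    """Simulate a scene stack, hotspot table and ground truth.

    Deterministic for a fixed ``config.seed``. Raises
    :class:`PlacementError` when the requested events cannot be placed
    without overlap within the retry budget.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    shape = grid.shape
    px_ha = pixel_area_ha(grid)
    months = sorted(config.months, key=lambda m: m.ordinal)
    if not months:
        raise ValueError("SimConfig.months must not be empty")

    # --- burn events -------------------------------------------------------
    events: list[BurnEvent] = []
    occupied = np.zeros(shape, dtype=bool)  # events + separation margin
    margin_px = 3  # keeps scars distinct components even after closing
    for i in range(config.n_burn_events):
        lo, hi = config.burn_size_range
        area_ha = float(rng.uniform(lo, hi))
        target_px = max(1, int(round(area_ha / px_ha)))
        grown = _grow_patch(rng, occupied, target_px)
        if grown is None:
            raise PlacementError(
                f"could not place event {i} of {target_px} px without overlap"
            )
        rows, cols = _smooth_patch(*grown, shape)
        if config.burn_month_assignment and i in config.burn_month_assignment:
            burn_month = config.burn_month_assignment[i]
        else:
            candidates = config.event_months or months
            burn_month = candidates[int(rng.integers(len(candidates)))]
        events.append(BurnEvent(i, rows, cols, burn_month))
        fp = np.zeros(shape, dtype=bool)
        fp[rows, cols] = True
        occupied |= _dilate(fp, margin_px)

    # re-burns: an earlier footprint burning again in a later month
    for src_idx, new_month in config.reburn_events:
        src = events[src_idx]
        if new_month.ordinal <= src.burn_month.ordinal:
            raise ValueError("re-burn month must follow the source event's month")
        events.append(BurnEvent(len(events), src.rows.copy(), src.cols.copy(), new_month))

    event_union = np.zeros(shape, dtype=bool)
    burn_count = np.zeros(shape, dtype=np.int32)
    for ev in events:
        event_union[ev.rows, ev.cols] = True
        burn_count[ev.rows, ev.cols] += 1

    # --- wet-soil confusers ------------------------------------------------
    # kept far enough from events that no hotspot (jittered by at most
    # half the sensor resolution) can land within jitter distance of a
    # confuser-only patch
    confuser_mask = np.zeros(shape, dtype=bool)
    sep_px = int(np.ceil((1.5 * config.hotspot_jitter_m + 100.0) / grid.pixel_size))
    blocked_for_confusers = _dilate(event_union, sep_px) | occupied
    for i in range(config.n_confusers):
        lo, hi = config.confuser_size_range
        target_px = max(1, int(round(float(rng.uniform(lo, hi)) / px_ha)))
        grown = _grow_patch(rng, blocked_for_confusers | _dilate(confuser_mask, 3), target_px)
        if grown is None:
            raise PlacementError(f"could not place confuser {i} of {target_px} px")
        c_rows, c_cols = _smooth_patch(*grown, shape)
        confuser_mask[c_rows, c_cols] = True

    # --- monthly mean reflectance cubes ------------------------------------
    veg = np.array([ENDMEMBERS["vegetation"][b] for b in BAND_SET], dtype=np.float32)
    burned = np.array([ENDMEMBERS["burned"][b] for b in BAND_SET], dtype=np.float32)
    wet = np.array([ENDMEMBERS["wet_soil"][b] for b in BAND_SET], dtype=np.float32)

    def month_mean_cube(mk: MonthKey) -> np.ndarray:
        w = np.zeros(shape, dtype=np.float32)
        for ev in events:
            dt = mk.ordinal - ev.burn_month.ordinal
            if dt >= 0:
                w_ev = float(regrowth_weight(dt, config.regrowth_halflife_months))
                # most recent burn dominates a re-burned pixel
                cur = w[ev.rows, ev.cols]
                w[ev.rows, ev.cols] = np.maximum(cur, w_ev)
        cube = veg[:, None, None] * (1.0 - w)[None] + burned[:, None, None] * w[None]
        cube[:, confuser_mask] = wet[:, None]
        return cube

    # --- observations -------------------------------------------------------
    dates = _observation_dates(months, config.revisit_days)
    observations: list[Observation] = []
    cube_cache: dict[int, np.ndarray] = {}
    for date in dates:
        mk = MonthKey(int(date[:4]), int(date[5:7]))
        if mk.ordinal not in cube_cache:
            cube_cache.clear()  # only the current month's cube is needed
            cube_cache[mk.ordinal] = month_mean_cube(mk)
        cube = cube_cache[mk.ordinal]
        noise = rng.normal(0.0, BAND_NOISE_SD, size=cube.shape).astype(np.float32)
        refl = np.clip(cube + noise, 0.0, 1.0)
        clouds = _cloud_mask(rng, shape, config.cloud_prob)
        dn = (refl * REFLECTANCE_SCALE).astype(np.uint16)
        bands = {b: dn[k] for k, b in enumerate(BAND_SET)}
        observations.append(Observation(date=date, bands=bands, valid=~clouds))

    stack = SceneStack(grid=grid, observations=observations)

    # --- hotspots ------------------------------------------------------------
    rows_out: list[dict] = []
    max_offset = config.hotspot_jitter_m / 2.0  # centroid stays inside sensor pixel
    for ev in events:
        if config.hotspot_miss_prob > 0 and rng.random() < config.hotspot_miss_prob:
            continue
        area_km2 = ev.n_pixels * px_ha / 100.0
        n_points = max(1, int(round(config.hotspot_density * area_km2)))
        for _ in range(n_points):
            for _attempt in range(50):
                j = int(rng.integers(ev.n_pixels))
                x, y = grid.pixel_centres(ev.rows[j], ev.cols[j])
                theta = rng.uniform(0, 2 * np.pi)
                rad = max_offset * np.sqrt(rng.random())
                hx = float(x + rad * np.cos(theta))
                hy = float(y + rad * np.sin(theta))
                hr, hc = grid.point_to_rowcol(hx, hy)
                hr = int(np.clip(hr, 0, shape[0] - 1))
                hc = int(np.clip(hc, 0, shape[1] - 1))
                # reject draws landing near a confuser patch
                if not confuser_mask[hr, hc]:
                    break
            day = int(rng.integers(1, 29))
            rows_out.append(
                {
                    "acq_date": f"{ev.burn_month.year:04d}-{ev.burn_month.month:02d}-{day:02d}",
                    "x": hx,
                    "y": hy,
                    "sensor_resolution_m": config.hotspot_jitter_m,
                    "event_id": ev.event_id,
                }
            )
    hotspots = pd.DataFrame(
        rows_out, columns=["acq_date", "x", "y", "sensor_resolution_m", "event_id"]
    )

    truth = TruthSet(
        grid=grid,
        events=events,
        burn_count=burn_count,
        confuser_mask=confuser_mask,
        hotspots=hotspots,
    )
    return stack, hotspots, truth


# ---------------------------------------------------------------------------
# Labelled point sampling
# ---------------------------------------------------------------------------

def sample_training_points(
    truth: TruthSet,
    n_burned: int,
    n_unburned: int,
    seed: int,
    months: list[MonthKey] | None = None,
    confuser_fraction: float = 0.25,
) -> pd.DataFrame:
    """Sample labelled training points from the truth.

    Labels follow the chain's convention: 0 = burned, 1 = unburned. Each
    burned point carries the month its event burned (spectra are
    extracted from that month's composite pair); unburned points get a
    random simulated month. When confuser patches exist, up to
    ``confuser_fraction`` of the unburned sample is drawn from them —
    the hard negatives that teach the classifier not to fire on wet,
    vegetation-free soils.
    """
    rng = np.random.default_rng(seed)
    first_burn = truth.first_burn_month()
    burned_rows, burned_cols = np.nonzero(truth.ever_burned())
    unburned_mask = ~truth.ever_burned()
    conf_rows, conf_cols = np.nonzero(unburned_mask & truth.confuser_mask)
    plain_rows, plain_cols = np.nonzero(unburned_mask & ~truth.confuser_mask)

    if n_burned > len(burned_rows):
        raise ValueError(f"requested {n_burned} burned points, {len(burned_rows)} available")
    if months is None:
        months = sorted({ev.burn_month for ev in truth.events}, key=lambda m: m.ordinal)
    if not months:
        raise ValueError("no months available for unburned point assignment")

    records: list[dict] = []
    if n_burned:
        idx = rng.choice(len(burned_rows), size=n_burned, replace=False)
        for i in idx:
            r, c = int(burned_rows[i]), int(burned_cols[i])
            mk = MonthKey.from_ordinal(int(first_burn[r, c]))
            records.append({"row": r, "col": c, "label": 0, "month": str(mk)})

    n_conf = min(int(round(confuser_fraction * n_unburned)), len(conf_rows))
    n_plain = n_unburned - n_conf
    if n_plain > len(plain_rows):
        raise ValueError(
            f"requested {n_unburned} unburned points, "
            f"{len(plain_rows) + len(conf_rows)} available"
        )
    for pool_rows, pool_cols, n in (
        (conf_rows, conf_cols, n_conf),
        (plain_rows, plain_cols, n_plain),
    ):
        if n == 0:
            continue
        idx = rng.choice(len(pool_rows), size=n, replace=False)
        for i in idx:
            r, c = int(pool_rows[i]), int(pool_cols[i])
            mk = months[int(rng.integers(len(months)))]
            records.append({"row": r, "col": c, "label": 1, "month": str(mk)})

    df = pd.DataFrame(records, columns=["row", "col", "label", "month"])
    x, y = truth.grid.pixel_centres(df["row"].to_numpy(), df["col"].to_numpy())
    df["x"], df["y"] = x, y
    return df


def sample_reference_points(
    map_burned: np.ndarray,
    truth: TruthSet,
    strata_counts: dict[str, int],
    seed: int,
    second_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stratified-random reference sample for accuracy assessment.

    Strata are defined by the map class ("burned"/"unburned"), optionally
    crossed with a second map ("burned_burned", "burned_unburned", ...)
    as used when rebalancing a sample between a monthly and an annual
    layer. Each point carries its map class, true class and stratum id.
    """
    rng = np.random.default_rng(seed)

    def cls(mask: np.ndarray) -> np.ndarray:
        return np.where(mask, "burned", "unburned")

    map_cls = cls(map_burned.astype(bool))
    if second_map is not None:
        strata = np.char.add(np.char.add(map_cls, "_"), cls(second_map.astype(bool)))
    else:
        strata = map_cls
    true_cls = cls(truth.ever_burned())
    first_burn = truth.first_burn_month()

    records: list[dict] = []
    for stratum, n in strata_counts.items():
        rows, cols = np.nonzero(strata == stratum)
        if n > len(rows):
            raise ValueError(
                f"stratum {stratum!r} has {len(rows)} pixels, {n} requested"
            )
        idx = rng.choice(len(rows), size=n, replace=False)
        for i in idx:
            r, c = int(rows[i]), int(cols[i])
            tb = int(first_burn[r, c])
            records.append(
                {
                    "row": r,
                    "col": c,
                    "map_class": str(map_cls[r, c]),
                    "true_class": str(true_cls[r, c]),
                    "stratum": stratum,
                    "true_burn_month": str(MonthKey.from_ordinal(tb)) if tb >= 0 else "",
                }
            )
    df = pd.DataFrame(
        records,
        columns=["row", "col", "map_class", "true_class", "stratum", "true_burn_month"],
    )
    if len(df):
        x, y = truth.grid.pixel_centres(df["row"].to_numpy(), df["col"].to_numpy())
        df["x"], df["y"] = x, y
    return df


# ---------------------------------------------------------------------------
# On-disk interchange: per-date multiband GeoTIFFs + manifest, truth rasters
# ---------------------------------------------------------------------------

def write_scene(stack: SceneStack, out_dir: str | Path) -> Path:
    """Write each observation as a multiband GeoTIFF plus a manifest CSV.

    Band order is the canonical band set; an extra trailing band holds
    the validity mask (1 valid / 0 invalid). Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for obs in stack.observations:
        cube = np.stack(
            [np.asarray(obs.bands[b], dtype=np.uint16) for b in stack.band_set]
            + [obs.valid.astype(np.uint16)]
        )
        path = out_dir / f"scene_{obs.date}.tif"
        write_raster(path, cube, stack.grid)
        rows.append({"date": obs.date, "path": path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_scene(manifest_path: str | Path) -> SceneStack:
    """Read a scene stack written by :func:`write_scene`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    rows = pd.read_csv(manifest_path)
    observations: list[Observation] = []
    grid: GridSpec | None = None
    for _, row in rows.iterrows():
        cube, _, g = read_raster(base / str(row["path"]), expected_grid=grid)
        grid = grid or g
        bands = {b: cube[i] for i, b in enumerate(BAND_SET)}
        valid = cube[len(BAND_SET)].astype(bool)
        observations.append(Observation(date=str(row["date"]), bands=bands, valid=valid))
    if grid is None:
        raise ValueError(f"empty manifest: {manifest_path}")
    return SceneStack(grid=grid, observations=observations)


def save_hotspots(hotspots: pd.DataFrame, path: str | Path) -> None:
    """Write a hotspot table as CSV, or point GeoJSON for .geojson/.json."""
    path = Path(path)
    if path.suffix in (".geojson", ".json"):
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                "properties": {
                    k: row[k] for k in hotspots.columns if k not in ("x", "y")
                },
            }
            for _, row in hotspots.iterrows()
        ]
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
    else:
        hotspots.to_csv(path, index=False)


def write_truth(truth: TruthSet, out_dir: str | Path) -> None:
    """Persist the truth: burn-count and event-label grids, confuser mask,
    events CSV (re-burn events reference the footprint they reuse)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_raster(out_dir / "burn_count.tif", truth.burn_count.astype(np.int32), truth.grid)
    write_raster(out_dir / "confusers.tif", truth.confuser_mask.astype(np.uint8), truth.grid)
    label = np.zeros(truth.grid.shape, dtype=np.int32)
    rows = []
    seen_px: dict[int, int] = {}
    for ev in truth.events:
        key = hash((ev.rows.tobytes(), ev.cols.tobytes()))
        source = seen_px.get(key, -1)
        if source < 0:
            label[ev.rows, ev.cols] = ev.event_id + 1
            seen_px[key] = ev.event_id
        rows.append(
            {"event_id": ev.event_id, "burn_month": str(ev.burn_month),
             "n_pixels": ev.n_pixels, "footprint_of": source}
        )
    write_raster(out_dir / "event_label.tif", label, truth.grid)
    pd.DataFrame(rows).to_csv(out_dir / "events.csv", index=False)
    save_hotspots(truth.hotspots, out_dir / "hotspots.csv")


def read_truth(out_dir: str | Path) -> TruthSet:
    out_dir = Path(out_dir)
    burn_count, _, grid = read_raster(out_dir / "burn_count.tif")
    confusers, _, _ = read_raster(out_dir / "confusers.tif", expected_grid=grid)
    label, _, _ = read_raster(out_dir / "event_label.tif", expected_grid=grid)
    ev_rows = pd.read_csv(out_dir / "events.csv")
    events: list[BurnEvent] = []
    by_id: dict[int, BurnEvent] = {}
    for _, row in ev_rows.iterrows():
        eid = int(row["event_id"])
        src = int(row["footprint_of"])
        if src >= 0:
            rows_, cols_ = by_id[src].rows.copy(), by_id[src].cols.copy()
        else:
            rows_, cols_ = np.nonzero(label == eid + 1)
        ev = BurnEvent(eid, rows_, cols_, MonthKey.parse(str(row["burn_month"])))
        events.append(ev)
        by_id[eid] = ev
    hotspots = pd.read_csv(out_dir / "hotspots.csv")
    return TruthSet(
        grid=grid, events=events, burn_count=burn_count.astype(np.int32),
        confuser_mask=confusers.astype(bool), hotspots=hotspots,
    )
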