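"""Month-by-month orchestration and aggregate burned-area products.

For each reference month the chain composes: pre/post median composites
-> 22-feature stack -> random-forest prediction -> the four
post-classification filters, threading the burn history through so
repeat detections of a persistent scar are flagged rather than
re-counted. Aggregates follow the product definitions: *burned extent*
counts each pixel once, *cumulative burned area* counts each pixel once
per distinct burn event (sum of k x area burned k times).

Pixels clouded out of either composite are *unobserved* for that month:
they cannot be detected, are excluded from denominators, and may appear
as newly burned in a later month if the scar is still visible — exactly
the behaviour that motivates the repeat filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, MonthKey, SceneStack, ZoneMask, month_window, pixel_area_ha, require_same_grid
from .compositing import EmptyWindowError, build_composite
from .classifier import CLASS_BURNED, BurnClassifier, assemble_features, predict
from .filters import BurnHistory, BurnMap, FilterParams, apply_filters


class StageError(RuntimeError):
    """An error in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, month: MonthKey, cause: Exception):
        super().__init__(f"[{stage}] {month}: {cause}")
        self.stage = stage
        self.month = month
        self.cause = cause


@dataclass
class RunConfig:
    """Every named constant of the chain in one auditable place."""

    pre_window_months: int = 3
    filters: FilterParams = field(default_factory=FilterParams)
    nbr_bands: tuple[str, str] = ("B8A", "B12")
    on_missing_month: str = "skip"  # "skip" | "fail"
    seed: int = 0


@dataclass
class BurnSummary:
    """Aggregate accounting over a run of monthly maps.

    Invariants: total_extent_ha = area_once_ha + area_multiple_ha, and
    cumulative_ha = sum_k k * area_k >= total_extent_ha.
    """

    months: list[str]
    monthly_new_ha: list[float]
    cumulative_series_ha: list[float]
    burn_count: np.ndarray
    pixel_ha: float

    @property
    def area_once_ha(self) -> float:
        return float((self.burn_count == 1).sum()) * self.pixel_ha

    @property
    def area_multiple_ha(self) -> float:
        return float((self.burn_count >= 2).sum()) * self.pixel_ha

    @property
    def total_extent_ha(self) -> float:
        return float((self.burn_count >= 1).sum()) * self.pixel_ha

    @property
    def cumulative_ha(self) -> float:
        return float(self.burn_count.sum()) * self.pixel_ha

    def area_burned_k_times(self, k: int) -> float:
        return float((self.burn_count == k).sum()) * self.pixel_ha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months,
                "burned_new_ha": self.monthly_new_ha,
                "cumulative_ha": self.cumulative_series_ha,
            }
        )


def get_composite(
    stack: SceneStack,
    ref: MonthKey,
    kind: str,
    config: "RunConfig",
    cache: dict | None = None,
):
    """Pre- or post-fire composite for ``ref``, memoised when a cache dict
    is supplied (training and monthly runs share composites)."""
    key = (kind, ref.ordinal)
    if cache is not None and key in cache:
        return cache[key]
    if kind == "pre":
        months = month_window(ref, 1, config.pre_window_months)
    else:
        months = [ref]
    comp = build_composite(stack, months, kind, config.nbr_bands)
    if cache is not None:
        cache[key] = comp
    return comp


def monthly_feature_stack(
    stack: SceneStack, ref: MonthKey, config: "RunConfig", cache: dict | None = None
):
    """The 22-feature stack (and post composite) for one reference month."""
    pre = get_composite(stack, ref, "pre", config, cache)
    post = get_composite(stack, ref, "post", config, cache)
    return assemble_features(pre, post), post


def run_month(
    stack: SceneStack,
    hotspots: pd.DataFrame,
    history: BurnHistory,
    ref: MonthKey,
    model: BurnClassifier,
    config: RunConfig | None = None,
    log: list[dict] | None = None,
    cache: dict | None = None,
) -> BurnMap:
    """Process one reference month end to end.

    Raises :class:`StageError` naming the failing stage; updates
    ``history`` with the month's burned_new layer as a side effect.
    """
    config = config or RunConfig()
    try:
        pre = get_composite(stack, ref, "pre", config, cache)
        post = get_composite(stack, ref, "post", config, cache)
    except EmptyWindowError as e:
        raise StageError("compositing", ref, e) from e
    try:
        fs = assemble_features(pre, post)
    except Exception as e:
        raise StageError("features", ref, e) from e
    try:
        raw = predict(model, fs)
    except Exception as e:
        raise StageError("classification", ref, e) from e
    try:
        burned = raw == CLASS_BURNED
        unobserved = ~fs.valid
        return apply_filters(
            burned, post.nbr, hotspots, history, stack.grid, ref,
            params=config.filters, unobserved=unobserved, log=log,
        )
    except Exception as e:
        raise StageError("postclassification", ref, e) from e


def run_range(
    months: list[MonthKey],
    stack: SceneStack,
    hotspots: pd.DataFrame,
    model: BurnClassifier,
    config: RunConfig | None = None,
    history: BurnHistory | None = None,
    log: list[dict] | None = None,
    cache: dict | None = None,
) -> tuple[list[BurnMap], BurnHistory]:
    """Process months in order, threading the burn history through.

    A month with no observations is skipped with a log record (or fails,
    per ``config.on_missing_month``).
    """
    config = config or RunConfig()
    history = history or BurnHistory(stack.grid.shape)
    maps: list[BurnMap] = []
    for ref in sorted(months, key=lambda m: m.ordinal):
        try:
            maps.append(run_month(stack, hotspots, history, ref, model, config, log, cache))
        except StageError as e:
            if config.on_missing_month == "skip" and isinstance(e.cause, EmptyWindowError):
                if log is not None:
                    log.append({"month": str(ref), "stage": "skipped", "burned_px": 0})
                continue
            raise
    return maps, history


def summarize(maps: list[BurnMap]) -> BurnSummary:
    """Aggregate monthly maps into the accounting identities.

    burn_count counts burned_new detections per pixel across the run;
    repeats never increment it, so the extent/cumulative split is exact.
    """
    if not maps:
        raise ValueError("no maps to summarize")
    grid = maps[0].grid
    for m in maps[1:]:
        require_same_grid(grid, m.grid, "summarize")
    px_ha = pixel_area_ha(grid)
    burn_count = np.zeros(grid.shape, dtype=np.int32)
    months: list[str] = []
    monthly: list[float] = []
    cumulative: list[float] = []
    running = 0.0
    for m in sorted(maps, key=lambda b: b.month.ordinal):
        new = m.burned_new_mask()
        burn_count += new.astype(np.int32)
        area = float(new.sum()) * px_ha
        running += area
        months.append(str(m.month))
        monthly.append(area)
        cumulative.append(running)
    return BurnSummary(
        months=months,
        monthly_new_ha=monthly,
        cumulative_series_ha=cumulative,
        burn_count=burn_count,
        pixel_ha=px_ha,
    )


def aggregate_fraction(
    burned: np.ndarray,
    observed: np.ndarray | None = None,
    factor: int = 50,
) -> np.ndarray:
    """Aggregate a 20-m burned mask to a coarse burned-area fraction.

    Each coarse cell (50x50 blocks -> 1 km at 20 m) is the burned pixel
    count over the valid pixel count in its block; blocks with no valid
    pixel are NaN (undefined, not zero). Grids not divisible by
    ``factor`` are padded with unobserved pixels.
    """
    burned = burned.astype(bool)
    if observed is None:
        observed = np.ones_like(burned)
    observed = observed.astype(bool)
    h, w = burned.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        burned = np.pad(burned, ((0, ph), (0, pw)))
        observed = np.pad(observed, ((0, ph), (0, pw)))
    H, W = burned.shape[0] // factor, burned.shape[1] // factor

    def block_sum(a: np.ndarray) -> np.ndarray:
        return a.reshape(H, factor, W, factor).sum(axis=(1, 3))

    n_burn = block_sum(burned & observed).astype(float)
    n_obs = block_sum(observed).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_obs > 0, n_burn / n_obs, np.nan)
    return frac


def zonal_area(maps: list[BurnMap], zone: ZoneMask) -> float:
    """Burned_new hectares falling inside a zone mask (forest, peat, ...)."""
    if not maps:
        return 0.0
    total_px = 0
    for m in maps:
        require_same_grid(m.grid, zone.grid, "zonal_area")
        total_px += int((m.burned_new_mask() & zone.member).sum())
    return total_px * pixel_area_ha(maps[0].grid)


def detected_months_for_points(maps: list[BurnMap], points: pd.DataFrame) -> pd.Series:
    """First month each point's pixel was detected burned_new ("" if never)."""
    ordered = sorted(maps, key=lambda m: m.month.ordinal)
    rows = points["row"].to_numpy()
    cols = points["col"].to_numpy()
    out = np.array([""] * len(points), dtype=object)
    found = np.zeros(len(points), dtype=bool)
    for m in ordered:
        new = m.burned_new_mask()
        hit = new[rows, cols] & ~found
        out[hit] = str(m.month)
        found |= hit
    return pd.Series(out, index=points.index, name="detected_month")


def write_burnmap(path, burnmap: BurnMap) -> None:
    """Monthly map as uint8 GeoTIFF: 0 unburned, 1 burned_new,
    2 burned_repeat, 255 unobserved."""
    from .grid import write_raster

    write_raster(path, burnmap.codes.astype(np.uint8), burnmap.grid, nodata=255)


def read_burnmap(path, month: MonthKey) -> BurnMap:
    from .grid import read_raster

    codes, _, grid = read_raster(path)
    return BurnMap(grid=grid, codes=codes.astype(np.uint8), month=month)
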