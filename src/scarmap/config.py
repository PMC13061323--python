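"""Configuration: every named constant of the chain, in one YAML file.

Defaults are the chain's operating values: 6.25-ha minimum mapping unit,
-0.1 NBR floor, 100-m hotspot buffer, 4-month hotspot window, 3-month
repeat lookback, 3-month pre-fire window. Unknown keys and out-of-range
values are rejected at load time, and the effective configuration can be
dumped back out, so no threshold is ever hidden in code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import RFConfig
from .filters import FilterParams
from .grid import GridSpec, MonthKey
from .pipeline import RunConfig
from .synth import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Union of the simulation, classification, filtering and run settings."""

    grid_rows: int = 256
    grid_cols: int = 256
    pixel_size_m: float = 20.0
    months: list[str] = field(default_factory=lambda: [f"2019-{m:02d}" for m in range(1, 7)])
    # simulation
    revisit_days: int = 5
    cloud_prob: float = 0.2
    n_burn_events: int = 3
    burn_size_min_ha: float = 20.0
    burn_size_max_ha: float = 300.0
    regrowth_halflife_months: float = 3.0
    n_confusers: int = 1
    confuser_size_min_ha: float = 10.0
    confuser_size_max_ha: float = 50.0
    hotspot_density: float = 2.0
    hotspot_jitter_m: float = 375.0
    hotspot_miss_prob: float = 0.0
    # classifier
    n_trees: int = 100
    features_per_split: str = "sqrt"
    min_leaf: int = 1
    n_train_burned: int = 852
    n_train_unburned: int = 1491
    # compositing + filters
    pre_window_months: int = 3
    nbr_band_pair: str = "B8A/B12"  # or "B8/B12"
    min_patch_ha: float = 6.25
    nbr_floor: float = -0.1
    buffer_m: float = 100.0
    hotspot_window_months: int = 4
    lookback: int = 3
    connectivity: int = 8
    # validation
    n_ref_burned: int = 150
    n_ref_unburned: int = 892
    # run
    seed: int = 0
    out_dir: str = "scarmap_out"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if not -1.0 <= self.nbr_floor <= 1.0:
            raise ConfigError(f"nbr_floor must be in [-1, 1], got {self.nbr_floor}")
        for name in ("cloud_prob", "hotspot_miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_patch_ha", "buffer_m", "pixel_size_m", "hotspot_jitter_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("pre_window_months", "hotspot_window_months", "lookback",
                     "n_trees", "grid_rows", "grid_cols", "revisit_days"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.nbr_band_pair not in ("B8A/B12", "B8/B12"):
            raise ConfigError("nbr_band_pair must be 'B8A/B12' or 'B8/B12'")
        if self.burn_size_min_ha > self.burn_size_max_ha:
            raise ConfigError("burn_size_min_ha exceeds burn_size_max_ha")
        mks = [MonthKey.parse(m) for m in self.months]
        if any(b.ordinal - a.ordinal != 1 for a, b in zip(mks, mks[1:])):
            raise ConfigError("months must be contiguous")
        return self

    # --- derived objects ---------------------------------------------------

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_rows, self.grid_cols, self.pixel_size_m)

    def month_keys(self) -> list[MonthKey]:
        return [MonthKey.parse(m) for m in self.months]

    def sim_config(self) -> SimConfig:
        return SimConfig(
            grid=self.grid(),
            months=self.month_keys(),
            revisit_days=self.revisit_days,
            cloud_prob=self.cloud_prob,
            n_burn_events=self.n_burn_events,
            burn_size_range=(self.burn_size_min_ha, self.burn_size_max_ha),
            regrowth_halflife_months=self.regrowth_halflife_months,
            n_confusers=self.n_confusers,
            confuser_size_range=(self.confuser_size_min_ha, self.confuser_size_max_ha),
            hotspot_density=self.hotspot_density,
            hotspot_jitter_m=self.hotspot_jitter_m,
            hotspot_miss_prob=self.hotspot_miss_prob,
            seed=self.seed,
        )

    def rf_config(self) -> RFConfig:
        return RFConfig(
            n_trees=self.n_trees,
            features_per_split=self.features_per_split,
            min_leaf=self.min_leaf,
            seed=self.seed,
        )

    def filter_params(self) -> FilterParams:
        from .grid import mmu_pixels
        return FilterParams(
            min_patch_ha=self.min_patch_ha,
            min_pixels=mmu_pixels(self.min_patch_ha, self.grid()),
            nbr_floor=self.nbr_floor,
            buffer_m=self.buffer_m,
            hotspot_window_months=self.hotspot_window_months,
            lookback=self.lookback,
            connectivity=self.connectivity,
        )

    def run_config(self) -> RunConfig:
        pair = tuple(self.nbr_band_pair.split("/"))
        return RunConfig(
            pre_window_months=self.pre_window_months,
            filters=self.filter_params(),
            nbr_bands=pair,  # type: ignore[arg-type]
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, fill defaults, validate invariants.

    An empty (or absent) file yields the full default configuration;
    unknown keys raise :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    return cfg.validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
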