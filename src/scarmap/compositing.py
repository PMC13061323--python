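"""Cloud-free pre- and post-fire median composites and NBR.

For a reference month the chain builds two composites: a *pre-fire*
composite from the three preceding calendar months (long enough to find
cloud-free looks under persistent tropical cloud, short enough that the
vegetation is stable) and a *post-fire* composite from the reference
month itself. Each is the per-pixel, per-band median over all valid
observations in the window; pixels with no valid observation are marked
unobserved and excluded from classification for that month.

NBR = (NIR - SWIR) / (NIR + SWIR), using B8A and B12 by default (both
native 20 m, avoiding resampling artefacts; B8/B12 available by option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import BAND_SET, GridSpec, MonthKey, Observation, SceneStack
from .synth import REFLECTANCE_SCALE


class EmptyWindowError(ValueError):
    """No observation at all falls inside the compositing window."""


@dataclass
class Composite:
    """Per-band median reflectance plus NBR for one compositing window."""

    grid: GridSpec
    bands: dict[str, np.ndarray]  # float32 reflectance fractions
    nbr: np.ndarray
    valid: np.ndarray  # bool; >=1 valid observation in the window
    window: list[MonthKey] = field(default_factory=list)
    kind: str = "pre"  # "pre" | "post"


def _to_reflectance(arr: np.ndarray) -> np.ndarray:
    """Integer DNs are scaled by 1/10000 (Sentinel-2 L2A); floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float32) / REFLECTANCE_SCALE
    return arr.astype(np.float32)


def mask_invalid(stack: SceneStack) -> SceneStack:
    """Apply each observation's quality mask: flagged pixels are excluded
    from all downstream aggregation (their values never reach a median).

    Returns a stack whose band values are NaN wherever invalid, making
    accidental use of flagged pixels loud rather than silent.
    """
    cleaned: list[Observation] = []
    for obs in stack.observations:
        if obs.valid is None:
            raise ValueError(f"observation {obs.date} has no validity mask")
        bands = {}
        for name, arr in obs.bands.items():
            refl = _to_reflectance(arr).copy()
            refl[~obs.valid] = np.nan
            bands[name] = refl
        cleaned.append(Observation(date=obs.date, bands=bands, valid=obs.valid.copy()))
    return SceneStack(grid=stack.grid, observations=cleaned, band_set=stack.band_set)


def resample_10m_to_20m(
    band_10m: np.ndarray, valid_10m: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a 10-m band to 20 m by the mean of each 2x2 block.

    The mean runs over the block's valid children only; a 20-m pixel is
    valid iff at least one child is. Dimensions must be even.
    """
    band_10m = np.asarray(band_10m)
    if band_10m.shape[0] % 2 or band_10m.shape[1] % 2:
        raise ValueError(f"10-m grid dimensions must be even, got {band_10m.shape}")
    if valid_10m is None:
        valid_10m = np.ones(band_10m.shape, dtype=bool)
    vals = _to_reflectance(band_10m).copy()
    vals[~valid_10m] = np.nan
    h, w = band_10m.shape[0] // 2, band_10m.shape[1] // 2
    blocks = vals.reshape(h, 2, w, 2).transpose(0, 2, 1, 3).reshape(h, w, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(blocks, axis=-1)
    valid = ~np.isnan(out)
    out = np.where(valid, out, 0.0).astype(np.float32)
    return out, valid


def build_composite(
    stack: SceneStack,
    months: list[MonthKey],
    kind: str = "pre",
    nbr_bands: tuple[str, str] = ("B8A", "B12"),
) -> Composite:
    """Per-pixel per-band median of valid observations within ``months``.

    Even observation counts take the mean of the two central values.
    Raises :class:`EmptyWindowError` when the stack holds no observation
    in the window; pixels valid in no observation come out with
    ``valid=False`` (unobserved that month).
    """
    window_obs = stack.in_months(months)
    if not window_obs:
        raise EmptyWindowError(
            f"no observations in window {[str(m) for m in months]}"
        )
    shape = stack.grid.shape
    bands: dict[str, np.ndarray] = {}
    any_valid = np.zeros(shape, dtype=bool)
    for name in stack.band_set:
        layers = np.empty((len(window_obs),) + shape, dtype=np.float32)
        for k, obs in enumerate(window_obs):
            refl = _to_reflectance(obs.bands[name])
            layers[k] = np.where(obs.valid, refl, np.nan)
        with warnings.catch_warnings():
            # pixels with no valid look in the window are expected: they
            # become unobserved, not an error
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(layers, axis=0)
        bands[name] = med.astype(np.float32)
        any_valid |= ~np.isnan(med)
    valid = any_valid
    for name in bands:
        bands[name] = np.where(valid & ~np.isnan(bands[name]), bands[name], 0.0).astype(
            np.float32
        )
    comp = Composite(
        grid=stack.grid, bands=bands, nbr=np.zeros(shape, np.float32),
        valid=valid, window=list(months), kind=kind,
    )
    comp.nbr, nbr_valid = compute_nbr(comp, nbr_bands)
    comp.valid = valid & nbr_valid
    return comp


def compute_nbr(
    composite: Composite, nbr_bands: tuple[str, str] = ("B8A", "B12")
) -> tuple[np.ndarray, np.ndarray]:
    """NBR = (NIR - SWIR)/(NIR + SWIR) on the composite's bands.

    Returns ``(nbr, valid)``; pixels where NIR + SWIR == 0 are flagged
    invalid rather than propagating NaN/inf into downstream maps.
    """
    nir_name, swir_name = nbr_bands
    nir = composite.bands[nir_name]
    swir = composite.bands[swir_name]
    denom = nir + swir
    ok = composite.valid & (denom != 0)
    nbr = np.zeros_like(nir, dtype=np.float32)
    np.divide(nir - swir, denom, out=nbr, where=ok)
    return nbr, ok
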