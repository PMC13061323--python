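# Methods

## The processing model

The chain detects burns as a spectral change between two cloud-free
median composites per reference month. The pre-fire composite spans the
three preceding calendar months: long enough to find valid looks under
persistent tropical cloud, short enough that vegetation is stable, so
the pre/post contrast isolates the fire signal. The post-fire composite
is restricted to the reference month so detections are datable to it.
All temporal logic is whole calendar months — there are no day-level
compositing cut-offs — and nodata travels as an explicit boolean
validity mask, never as a sentinel value inside arithmetic.

A pixel clouded out of either composite is *unobserved* for that month:
it cannot be classified, is excluded from denominators, and may surface
later as a new detection if the scar is still visible — the behaviour
the repeat filter exists for. The repeat filter flags pixels
re-detected within a three-month lookback as `burned_repeat`, so the
monthly `burned_new` layers partition each scar's first appearance: the
union of `burned_new` over a year is the annual extent, and summing
`burned_new` areas never double-counts within any lookback window. The
lookback crosses year boundaries (history is a running state).

*Burned extent* counts each pixel once; *cumulative burned area* counts
each pixel once per distinct burn, i.e. Σ_k k·(area burned k times).
Extent = once + multiple holds by construction, exactly.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size | 20 | m | native resolution of the 20-m Sentinel-2 bands |
| pre-fire window | 3 | months | cloud robustness vs vegetation stability |
| minimum mapping unit | 6.25 (156 px) | ha | Indonesian official minimum burn-scar size |
| NBR floor | −0.1 (strict >) | — | still-vegetated pixels are unlikely burns |
| hotspot buffer | 100 | m | scar buffered, not the point; sensor uncertainty is *not* added |
| hotspot window | 4 | months | reference month + three preceding (a 3-month variant is a config option) |
| repeat lookback | 3 | months | scar visibility persistence |
| forest | 100 trees, √p splits, leaf 1 | — | common defaults for the platform class of RF |
| connectivity | 8 | — | scars are diagonal-contiguous; 4 available |

NBR uses B8A/B12, both native 20 m, avoiding resampling artefacts; the
B8/B12 pair is a config option. 10-m bands are aggregated to 20 m by
the valid-child block mean (unbiased, simple). Median of an even count
is the mean of the two central values. The "3×3 circular" closing
element is implemented as the cross/plus element — the only 3×3
structuring element distinguishable from the square. The filter order
is minimum-mapping-unit → morphology → NBR floor → hotspot mask →
repeat mask; the size filter is not re-run after later stages. Repeat
masking is pixel-level, not patch-level.

## The synthetic generator

The generator produces the statistical structure the chain assumes, not
radiometric realism. Land cover is a mixture of per-class band-mean
endmembers with iid Gaussian noise (sd 0.012 reflectance): vegetation
(NBR +0.5), fresh burn (−0.375), wet soil (−0.24 — burn-like in NBR but
2–3× brighter in the visible bands, so a classifier with all 22
features can separate it while an NBR threshold cannot). Burned pixels
relax back to vegetation as a blend with weight 0.5^(t/h), h = 3 months
by default; the burn takes effect on the first day of its month.
Reflectance is stored as uint16 DNs scaled by 10⁴, the Sentinel-2 L2A
convention. Observations arrive every `revisit_days` (default 5) on
days 1–28 of each month so every month has the same cadence.

Scars are grown by random neighbour accretion from a seed pixel and
then regularised (morphological close/open, largest component kept):
real burn scars are compact at 20 m, and an unregularised accretion
cluster has a 1-pixel-deep ragged fringe that no mapping chain — and no
visual interpreter — would treat as part of the scar. Events are placed
without overlap (a 3-pixel separation keeps them distinct components);
repeated burning is modelled explicitly by re-burning an earlier
footprint in a later month (`reburn_events`). Clouds are blobby
(thresholded smoothed noise) with exact per-observation coverage.
Hotspots are drawn inside each footprint during its burn month, 
displaced by at most half the sensor resolution (375 m VIIRS / 1 km
MODIS — the point is the centroid of the sensor pixel containing the
fire), at ~2 points per burned km²; confuser patches are placed far
enough from events that no hotspot can fall near them, and never emit
hotspots themselves.

What passing tests therefore show: the chain's logic — compositing
windows, filter contracts, accounting identities, estimator calibration
— is correct, and the end-to-end system recovers known truth under
moderate cloud and full hotspot coverage. What they do not show:
performance on real imagery with mixed pixels, sub-scar heterogeneity,
haze, canopy-obscured burns, re-greening savanna, or incomplete hotspot
coverage — the omission-error regime the real product documents.

## Validation machinery

Accuracy estimators are stratified area-weighted good-practice
estimators written as ratios of stratified totals with linearised
variances; when strata coincide with the map classes they reduce to the
familiar error-matrix formulas, and the general form also covers
cross-strata produced by rebalancing a sample between a monthly and an
annual layer. CIs are normal-approximation 95% intervals, clipped to
[0, 100]. The calibration test uses 300/800 points per stratum: large
enough that the large-sample interval is valid (at very small per-cell
expected counts the normal approximation under-covers, a property of
the interval, not of the estimator). Commission ≡ 100 − UA and
omission ≡ 100 − PA identically.

The rebalancing operation takes explicit per-cross-stratum targets
(e.g. add to 20, reduce to 4, reduce to 150) rather than deriving them:
target arithmetic is a study-design input, not something the code can
reconstruct. The "annual" map validated against is the union of the
twelve monthly `burned_new` layers.

Temporal confusion reports exact ratios (exact-month agreement and the
rate of >1-month mismatches) over sites with both a detected and an
interpreted burn month. Size-distribution tests run Kruskal–Wallis,
two-sample Kolmogorov–Smirnov and Mann–Whitney U on patch areas at or
above each threshold; rows where either sample is empty are marked not
applicable rather than tested.

## Numerical and design choices

- Hotspot-to-scar distance is Euclidean from the point to the nearest
  burned-pixel centre (KD-tree), equivalent to buffering the scar by a
  100-m disc.
- The classifier decision is the forest's vote; with fully grown trees
  this equals the hard per-tree majority away from exact ties.
- Training spectra are extracted from the composite pair of the month
  each point was labelled in; class imbalance is left as sampled (no
  reweighting).
- Problem sizes: unit tests run on 96×96 scenes; the end-to-end
  recovery check uses a 512×512, 12-month scene (ten events, 30%
  cloud), which one CPU core processes in about a minute — composites
  are memoised so training and monthly runs share them.
- Degenerate inputs: NIR+SWIR = 0 yields an invalid pixel, not NaN;
  empty compositing windows raise a named error; a fully invalid
  feature stack predicts all-invalid; an empty hotspot table removes
  every candidate patch (no evidence of fire, no detection).

## Known limitations

- Single-CRS, in-memory processing: no reprojection, tiling or
  country-scale scheduling.
- GeoTIFF I/O writes/reads the standard georeferencing tags directly;
  exotic GeoTIFF variants produced by other tools may not round-trip.
- Hotspot confidence levels, day/night flags and per-sensor treatment
  beyond the resolution figure are out of scope.
- The generator's clouds are independent between observations, so
  multi-month obscuration (the dominant real omission mode) is rarer
  than in reality at the same cloud fraction.
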