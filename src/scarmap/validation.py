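"""Map-accuracy assessment, temporal confusion and burn-size analysis.

Spatial accuracy follows the stratified good-practice estimators: the
error matrix is expressed in area-weighted proportions (stratum weight =
stratum area / total area), and overall, user's and producer's
accuracies are stratified means / ratio estimators with normal-
approximation 95% confidence intervals. When strata coincide with the
map classes these reduce to the familiar formulas; the general form also
covers cross-strata from a rebalanced sample. Commission error is
100 - UA and omission error 100 - PA by definition.

Temporal accuracy compares each reference site's detected month with its
interpreted burn month; size analysis extracts connected burn patches
and compares two size distributions with Kruskal-Wallis,
Kolmogorov-Smirnov and Mann-Whitney U tests above a set of patch-size
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import MonthKey, pixel_area_ha
from .filters import BurnMap, _structure

CLASSES = ("burned", "unburned")
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Sample rebalancing between a monthly and an annual layer
# ---------------------------------------------------------------------------

def cross_stratum(monthly_burned: np.ndarray, annual_burned: np.ndarray) -> np.ndarray:
    """Per-pixel cross-stratum ids "monthlyclass_annualclass"."""
    m = np.where(monthly_burned.astype(bool), "burned", "unburned")
    a = np.where(annual_burned.astype(bool), "burned", "unburned")
    return np.char.add(np.char.add(m, "_"), a)


def rebalance_sample(
    points: pd.DataFrame,
    monthly_burned: np.ndarray,
    annual_burned: np.ndarray,
    targets: dict[str, int],
    seed: int,
    true_burned: np.ndarray | None = None,
) -> pd.DataFrame:
    """Adjust per-cross-stratum point counts to explicit targets.

    Strata are the cross of monthly and annual map class at each point's
    pixel. Over-represented strata are uniformly subsampled; under-
    represented strata gain points sampled uniformly within the stratum
    region (labelled from ``true_burned`` when provided). Strata absent
    from ``targets`` pass through unchanged. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    strata_grid = cross_stratum(monthly_burned, annual_burned)
    pts = points.copy().reset_index(drop=True)
    pts["stratum"] = strata_grid[pts["row"].to_numpy(), pts["col"].to_numpy()]

    kept: list[pd.DataFrame] = []
    for stratum, group in pts.groupby("stratum", sort=True):
        target = targets.get(str(stratum))
        if target is None or len(group) == target:
            kept.append(group)
        elif len(group) > target:
            idx = rng.choice(len(group), size=target, replace=False)
            kept.append(group.iloc[np.sort(idx)])
        else:
            kept.append(group)
    out = pd.concat(kept, ignore_index=True) if kept else pts.iloc[0:0]

    # additions for strata below target (including strata with no points yet)
    counts = out["stratum"].value_counts()
    additions: list[dict] = []
    for stratum, target in sorted(targets.items()):
        have = int(counts.get(stratum, 0))
        if have >= target:
            continue
        rows, cols = np.nonzero(strata_grid == stratum)
        if len(rows) < target - have:
            raise ValueError(
                f"stratum {stratum!r} has {len(rows)} pixels, cannot reach {target}"
            )
        taken = set(
            zip(out.loc[out["stratum"] == stratum, "row"], out.loc[out["stratum"] == stratum, "col"])
        )
        order = rng.permutation(len(rows))
        for i in order:
            if have >= target:
                break
            r, c = int(rows[i]), int(cols[i])
            if (r, c) in taken:
                continue
            taken.add((r, c))
            map_cls = "burned" if monthly_burned.astype(bool)[r, c] else "unburned"
            if true_burned is not None:
                true_cls = "burned" if true_burned.astype(bool)[r, c] else "unburned"
            else:
                true_cls = ""
            additions.append(
                {"row": r, "col": c, "map_class": map_cls, "true_class": true_cls,
                 "stratum": stratum}
            )
            have += 1
    if additions:
        out = pd.concat([out, pd.DataFrame(additions)], ignore_index=True)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stratified accuracy assessment
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Error matrix and accuracies with 95% confidence intervals (percent)."""

    counts: pd.DataFrame  # sample counts, map class rows x true class cols
    proportions: pd.DataFrame  # area-weighted proportions, sum to 1
    oa: float
    oa_ci: tuple[float, float]
    ua: dict[str, float]
    ua_ci: dict[str, tuple[float, float]]
    pa: dict[str, float]
    pa_ci: dict[str, tuple[float, float]]
    strata_weights: dict[str, float] = field(default_factory=dict)

    @property
    def commission(self) -> dict[str, float]:
        return {c: 100.0 - v for c, v in self.ua.items()}

    @property
    def omission(self) -> dict[str, float]:
        return {c: 100.0 - v for c, v in self.pa.items()}

    def to_text(self) -> str:
        lines = ["Stratified accuracy assessment", "", "Sample counts (map x true):",
                 self.counts.to_string(), "",
                 f"OA (%): {self.oa:.1f} ({self.oa_ci[0]:.1f}, {self.oa_ci[1]:.1f})"]
        for c in self.ua:
            lines.append(
                f"UA {c} (%): {self.ua[c]:.1f} ({self.ua_ci[c][0]:.1f}, {self.ua_ci[c][1]:.1f})"
                f"   commission {self.commission[c]:.1f}"
            )
        for c in self.pa:
            lines.append(
                f"PA {c} (%): {self.pa[c]:.1f} ({self.pa_ci[c][0]:.1f}, {self.pa_ci[c][1]:.1f})"
                f"   omission {self.omission[c]:.1f}"
            )
        return "\n".join(lines)


def _stratified_mean(values: dict[str, np.ndarray], weights: dict[str, float]) -> tuple[float, float]:
    """Stratified mean and its variance for per-stratum indicator arrays."""
    est = 0.0
    var = 0.0
    for h, z in values.items():
        n_h = len(z)
        w = weights[h]
        est += w * z.mean()
        if n_h > 1:
            var += w**2 * z.var(ddof=1) / n_h
    return est, var


def _stratified_ratio(
    ys: dict[str, np.ndarray], xs: dict[str, np.ndarray], weights: dict[str, float]
) -> tuple[float, float]:
    """Ratio of stratified totals Y/X with its linearised variance."""
    y_est = sum(weights[h] * ys[h].mean() for h in ys)
    x_est = sum(weights[h] * xs[h].mean() for h in xs)
    if x_est == 0:
        return float("nan"), float("nan")
    r = y_est / x_est
    var = 0.0
    for h in ys:
        n_h = len(ys[h])
        if n_h <= 1:
            continue
        y, x = ys[h], xs[h]
        s_yy = y.var(ddof=1)
        s_xx = x.var(ddof=1)
        s_yx = np.cov(y, x, ddof=1)[0, 1]
        var += weights[h] ** 2 * (s_yy + r**2 * s_xx - 2 * r * s_yx) / n_h
    return r, var / x_est**2


def accuracy_assessment(
    points: pd.DataFrame, strata_areas: dict[str, float]
) -> AccuracyReport:
    """Stratified area-weighted accuracy from reference points.

    ``points`` needs map_class, true_class and stratum columns;
    ``strata_areas`` gives each stratum's pixel count (or area — only
    ratios matter). Every stratum with nonzero area must be sampled.
    """
    total = float(sum(strata_areas.values()))
    if total <= 0:
        raise ValueError("strata areas must be positive")
    weights = {h: a / total for h, a in strata_areas.items()}
    grouped = {str(h): g for h, g in points.groupby("stratum")}
    for h, a in strata_areas.items():
        if a > 0 and h not in grouped:
            raise ValueError(f"stratum {h!r} has area but no sample points")
    for h in grouped:
        if h not in strata_areas:
            raise ValueError(f"sampled stratum {h!r} has no declared area")

    def indicators(fn) -> dict[str, np.ndarray]:
        return {h: fn(g).to_numpy(dtype=float) for h, g in grouped.items()}

    counts = pd.crosstab(points["map_class"], points["true_class"]).reindex(
        index=CLASSES, columns=CLASSES, fill_value=0
    )
    prop = pd.DataFrame(0.0, index=CLASSES, columns=CLASSES)
    for i in CLASSES:
        for j in CLASSES:
            est, _ = _stratified_mean(
                indicators(lambda g, i=i, j=j: (g["map_class"] == i) & (g["true_class"] == j)),
                weights,
            )
            prop.loc[i, j] = est

    oa_est, oa_var = _stratified_mean(
        indicators(lambda g: g["map_class"] == g["true_class"]), weights
    )
    ua, ua_ci, pa, pa_ci = {}, {}, {}, {}
    for c in CLASSES:
        r, v = _stratified_ratio(
            indicators(lambda g, c=c: (g["map_class"] == c) & (g["true_class"] == c)),
            indicators(lambda g, c=c: g["map_class"] == c),
            weights,
        )
        ua[c] = 100.0 * r
        half = 100.0 * _Z95 * np.sqrt(max(v, 0.0))
        ua_ci[c] = (max(0.0, ua[c] - half), min(100.0, ua[c] + half))
        r, v = _stratified_ratio(
            indicators(lambda g, c=c: (g["map_class"] == c) & (g["true_class"] == c)),
            indicators(lambda g, c=c: g["true_class"] == c),
            weights,
        )
        pa[c] = 100.0 * r
        half = 100.0 * _Z95 * np.sqrt(max(v, 0.0))
        pa_ci[c] = (max(0.0, pa[c] - half), min(100.0, pa[c] + half))

    oa = 100.0 * oa_est
    half = 100.0 * _Z95 * np.sqrt(max(oa_var, 0.0))
    return AccuracyReport(
        counts=counts,
        proportions=prop,
        oa=oa,
        oa_ci=(max(0.0, oa - half), min(100.0, oa + half)),
        ua=ua,
        ua_ci=ua_ci,
        pa=pa,
        pa_ci=pa_ci,
        strata_weights=weights,
    )


# ---------------------------------------------------------------------------
# Temporal confusion
# ---------------------------------------------------------------------------

@dataclass
class TemporalConfusion:
    matrix: pd.DataFrame  # detected month rows x true month cols, counts
    n_sites: int
    exact_agreement: float  # fraction in [0, 1]
    over_one_month: float  # fraction with |lag| > 1 month

    @property
    def exact_agreement_pct(self) -> float:
        return 100.0 * self.exact_agreement


def temporal_confusion(points: pd.DataFrame) -> TemporalConfusion:
    """Detected-vs-interpreted burn month confusion for burned sites.

    Uses rows where both ``detected_month`` and ``true_burn_month`` are
    present ("YYYY-MM"); reports the exact ratios.
    """
    df = points.copy()
    df = df[(df["detected_month"].astype(str) != "") & (df["true_burn_month"].astype(str) != "")]
    if len(df) == 0:
        raise ValueError("no points with both detected and true burn months")
    det = df["detected_month"].astype(str)
    true = df["true_burn_month"].astype(str)
    matrix = pd.crosstab(det, true)
    lag = np.array(
        [MonthKey.parse(d).ordinal - MonthKey.parse(t).ordinal for d, t in zip(det, true)]
    )
    return TemporalConfusion(
        matrix=matrix,
        n_sites=len(df),
        exact_agreement=float((lag == 0).mean()),
        over_one_month=float((np.abs(lag) > 1).mean()),
    )


# ---------------------------------------------------------------------------
# Burn-size distributions
# ---------------------------------------------------------------------------

@dataclass
class SizeDistribution:
    areas_ha: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.areas_ha = np.asarray(self.areas_ha, dtype=float)
        if len(self.areas_ha) and (self.areas_ha <= 0).any():
            raise ValueError("patch areas must be positive")

    @property
    def total_ha(self) -> float:
        return float(self.areas_ha.sum())


def patch_sizes(
    maps: list[BurnMap], connectivity: int = 8, label: str = ""
) -> SizeDistribution:
    """Connected burned_new patch areas (ha) pooled over monthly maps."""
    areas: list[float] = []
    for m in maps:
        px_ha = pixel_area_ha(m.grid)
        labels, n = ndimage.label(m.burned_new_mask(), structure=_structure(connectivity))
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            areas.extend((sizes * px_ha).tolist())
    return SizeDistribution(np.asarray(areas), label=label)


def size_distribution_tests(
    dist_a: SizeDistribution,
    dist_b: SizeDistribution,
    thresholds: tuple[float, ...] = (25.0, 100.0, 1000.0, 5000.0),
) -> pd.DataFrame:
    """Distribution tests on patches at or above each size threshold.

    Per threshold: Kruskal-Wallis H, Kolmogorov-Smirnov and
    Mann-Whitney U statistics and p-values; a row where either sample is
    empty is marked not applicable (NaN).
    """
    rows = []
    for thr in thresholds:
        a = dist_a.areas_ha[dist_a.areas_ha >= thr]
        b = dist_b.areas_ha[dist_b.areas_ha >= thr]
        row: dict[str, float] = {"threshold_ha": thr, "n_a": len(a), "n_b": len(b)}
        if len(a) == 0 or len(b) == 0:
            row.update({k: np.nan for k in
                        ("kw_h", "kw_p", "ks_stat", "ks_p", "mwu_u", "mwu_p")})
        else:
            kw = stats.kruskal(a, b)
            ks = stats.ks_2samp(a, b)
            mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
            row.update(
                kw_h=kw.statistic, kw_p=kw.pvalue,
                ks_stat=ks.statistic, ks_p=ks.pvalue,
                mwu_u=mwu.statistic, mwu_p=mwu.pvalue,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_curve(dist: SizeDistribution) -> pd.DataFrame:
    """Cumulative burned area as a function of patch size.

    Sizes ascending; the cumulative column is non-decreasing and ends at
    the distribution's total area.
    """
    if len(dist.areas_ha) == 0:
        raise ValueError("empty size distribution")
    sizes = np.sort(dist.areas_ha)
    return pd.DataFrame({"size_ha": sizes, "cumulative_ha": np.cumsum(sizes)})


def event_detection_months(maps: list[BurnMap], events) -> dict[int, str]:
    """First month in which at least half of each truth event's footprint
    is detected burned_new ("" if the event is never detected)."""
    ordered = sorted(maps, key=lambda m: m.month.ordinal)
    out: dict[int, str] = {}
    for ev in events:
        detected = ""
        for m in ordered:
            frac = m.burned_new_mask()[ev.rows, ev.cols].mean()
            if frac >= 0.5:
                detected = str(m.month)
                break
        out[ev.event_id] = detected
    return out
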