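"""22-feature stack assembly and burned/unburned random-forest classification.

Features are the ten Sentinel-2 bands plus NBR of the pre-fire composite
and the same eleven of the post-fire composite — 22 in total, in a fixed
order (pre bands, pre NBR, post bands, post NBR). Class labels follow
the chain's convention: 0 = burned, 1 = unburned; pixels invalid in
either composite are excluded and coded 255 in the prediction grid.

The forest itself is scikit-learn's RandomForestClassifier with common
defaults (100 trees, sqrt-features splits, minimum leaf 1) and a fixed
seed, so the whole pipeline is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grid import BAND_SET, GridSpec, MonthKey, require_same_grid
from .compositing import Composite

CLASS_BURNED = 0
CLASS_UNBURNED = 1
CLASS_INVALID = 255

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"pre_{b}" for b in BAND_SET] + ["pre_NBR"]
    + [f"post_{b}" for b in BAND_SET] + ["post_NBR"]
)

_MODEL_FORMAT_VERSION = 1


@dataclass
class RFConfig:
    n_trees: int = 100
    features_per_split: str | int = "sqrt"
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FeatureStack:
    """The 22 named feature grids for one reference month."""

    grid: GridSpec
    features: dict[str, np.ndarray]
    valid: np.ndarray  # valid in BOTH composites

    def __post_init__(self) -> None:
        if tuple(self.features) != FEATURE_NAMES:
            raise ValueError(
                f"feature stack must contain exactly the {len(FEATURE_NAMES)} "
                "canonical features in order"
            )

    def matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, 22) feature matrix at the given pixels."""
        return np.column_stack([self.features[f][rows, cols] for f in FEATURE_NAMES])


@dataclass
class BurnClassifier:
    """Trained forest plus the feature-order manifest it was fitted with."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: RFConfig = field(default_factory=RFConfig)

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "feature_names": list(self.feature_names),
                "config": self.config,
                "forest": self.forest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "BurnClassifier":
        payload = joblib.load(path)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        return cls(
            forest=payload["forest"],
            feature_names=tuple(payload["feature_names"]),
            config=payload["config"],
        )


def assemble_features(pre: Composite, post: Composite) -> FeatureStack:
    """Stack the pre and post composites into the canonical 22 features.

    A pixel is valid iff it is valid in both composites: a pixel clouded
    out of either window cannot be classified that month.
    """
    require_same_grid(pre.grid, post.grid, "assemble_features")
    features: dict[str, np.ndarray] = {}
    for b in BAND_SET:
        features[f"pre_{b}"] = pre.bands[b]
    features["pre_NBR"] = pre.nbr
    for b in BAND_SET:
        features[f"post_{b}"] = post.bands[b]
    features["post_NBR"] = post.nbr
    valid = pre.valid & post.valid
    return FeatureStack(grid=pre.grid, features=features, valid=valid)


def extract_training_matrix(
    stacks_by_month: dict[str, FeatureStack], points: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels for training points.

    Each point's spectra come from the composite pair of the month it
    was labelled in (``points['month']``, "YYYY-MM"). Points falling on
    pixels invalid in that month's stack are dropped.
    """
    xs: list[np.ndarray] = []
    ys: list[int] = []
    for month, group in points.groupby("month"):
        key = str(MonthKey.parse(str(month)))
        if key not in stacks_by_month:
            raise KeyError(f"no feature stack for training month {key}")
        fs = stacks_by_month[key]
        rows = group["row"].to_numpy()
        cols = group["col"].to_numpy()
        ok = fs.valid[rows, cols]
        if ok.any():
            xs.append(fs.matrix(rows[ok], cols[ok]))
            ys.extend(group["label"].to_numpy()[ok].tolist())
    if not xs:
        raise ValueError("no training point falls on a valid pixel")
    return np.vstack(xs), np.asarray(ys, dtype=int)


def train(
    stacks_by_month: dict[str, FeatureStack],
    points: pd.DataFrame,
    config: RFConfig | None = None,
) -> BurnClassifier:
    """Fit the burned/unburned forest on labelled points.

    Requires at least one valid point per class; no class reweighting is
    applied (the chain trains on its raw 852/1491-style point sets).
    Deterministic for a fixed ``config.seed``.
    """
    config = config or RFConfig()
    X, y = extract_training_matrix(stacks_by_month, points)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training set contains a single class: {classes.tolist()}")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return BurnClassifier(forest=forest, feature_names=FEATURE_NAMES, config=config)


def predict(model: BurnClassifier, stack: FeatureStack) -> np.ndarray:
    """Classify every valid pixel; returns uint8 grid of {0, 1, 255}.

    0 = burned, 1 = unburned, 255 = invalid (unobserved). The decision is
    the forest's majority vote over trees.
    """
    if tuple(stack.features) != model.feature_names:
        raise ValueError("feature order mismatch between model and stack")
    out = np.full(stack.grid.shape, CLASS_INVALID, dtype=np.uint8)
    rows, cols = np.nonzero(stack.valid)
    if len(rows) == 0:
        return out
    X = stack.matrix(rows, cols)
    out[rows, cols] = model.forest.predict(X).astype(np.uint8)
    return out
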