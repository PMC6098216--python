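"""Voxelwise SVM segmentation inside the ROI.

Segmentation is a binary voxel classification with a Gaussian-kernel
support vector machine, trained on a uniformly random subset of ROI voxels
from the training images and applied to all ROI voxels of the test image.
The left and right structures get separate classifiers, since their
appearance differs slightly.  Hyperparameters (slack C, kernel width gamma)
can be tuned by leave-one-group-out cross validation with held-out
foreground Dice as the selection criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .atlas import ROIMask
from .features import FeatureTable, NormalizationParams

__all__ = [
    "TrainingSet",
    "TrainedSegmenter",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "sample_training_voxels",
    "tune_hyperparameters",
    "train_segmenter",
    "predict_segmentation",
]

DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 8, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**p for p in range(-9, 4, 2))


@dataclass
class TrainingSet:
    """ROI voxel samples with binary labels for one hemisphere."""

    features: FeatureTable
    labels: np.ndarray
    hemisphere: str = ""
    groups: np.ndarray | None = None  # image-or-site id per row, for CV

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.shape[0] != self.features.n_samples:
            raise ValueError("label count does not match feature rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.labels.shape[0]:
                raise ValueError("group count does not match rows")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]


@dataclass
class TrainedSegmenter:
    """One fitted Gaussian-kernel SVM per hemisphere plus provenance."""

    model_left: SVC
    model_right: SVC
    feature_names: list[str]
    C: float
    gamma: float
    normalization: NormalizationParams | None = None
    metadata: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        """Serialize the segmenter (both models + provenance) to one file."""
        import pickle

        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path: str) -> "TrainedSegmenter":
        import pickle

        with open(path, "rb") as f:
            obj = pickle.load(f)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a TrainedSegmenter")
        return obj


def sample_training_voxels(train: TrainingSet, n: int = 10000, seed: int = 0) -> TrainingSet:
    """Uniform random subset of n rows without replacement, seeded.

    If the pool holds fewer than n rows the whole pool is returned with a
    warning.
    """
    if train.n_samples == 0:
        raise ValueError("empty training pool")
    if n >= train.n_samples:
        if n > train.n_samples:
            warnings.warn(
                f"requested {n} samples but pool holds {train.n_samples}; taking all",
                stacklevel=2,
            )
        return train
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(train.n_samples, size=n, replace=False))
    ft = FeatureTable(
        train.features.values[pick],
        train.features.voxel_index[pick],
        train.features.feature_names,
        train.features.scanner_id,
    )
    return TrainingSet(
        ft,
        train.labels[pick],
        train.hemisphere,
        None if train.groups is None else train.groups[pick],
    )


def _foreground_dice(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    denom = int(np.sum(y_true == 1)) + int(np.sum(y_pred == 1))
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def _fit_svc(x: np.ndarray, y: np.ndarray, C: float, gamma: float) -> SVC:
    clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=256)
    clf.fit(x, y)
    return clf


def tune_hyperparameters(
    train: TrainingSet,
    groups: np.ndarray | None = None,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
) -> tuple[float, float]:
    """Grid search (C, gamma) by leave-one-group-out CV on foreground Dice.

    Groups are image or site ids so the search optimizes robustness to
    between-image differences.  Ties break toward smallest C, then smallest
    gamma.  Raises if only one group is present (use per-image grouping).
    """
    if groups is None:
        groups = train.groups
    if groups is None:
        raise ValueError("groups required for cross validation")
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError(
            "only one group present; use leave-one-image-out grouping (one group per image)"
        )
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    x, y = train.features.values, train.labels
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for C, gamma in itertools.product(sorted(C_grid), sorted(gamma_grid)):
        scores = []
        for g in uniq:
            held = groups == g
            if y[~held].min() == y[~held].max():
                continue  # single-class fold; skip
            clf = _fit_svc(x[~held], y[~held], C, gamma)
            scores.append(_foreground_dice(y[held], clf.predict(x[held])))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score + 1e-12:
            best_score, best = score, (C, gamma)
    if best is None:
        raise ValueError("cross validation produced no valid folds")
    return best


def train_segmenter(
    train_left: TrainingSet,
    train_right: TrainingSet,
    C: float,
    gamma: float,
    normalization: NormalizationParams | None = None,
) -> TrainedSegmenter:
    """Fit the per-hemisphere Gaussian-kernel SVMs."""
    for ts, side in ((train_left, "left"), (train_right, "right")):
        if np.unique(ts.labels).size < 2:
            raise ValueError(f"{side} training set contains a single class")
    if train_left.features.feature_names != train_right.features.feature_names:
        raise ValueError("left/right feature names differ")
    ml = _fit_svc(train_left.features.values, train_left.labels, C, gamma)
    mr = _fit_svc(train_right.features.values, train_right.labels, C, gamma)
    meta = {
        "n_left": train_left.n_samples,
        "n_right": train_right.n_samples,
        "hemisphere_left": train_left.hemisphere or "left",
        "hemisphere_right": train_right.hemisphere or "right",
    }
    return TrainedSegmenter(
        ml, mr, list(train_left.features.feature_names), C, gamma, normalization, meta
    )


def _decision_volume(model: SVC, names: list[str], table, roi: ROIMask, grid_shape) -> np.ndarray:
    """Decision values on the ROI voxels covered by the table; -inf elsewhere."""
    dec = np.full(grid_shape, -np.inf)
    if table is None:
        return dec
    if set(table.feature_names) != set(names):
        raise ValueError(
            f"feature columns differ: segmenter {names}, test {table.feature_names}"
        )
    sub = table.select(names)
    in_roi = roi.data[tuple(sub.voxel_index.T)]
    if in_roi.any():
        ijk = sub.voxel_index[in_roi]
        dec[tuple(ijk.T)] = model.decision_function(sub.values[in_roi])
    return dec


def predict_segmentation(
    segmenter: TrainedSegmenter,
    test_features,
    roi_left: ROIMask,
    roi_right: ROIMask,
    grid_shape,
) -> np.ndarray:
    """Segment a test image: labels 0 (background), 1 (left), 2 (right).

    ``test_features`` is either a single FeatureTable covering both ROIs or
    a (left, right) pair of tables — the latter allows the atlas-prior
    column to carry each hemisphere's own prior.  Voxels outside both ROIs
    are background.  Inside each ROI the hemisphere's classifier decides;
    where the ROIs overlap, the classifier with the larger decision value
    wins.  Feature columns are matched to the training columns by name.
    """
    if isinstance(test_features, FeatureTable) or test_features is None:
        feats_l = feats_r = test_features
    else:
        feats_l, feats_r = test_features
    names = segmenter.feature_names
    dec_l = _decision_volume(segmenter.model_left, names, feats_l, roi_left, grid_shape)
    dec_r = _decision_volume(segmenter.model_right, names, feats_r, roi_right, grid_shape)

    out = np.zeros(grid_shape, dtype=np.int16)
    with np.errstate(invalid="ignore"):
        left_fg = (dec_l >= 0) & ((dec_l >= dec_r) | (dec_r < 0))
        right_fg = (dec_r >= 0) & ~left_fg
    out[left_fg] = 1
    out[right_fg] = 2
    return out
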