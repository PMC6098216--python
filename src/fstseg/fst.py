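"""Feature-space transformation (FST): transfer learning from rescan pairs.

Supervised voxel classifiers degrade when training and test images come
from different scanners, because the feature distributions differ.  The FST
learns a mapping f_{s->t} from the source scanner's feature space to the
target scanner's from *unlabeled* images of subjects scanned with both
protocols (source-target pairs).  After upstream alignment, every source
voxel z_i^s has a corresponding target voxel z_l^t; these correspondences
are observed transformations in feature space.  A training sample x is
transformed by finding its k nearest source samples (Euclidean distance in
the standardized feature space) and adding the *robust median* of their k
transformation vectors — the medoid, i.e. the member vector with minimal
total distance to the others — which guarantees that the applied
transformation is one actually observed in the data.

Defaults follow the method's reference configuration: k = 1 neighbor and
all available source-target pairs.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .features import FeatureTable, NormalizationParams
from .volume import BrainMask, ImageVolume

__all__ = [
    "CorrespondencePairs",
    "FSTModel",
    "build_correspondence",
    "robust_median",
    "fit_fst",
    "apply_fst",
    "apply_fst_intensity_only",
]

# Extra neighbors fetched from the k-d tree so that equal-distance ties at
# the k-boundary can be resolved deterministically (lowest row index wins).
_TIE_SLACK = 8


@dataclass
class CorrespondencePairs:
    """Matched unlabeled (source, target) feature rows from one rescan pair.

    Row ``m`` of ``source_rows`` and ``target_rows`` are feature vectors of
    corresponding voxels in the two acquisitions of the same subject.
    """

    source_rows: np.ndarray
    target_rows: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.source_rows = np.atleast_2d(np.asarray(self.source_rows, dtype=np.float64))
        self.target_rows = np.atleast_2d(np.asarray(self.target_rows, dtype=np.float64))
        if self.source_rows.shape[0] != self.target_rows.shape[0]:
            raise ValueError("source and target row counts differ")
        if self.source_rows.shape[0] < 1:
            raise ValueError("need at least one correspondence pair")
        if not (
            np.all(np.isfinite(self.source_rows)) and np.all(np.isfinite(self.target_rows))
        ):
            raise ValueError("correspondence rows contain non-finite values")

    @property
    def n_pairs(self) -> int:
        return self.source_rows.shape[0]


def build_correspondence(
    source_features: FeatureTable,
    target_features_on_source_grid: FeatureTable,
    joint_mask: BrainMask,
    subject_id: str = "",
) -> CorrespondencePairs:
    """Pair source and target feature rows voxel-by-voxel inside a joint mask.

    Both tables must cover every voxel of ``joint_mask`` (the intersection
    of the two brain masks).  Target features are expected to have been
    computed on the original target image and sampled onto the source grid
    by the upstream alignment.
    """
    sel = joint_mask.data
    if not sel.any():
        raise ValueError("empty mask intersection: no correspondence voxels")

    def rows_at_mask(table: FeatureTable, which: str) -> np.ndarray:
        flat = np.ravel_multi_index(tuple(table.voxel_index.T), sel.shape)
        order = np.full(sel.size, -1, dtype=np.intp)
        order[flat] = np.arange(table.n_samples)
        want = np.flatnonzero(sel.ravel())
        pos = order[want]
        if (pos < 0).any():
            raise ValueError(f"{which} table is missing voxels inside the joint mask")
        return table.values[pos]

    src = rows_at_mask(source_features, "source")
    tgt = rows_at_mask(target_features_on_source_grid, "target")
    return CorrespondencePairs(src, tgt, subject_id)


def robust_median(vectors) -> np.ndarray:
    """The medoid: the input vector with minimal total Euclidean distance
    to all inputs.  Always returns an element of the input set; ties are
    broken by lowest index."""
    v = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if v.shape[0] == 0:
        raise ValueError("robust_median of an empty set")
    if v.shape[0] == 1:
        return v[0].copy()
    d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=2)
    return v[int(np.argmin(d.sum(axis=1)))].copy()


@dataclass
class FSTModel:
    """The fitted feature-space transformation f_{s->t}.

    Stores the pooled correspondence rows over N subjects, the neighbor
    count k, and a k-d tree over the source rows for nearest-neighbor
    queries (verified against brute force in the test suite).
    """

    source_rows: np.ndarray
    target_rows: np.ndarray
    k: int
    n_subjects: int
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.source_rows = np.atleast_2d(np.asarray(self.source_rows, dtype=np.float64))
        self.target_rows = np.atleast_2d(np.asarray(self.target_rows, dtype=np.float64))
        m = self.source_rows.shape[0]
        if not 1 <= self.k <= m:
            raise ValueError(f"k must satisfy 1 <= k <= M={m}, got k={self.k}")
        if self.source_rows.shape != self.target_rows.shape:
            raise ValueError("source/target row shapes differ")
        self._tree = cKDTree(self.source_rows)

    @property
    def n_pairs(self) -> int:
        return self.source_rows.shape[0]

    @property
    def d(self) -> int:
        return self.source_rows.shape[1]

    def nearest_sources(self, queries: np.ndarray, k: int | None = None):
        """Indices of the k nearest stored source rows per query row.

        Equal-distance ties are broken by lowest row index in the pooled
        pair matrix, which makes results reproducible across runs and
        library versions.
        """
        k = self.k if k is None else k
        q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        kq = min(self.n_pairs, k + _TIE_SLACK)
        dist, idx = self._tree.query(q, k=kq)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        # stable re-sort by (distance, index) then truncate to k
        order = np.lexsort((idx, dist), axis=1)
        rows = np.arange(q.shape[0])[:, None]
        return idx[rows, order][:, :k]

    def save(self, path: str) -> None:
        """Serialize the model (pairs + k + N + metadata) to one archive."""
        buf = io.BytesIO()
        np.savez_compressed(buf, source_rows=self.source_rows, target_rows=self.target_rows)
        meta = {
            "k": self.k,
            "n_subjects": self.n_subjects,
            "feature_names": self.feature_names,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("pairs.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str) -> "FSTModel":
        with zipfile.ZipFile(path) as zf:
            with zf.open("pairs.npz") as f:
                arrs = np.load(io.BytesIO(f.read()))
                src, tgt = arrs["source_rows"], arrs["target_rows"]
            meta = json.loads(zf.read("meta.json"))
        return cls(src, tgt, meta["k"], meta["n_subjects"], meta["feature_names"])


def fit_fst(
    pair_blocks: list[CorrespondencePairs] | CorrespondencePairs,
    k: int = 1,
    feature_names: list[str] | None = None,
) -> FSTModel:
    """Pool correspondence pairs over subjects and build the search index."""
    if isinstance(pair_blocks, CorrespondencePairs):
        pair_blocks = [pair_blocks]
    if not pair_blocks:
        raise ValueError("no correspondence blocks given")
    d = pair_blocks[0].source_rows.shape[1]
    for b in pair_blocks:
        if b.source_rows.shape[1] != d or b.target_rows.shape[1] != d:
            raise ValueError("dimensionality mismatch across correspondence blocks")
    src = np.vstack([b.source_rows for b in pair_blocks])
    tgt = np.vstack([b.target_rows for b in pair_blocks])
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > src.shape[0]:
        raise ValueError(f"k={k} exceeds pooled pair count M={src.shape[0]}")
    return FSTModel(src, tgt, k, n_subjects=len(pair_blocks), feature_names=feature_names)


def _median_transformations(model: FSTModel, queries: np.ndarray) -> np.ndarray:
    """Robust-median transformation vector per query row (Eq. 4/5 core)."""
    nn = model.nearest_sources(queries)  # (n, k)
    vecs = model.target_rows[nn] - model.source_rows[nn]  # (n, k, d)
    k = vecs.shape[1]
    if k == 1:
        return vecs[:, 0, :]
    d = np.linalg.norm(vecs[:, :, None, :] - vecs[:, None, :, :], axis=3)
    pick = np.argmin(d.sum(axis=2), axis=1)
    return vecs[np.arange(vecs.shape[0]), pick]


def apply_fst(model: FSTModel, training: FeatureTable) -> FeatureTable:
    """Transform training samples into the target scanner's feature space.

    Each row x gets x + robust_median of the transformation vectors of its
    k nearest stored source rows.  Row order and voxel indices are
    preserved.  Requires the training features to live in the same
    (standardized) space as the model's source rows.
    """
    if training.d != model.d:
        raise ValueError(
            f"training dimensionality {training.d} does not match model d={model.d}; "
            "the FST adds observed transformation vectors and therefore needs a "
            "shared source/target feature space"
        )
    if model.feature_names is not None and training.feature_names != model.feature_names:
        raise ValueError(
            f"feature names differ: model {model.feature_names}, "
            f"table {training.feature_names}"
        )
    med = _median_transformations(model, training.values)
    return training.with_values(training.values + med)


def apply_fst_intensity_only(
    model: FSTModel,
    training: FeatureTable,
    source_image: ImageVolume,
    intensity_feature: str = "intensity",
) -> ImageVolume:
    """Transform only the intensity component, returning an intensity image.

    The neighbor search runs in the model's full feature space, but only the
    intensity component of each median transformation vector is applied.
    ``source_image`` must hold the same (standardized) intensity values the
    table's intensity column was built from; voxels not covered by the table
    keep their original values.  Downstream, appearance features are
    recomputed from the returned image.
    """
    if training.d != model.d:
        raise ValueError("training dimensionality does not match the model")
    col = training.feature_names.index(intensity_feature)
    med = _median_transformations(model, training.values)
    out = source_image.data.copy()
    ijk = tuple(training.voxel_index.T)
    out[ijk] = training.values[:, col] + med[:, col]
    return source_image.with_data(out)
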