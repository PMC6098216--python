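"""Intensity normalization and Gaussian scale-space appearance features.

The classifier operates on 10 rotationally invariant appearance features per
voxel: the raw intensity; the intensity after Gaussian smoothing at
sigma = 1, 2.2 and 5 mm; the gradient magnitude at the same three scales;
and the Laplacian at the same three scales.  Derivatives are expressed per
mm so the features are independent of the voxel grid.  Images are intensity
normalized by 4th-96th percentile range matching within the brain mask
before feature extraction, and features are standardized per scanner to
zero mean, unit variance so Euclidean distances in feature space weight all
features equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import BrainMask, ImageVolume

__all__ = [
    "FeatureTable",
    "NormalizationParams",
    "APPEARANCE_FEATURE_NAMES",
    "SIGMAS_MM",
    "range_match",
    "appearance_feature_volumes",
    "appearance_features",
    "zscore_fit",
    "zscore_apply",
]

#: Gaussian scales in mm used for the smoothed, gradient and Laplacian features.
SIGMAS_MM = (1.0, 2.2, 5.0)

#: Canonical feature order; stable across calls so tables from different
#: scanners are comparable column-by-column.
APPEARANCE_FEATURE_NAMES = (
    ["intensity"]
    + [f"smooth_{s:g}mm" for s in SIGMAS_MM]
    + [f"gradmag_{s:g}mm" for s in SIGMAS_MM]
    + [f"laplacian_{s:g}mm" for s in SIGMAS_MM]
)

#: Boundary rule for all Gaussian filtering (mirror padding avoids edge
#: darkening that would corrupt derivative features near the mask border).
_BOUNDARY_MODE = "reflect"

#: Kernel truncation radius in sigmas.  Generous so the second-derivative
#: kernels have near-zero DC response (~1e-8): a constant image then has
#: (numerically) zero gradient magnitude and Laplacian.
_TRUNCATE = 6.0


@dataclass
class FeatureTable:
    """Per-voxel feature vectors with voxel indices and a scanner tag.

    ``values`` is (n_samples, d); ``voxel_index`` is (n_samples, 3) integer
    grid coordinates, unique within a table.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    feature_names: list[str]
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.voxel_index = np.atleast_2d(np.asarray(self.voxel_index, dtype=np.intp))
        self.feature_names = list(self.feature_names)
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("values and voxel_index row counts differ")
        if self.voxel_index.shape[1] != 3:
            raise ValueError("voxel_index must have 3 columns")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: list[str]) -> "FeatureTable":
        """Column subset (by name), preserving row order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, idx], self.voxel_index, list(names), self.scanner_id)

    def with_values(self, values: np.ndarray, feature_names=None) -> "FeatureTable":
        return FeatureTable(
            values,
            self.voxel_index,
            self.feature_names if feature_names is None else feature_names,
            self.scanner_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.voxel_index, columns=["i", "j", "k"])
        for c, name in enumerate(self.feature_names):
            df[name] = self.values[:, c]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scanner_id: str = "") -> "FeatureTable":
        names = [c for c in df.columns if c not in ("i", "j", "k")]
        return cls(df[names].to_numpy(float), df[["i", "j", "k"]].to_numpy(int), names, scanner_id)


@dataclass
class NormalizationParams:
    """Per-feature location/scale for z-score standardization.

    ``scope`` records what the parameters were fit on (scanner id and mask
    kind) for provenance only.
    """

    location: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    scope: str = ""

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.feature_names = list(self.feature_names)
        if not (self.scale > 0).all():
            raise ValueError("all scales must be strictly positive")


def range_match(
    image: ImageVolume, mask: BrainMask, p_low: float = 4.0, p_high: float = 96.0
) -> ImageVolume:
    """Affine intensity normalization by percentile range matching.

    Maps the ``p_low`` percentile of in-mask intensities to 0.0 and the
    ``p_high`` percentile to 1.0; the affine map is applied to the whole
    volume.  Raises on (near-)constant input, where the percentiles coincide.
    """
    if not p_low < p_high:
        raise ValueError(f"p_low ({p_low}) must be < p_high ({p_high})")
    if image.grid_shape != mask.grid_shape:
        raise ValueError("image and mask grids do not match")
    in_mask = image.data[mask.data]
    lo, hi = np.percentile(in_mask, [p_low, p_high])
    if hi - lo <= 0:
        raise ValueError(
            f"degenerate image: {p_low}th and {p_high}th percentiles coincide ({lo})"
        )
    return image.with_data((image.data - lo) / (hi - lo))


def _sigma_voxels(sigma_mm: float, spacing) -> tuple[float, float, float]:
    return tuple(sigma_mm / s for s in spacing)


def appearance_feature_volumes(image: ImageVolume) -> dict[str, np.ndarray]:
    """The 10 appearance features as full volumes, keyed by canonical name.

    Gradient magnitudes are the L2 norm of the three first Gaussian
    derivatives and Laplacians the sum of the three second derivatives, both
    per mm (voxel-space derivatives divided by the per-axis spacing).
    """
    data, spacing = image.data, image.spacing
    out: dict[str, np.ndarray] = {"intensity": data.copy()}
    for s in SIGMAS_MM:
        sig = _sigma_voxels(s, spacing)
        out[f"smooth_{s:g}mm"] = ndimage.gaussian_filter(data, sig, mode=_BOUNDARY_MODE, truncate=_TRUNCATE)
        grad_sq = np.zeros_like(data)
        lap = np.zeros_like(data)
        for ax in range(3):
            order = [0, 0, 0]
            order[ax] = 1
            d1 = ndimage.gaussian_filter(data, sig, order=order, mode=_BOUNDARY_MODE, truncate=_TRUNCATE)
            grad_sq += (d1 / spacing[ax]) ** 2
            order[ax] = 2
            d2 = ndimage.gaussian_filter(data, sig, order=order, mode=_BOUNDARY_MODE, truncate=_TRUNCATE)
            lap += d2 / spacing[ax] ** 2
        out[f"gradmag_{s:g}mm"] = np.sqrt(grad_sq)
        out[f"laplacian_{s:g}mm"] = lap
    return out


def appearance_features(
    image: ImageVolume, mask: BrainMask | None = None, scanner_id: str = ""
) -> FeatureTable:
    """Per-voxel appearance features, one row per (mask) voxel.

    With ``mask=None`` every voxel of the grid contributes a row.
    """
    vols = appearance_feature_volumes(image)
    return feature_table_from_volumes(vols, APPEARANCE_FEATURE_NAMES, image.grid_shape, mask, scanner_id)


def feature_table_from_volumes(
    volumes: dict[str, np.ndarray],
    names,
    grid_shape,
    mask: BrainMask | None = None,
    scanner_id: str = "",
) -> FeatureTable:
    """Assemble a FeatureTable by sampling feature volumes at mask voxels."""
    if mask is None:
        sel = np.ones(grid_shape, dtype=bool)
    else:
        if mask.grid_shape != tuple(grid_shape):
            raise ValueError("mask grid does not match feature volumes")
        sel = mask.data
    idx = np.argwhere(sel)
    values = np.column_stack([volumes[n][sel] for n in names])
    return FeatureTable(values, idx, list(names), scanner_id)


def zscore_fit(
    tables: list[FeatureTable] | FeatureTable,
    restrict_to: np.ndarray | None = None,
    scope: str = "",
) -> NormalizationParams:
    """Pooled per-feature mean and population SD over the given tables.

    ``restrict_to`` optionally limits rows to voxels inside a boolean grid
    (e.g. an ROI); by default every row contributes.  A zero-variance
    feature is an error naming the feature.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    if not tables:
        raise ValueError("no tables given")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise ValueError("tables have differing feature names")
    rows = []
    for t in tables:
        v = t.values
        if restrict_to is not None:
            keep = restrict_to[tuple(t.voxel_index.T)]
            v = v[keep]
        rows.append(v)
    pooled = np.vstack(rows)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled samples to standardize")
    location = pooled.mean(axis=0)
    scale = pooled.std(axis=0)  # population convention (ddof=0)
    for name, s in zip(names, scale):
        if s <= 0:
            raise ValueError(f"feature '{name}' has zero variance; cannot standardize")
    return NormalizationParams(location, scale, names, scope)


def zscore_apply(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Standardize a table: value' = (value - location) / scale per feature."""
    if table.feature_names != params.feature_names:
        raise ValueError(
            f"feature sets differ: table has {table.feature_names}, "
            f"params were fit for {params.feature_names}"
        )
    return table.with_values((table.values - params.location) / params.scale)
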