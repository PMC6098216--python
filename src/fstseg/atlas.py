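"""Multi-atlas probability prior, ROI definition and the majority-vote baseline.

A set of registered binary atlases (training segmentations brought onto the
test grid) is averaged voxelwise into a prior probability of a voxel
belonging to the target structure.  The prior serves two roles: thresholded
at 10% it defines the region of interest (ROI) inside which all training
and classification happens, and it enters the classifier as an additional
feature.  Thresholded at 0.5 it is the classical majority-vote baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AtlasProbability",
    "ROIMask",
    "multi_atlas_probability",
    "define_roi",
    "majority_vote",
]


@dataclass
class AtlasProbability:
    """Voxelwise mean of registered binary atlases; values in [0, 1]."""

    data: np.ndarray
    n_atlases: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class ROIMask:
    """Region of interest: voxels whose atlas prior meets the threshold."""

    data: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def multi_atlas_probability(atlases, structure_label: int = 1) -> AtlasProbability:
    """Voxelwise mean of the indicator (atlas == structure_label).

    ``atlases`` are integer label volumes registered onto a common grid;
    the structure of interest is selected by its label so left and right
    structures get separate probability volumes.
    """
    atlases = list(atlases)
    if not atlases:
        raise ValueError("need at least one atlas")
    shape = np.asarray(atlases[0]).shape
    acc = np.zeros(shape, dtype=np.float64)
    for a in atlases:
        a = np.asarray(a)
        if a.shape != shape:
            raise ValueError(f"atlas grid {a.shape} does not match {shape}")
        acc += a == structure_label
    return AtlasProbability(acc / len(atlases), n_atlases=len(atlases))


def define_roi(prob: AtlasProbability, threshold: float = 0.10) -> ROIMask:
    """ROI = voxels with prior probability of at least ``threshold`` (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return ROIMask(prob.data >= threshold, threshold)


def majority_vote(prob: AtlasProbability) -> np.ndarray:
    """Majority-vote segmentation: prior >= 0.5 (ties count as foreground)."""
    return prob.data >= 0.5
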