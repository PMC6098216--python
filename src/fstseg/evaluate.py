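"""Segmentation evaluation: Dice overlap, volumes, Bland-Altman, signed-rank.

Per-subject performance is the Dice overlap against the manual labels,
averaged over the left and right structure.  Cross-scanner reproducibility
is assessed with Bland-Altman analysis of paired segmented volumes (each
structure contributes one point), and paired method differences are tested
with the Wilcoxon signed-rank test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "dice",
    "subject_mean_dice",
    "volume_mm3",
    "BlandAltmanResult",
    "bland_altman",
    "bland_altman_plot",
    "SignedRankResult",
    "paired_signed_rank",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def subject_mean_dice(left: float, right: float) -> float:
    """Per-subject score: arithmetic mean of the left and right Dice."""
    return 0.5 * (left + right)


def volume_mm3(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Segmented volume: voxel count times the voxel volume."""
    return float(np.asarray(mask).astype(bool).sum()) * float(np.prod(spacing))


@dataclass
class BlandAltmanResult:
    """Bias and limits of agreement of paired measurements."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    @property
    def sd(self) -> float:
        return (self.loa_high - self.bias) / 1.96


def bland_altman(vol_a, vol_b) -> BlandAltmanResult:
    """Bland-Altman analysis of matched measurement lists.

    bias = mean(a - b); limits of agreement = bias ± 1.96 · SD(a - b)
    (population SD); per-point (mean, difference) pairs for plotting.
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be matched 1D lists")
    if a.size == 0:
        raise ValueError("empty input")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std())  # population convention
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, (a + b) / 2.0, d)


def bland_altman_plot(result: BlandAltmanResult, path: str, title: str = "") -> None:
    """Write the Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=20)
    ax.axhline(result.bias, color="k", label=f"bias {result.bias:.1f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel("mean volume (mm$^3$)")
    ax.set_ylabel("volume difference (mm$^3$)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class SignedRankResult:
    statistic: float  # signed rank sum W+ - W-
    p_value: float
    significant: bool
    degenerate: bool = False


def paired_signed_rank(scores_a, scores_b, alpha: float = 0.05) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on per-subject differences.

    Zero differences are dropped.  Exact distribution for n <= 25, normal
    approximation with tie correction above.  All-zero differences are a
    degenerate case reported as non-significant with a flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be matched 1D lists")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return SignedRankResult(0.0, 1.0, False, degenerate=True)
    method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "approx"
    res = stats.wilcoxon(nz, method=method)
    ranks = stats.rankdata(np.abs(nz))
    signed = float(np.sum(ranks[nz > 0]) - np.sum(ranks[nz < 0]))
    p = float(res.pvalue)
    return SignedRankResult(signed, p, p < alpha)
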