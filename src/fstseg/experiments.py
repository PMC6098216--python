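"""Experiment orchestration: method comparison, k/N sweeps, rescan analysis.

Reproduces the method-comparison design on phantom studies: each test image
is segmented by classifiers trained on images from the other scanner, with
and without the feature-space transformation, and performance is reported
as per-subject Dice (left/right averaged) with signed-rank significance
against the best method.  Additional harnesses sweep the FST's k and N
parameters and measure cross-scanner volume reproducibility on rescan
pairs (Bland-Altman).

Compared methods
----------------
``atlas_mv``            majority vote: multi-atlas probability >= 0.5
``svm_atlas``           SVM on the atlas-probability feature alone
``svm``                 SVM on atlas + appearance features, no FST
``svm_fst``             SVM on atlas + FST-transformed appearance features
``svm_fst_intensity``   FST applied to the intensity only; other appearance
                        features recomputed from the transformed image

The appearance features of each scanner are standardized on that scanner's
rescan-pair images, so the two normalizations are estimated from the same
anatomies and differ only through the scanner effect; with two identical
scanner models the pipeline then reduces exactly to the plain SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasProbability, ROIMask, define_roi, majority_vote, multi_atlas_probability
from .classify import (
    TrainingSet,
    predict_segmentation,
    sample_training_voxels,
    train_segmenter,
    tune_hyperparameters,
)
from .evaluate import BlandAltmanResult, bland_altman, dice, paired_signed_rank, subject_mean_dice, volume_mm3
from .features import (
    APPEARANCE_FEATURE_NAMES,
    FeatureTable,
    NormalizationParams,
    appearance_feature_volumes,
    feature_table_from_volumes,
    range_match,
    zscore_apply,
    zscore_fit,
)
from .fst import FSTModel, apply_fst, apply_fst_intensity_only, build_correspondence, fit_fst
from .phantom import LEFT, RIGHT, PhantomStudy
from .volume import BrainMask, ImageVolume

__all__ = [
    "METHOD_NAMES",
    "MethodSpec",
    "ExperimentConfig",
    "ComparisonResult",
    "run_comparison",
    "sweep_k_n",
    "rescan_reproducibility",
]

METHOD_NAMES = ("atlas_mv", "svm_atlas", "svm", "svm_fst", "svm_fst_intensity")
_FST_METHODS = ("svm_fst", "svm_fst_intensity")

ATLAS_FEATURE = "atlas_prior"
_HEMIS = ((LEFT, "left"), (RIGHT, "right"))


@dataclass(frozen=True)
class MethodSpec:
    """One compared method and its FST options (k neighbors, N pairs)."""

    name: str
    k: int | None = None
    n_pairs_used: int | None = None

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method '{self.name}'; choose from {METHOD_NAMES}")
        if self.name not in _FST_METHODS and (self.k is not None or self.n_pairs_used is not None):
            raise ValueError(f"k / n_pairs_used only apply to FST methods, not '{self.name}'")


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment parameters.

    n_samples is the SVM training-subset size per hemisphere; C and gamma
    are used as-is unless ``tune`` is set, in which case a leave-one-image-
    out grid search picks them per hemisphere.  k=1 and all pairs are the
    FST defaults.
    """

    n_samples: int = 2000
    svm_C: float = 10.0
    svm_gamma: float = 0.1
    tune: bool = False
    C_grid: tuple = (1.0, 10.0, 100.0)
    gamma_grid: tuple = (0.01, 0.1, 1.0)
    k: int = 1
    n_pairs_used: int | None = None
    roi_threshold: float = 0.10
    leave_self_out_prior: bool = False
    use_extra_atlases: bool = False
    sample_seed: int = 0


# --------------------------------------------------------------------------
# per-image feature packs and per-direction preparation


class _Pack:
    """Range-matched image, its feature volumes and ground truth."""

    def __init__(self, subject_id: str, image: ImageVolume, mask: BrainMask, labels):
        self.subject_id = subject_id
        self.mask = mask
        self.labels = labels
        self.image_rm = range_match(image, mask)
        self.vols = appearance_feature_volumes(self.image_rm)
        self.spacing = image.spacing
        self._brain_table: FeatureTable | None = None

    def table_at(self, sel: np.ndarray) -> FeatureTable:
        return feature_table_from_volumes(
            self.vols, APPEARANCE_FEATURE_NAMES, self.image_rm.grid_shape, _as_mask(sel)
        )

    def brain_table(self) -> FeatureTable:
        if self._brain_table is None:
            self._brain_table = self.table_at(self.mask.data)
        return self._brain_table


def _as_mask(sel: np.ndarray) -> BrainMask:
    return BrainMask(sel)


@dataclass
class _Prepared:
    """Everything shared by the methods for one train->test direction."""

    study: PhantomStudy
    config: ExperimentConfig
    train_slot: str
    test_slot: str
    train: list[_Pack]
    test: list[_Pack]
    pair_src: list[_Pack]
    pair_tgt: list[_Pack]
    norm_src: NormalizationParams
    norm_tgt: NormalizationParams
    priors: dict  # (subject_id, hemi) -> AtlasProbability
    rois: dict  # (subject_id, hemi) -> ROIMask
    atlas_norm: dict  # hemi -> (location, scale)
    _fst_cache: dict = field(default_factory=dict)

    def fst_model(self, k: int, n_used: int | None = None, exclude_pair: int | None = None) -> FSTModel:
        n_pairs = len(self.pair_src)
        n_used = n_pairs if n_used is None else n_used
        if n_used > n_pairs:
            raise ValueError(f"N={n_used} exceeds available pairs ({n_pairs})")
        key = (k, n_used, exclude_pair)
        if key not in self._fst_cache:
            blocks = []
            for i in range(n_used):
                if i == exclude_pair:
                    continue
                src = zscore_apply(self.pair_src[i].brain_table(), self.norm_src)
                tgt = zscore_apply(self.pair_tgt[i].brain_table(), self.norm_tgt)
                joint = BrainMask(self.pair_src[i].mask.intersection(self.pair_tgt[i].mask))
                blocks.append(build_correspondence(src, tgt, joint, subject_id=str(i)))
            if not blocks:
                raise ValueError("no correspondence pairs left to fit the FST")
            self._fst_cache[key] = fit_fst(blocks, k=k, feature_names=list(APPEARANCE_FEATURE_NAMES))
        return self._fst_cache[key]


def _image_for(study: PhantomStudy, record, slot: str) -> ImageVolume:
    if hasattr(record, "images"):
        return record.images[slot]
    return record.image_a if slot == "A" else record.image_b


def _prepare(
    study: PhantomStudy,
    config: ExperimentConfig,
    train_slot: str,
    test_slot: str,
    test_records=None,
) -> _Prepared:
    """Build feature packs, normalizations, priors and ROIs for a direction."""
    train = [
        _Pack(r.subject_id, r.images[train_slot], r.anatomy.mask, r.anatomy.labels)
        for r in study.train
    ]
    test_records = study.test if test_records is None else test_records
    test = [
        _Pack(r.subject_id, _image_for(study, r, test_slot), r.anatomy.mask, r.anatomy.labels)
        for r in test_records
    ]
    pair_src = [
        _Pack(p.subject_id, _image_for(study, p, train_slot), p.anatomy.mask, None)
        for p in study.pairs
    ]
    pair_tgt = [
        _Pack(p.subject_id, _image_for(study, p, test_slot), p.anatomy.mask, None)
        for p in study.pairs
    ]

    # Per-scanner z-scoring, fit on that scanner's rescan-pair images (same
    # anatomies on both sides, so parameter differences are scanner effects).
    norm_src = zscore_fit([p.brain_table() for p in pair_src], scope=f"scanner:{train_slot}")
    norm_tgt = zscore_fit([p.brain_table() for p in pair_tgt], scope=f"scanner:{test_slot}")

    n_core = study.config.n_train
    n_atlas = n_core + (len(study.extra_atlas_labels) if config.use_extra_atlases else 0)

    priors, rois = {}, {}
    for group, is_train in ((train, True), (test, False), (pair_tgt, False), (pair_src, False)):
        for idx, pack in enumerate(group):
            if (pack.subject_id, LEFT) in priors:
                continue
            atl = list(study.atlases[pack.subject_id][:n_core])
            if config.use_extra_atlases:
                atl += list(study.atlases[pack.subject_id][n_core:n_atlas])
            if is_train and config.leave_self_out_prior and len(atl) > 1:
                atl = atl[:idx] + atl[idx + 1 :]
            for hemi, _ in _HEMIS:
                prob = multi_atlas_probability(atl, structure_label=hemi)
                priors[(pack.subject_id, hemi)] = prob
                rois[(pack.subject_id, hemi)] = define_roi(prob, config.roi_threshold)

    # Atlas feature z-scored within the ROI, fit on the training images.
    atlas_norm = {}
    for hemi, _ in _HEMIS:
        vals = np.concatenate(
            [
                priors[(p.subject_id, hemi)].data[rois[(p.subject_id, hemi)].data]
                for p in train
            ]
        )
        sd = vals.std()
        if sd <= 0:
            raise ValueError("atlas prior has zero variance inside the ROI")
        atlas_norm[hemi] = (float(vals.mean()), float(sd))

    return _Prepared(
        study, config, train_slot, test_slot, train, test, pair_src, pair_tgt,
        norm_src, norm_tgt, priors, rois, atlas_norm,
    )


# --------------------------------------------------------------------------
# training-set assembly and prediction per method


def _atlas_column(prep: _Prepared, subject_id: str, hemi: int, ijk: np.ndarray) -> np.ndarray:
    loc, sd = prep.atlas_norm[hemi]
    prob = prep.priors[(subject_id, hemi)].data
    return (prob[tuple(ijk.T)] - loc) / sd


def _fst_intensity_pack(prep: _Prepared, pack: _Pack, model: FSTModel) -> _Pack:
    """Re-extract appearance features from the intensity-transformed image."""
    int_idx = APPEARANCE_FEATURE_NAMES.index("intensity")
    loc_s, sc_s = prep.norm_src.location[int_idx], prep.norm_src.scale[int_idx]
    loc_t, sc_t = prep.norm_tgt.location[int_idx], prep.norm_tgt.scale[int_idx]
    std_int = ImageVolume((pack.image_rm.data - loc_s) / sc_s, pack.spacing)
    std_table = zscore_apply(pack.brain_table(), prep.norm_src)
    transformed = apply_fst_intensity_only(model, std_table, std_int)
    raw_target = ImageVolume(transformed.data * sc_t + loc_t, pack.spacing)
    out = _Pack.__new__(_Pack)
    out.subject_id = pack.subject_id
    out.mask = pack.mask
    out.labels = pack.labels
    out.image_rm = raw_target
    out.vols = appearance_feature_volumes(raw_target)
    out.spacing = pack.spacing
    out._brain_table = None
    return out


def _training_set(prep: _Prepared, method: MethodSpec, hemi: int, hemi_name: str) -> TrainingSet:
    """Pool ROI training rows over the training images for one hemisphere."""
    cfg = prep.config
    model = None
    if method.name in _FST_METHODS:
        model = prep.fst_model(method.k or cfg.k, method.n_pairs_used or cfg.n_pairs_used)

    values, ijks, labels, groups = [], [], [], []
    for t_idx, pack in enumerate(prep.train):
        roi = prep.rois[(pack.subject_id, hemi)]
        src_pack = pack
        if method.name == "svm_fst_intensity":
            src_pack = _fst_intensity_pack(prep, pack, model)
        raw = src_pack.table_at(roi.data)
        if method.name == "svm_atlas":
            app = np.empty((raw.n_samples, 0))
            names = []
        else:
            norm = prep.norm_tgt if method.name == "svm_fst_intensity" else prep.norm_src
            std = zscore_apply(raw, norm)
            if method.name == "svm_fst":
                std = apply_fst(model, std)
            app = std.values
            names = list(APPEARANCE_FEATURE_NAMES)
        atlas_col = _atlas_column(prep, pack.subject_id, hemi, raw.voxel_index)
        values.append(np.column_stack([app, atlas_col]))
        ijks.append(raw.voxel_index)
        labels.append((pack.labels[tuple(raw.voxel_index.T)] == hemi).astype(int))
        groups.append(np.full(raw.n_samples, t_idx))

    table = FeatureTable(
        np.vstack(values), np.vstack(ijks), names + [ATLAS_FEATURE], prep.train_slot
    )
    return TrainingSet(table, np.concatenate(labels), hemi_name, np.concatenate(groups))


def _test_tables(prep: _Prepared, pack: _Pack, atlas_only: bool):
    """Per-hemisphere test tables over that hemisphere's ROI voxels."""
    out = {}
    for hemi, _ in _HEMIS:
        roi = prep.rois[(pack.subject_id, hemi)]
        if not roi.data.any():
            out[hemi] = None
            continue
        raw = pack.table_at(roi.data)
        atlas_col = _atlas_column(prep, pack.subject_id, hemi, raw.voxel_index)
        if atlas_only:
            vals, names = atlas_col[:, None], [ATLAS_FEATURE]
        else:
            std = zscore_apply(raw, prep.norm_tgt)
            vals = np.column_stack([std.values, atlas_col])
            names = list(APPEARANCE_FEATURE_NAMES) + [ATLAS_FEATURE]
        out[hemi] = FeatureTable(vals, raw.voxel_index, names, prep.test_slot)
    return out


def _fit_method(prep: _Prepared, method: MethodSpec):
    """Train the per-hemisphere segmenter for one SVM-based method."""
    cfg = prep.config
    sets = {}
    for hemi, hemi_name in _HEMIS:
        ts = _training_set(prep, method, hemi, hemi_name)
        seed = (prep.study.master_seed * 7 + hemi) % (2**31)
        sets[hemi] = sample_training_voxels(ts, cfg.n_samples, seed=seed)
    if cfg.tune:
        C_l, g_l = tune_hyperparameters(sets[LEFT], C_grid=cfg.C_grid, gamma_grid=cfg.gamma_grid)
        C_r, g_r = tune_hyperparameters(sets[RIGHT], C_grid=cfg.C_grid, gamma_grid=cfg.gamma_grid)
        left = train_segmenter(sets[LEFT], sets[RIGHT], C_l, g_l)
        right = train_segmenter(sets[LEFT], sets[RIGHT], C_r, g_r)
        # independently tuned hemispheres: take each side from its own fit
        seg = left
        seg.model_right = right.model_right
        seg.metadata["C_right"], seg.metadata["gamma_right"] = C_r, g_r
        return seg
    return train_segmenter(sets[LEFT], sets[RIGHT], cfg.svm_C, cfg.svm_gamma)


def _predict_pack(prep: _Prepared, method: MethodSpec, segmenter, pack: _Pack) -> np.ndarray:
    """Segment one test image with a fitted method."""
    grid = pack.image_rm.grid_shape
    roi_l = prep.rois[(pack.subject_id, LEFT)]
    roi_r = prep.rois[(pack.subject_id, RIGHT)]
    if method.name == "atlas_mv":
        out = np.zeros(grid, dtype=np.int16)
        out[majority_vote(prep.priors[(pack.subject_id, LEFT)])] = LEFT
        out[majority_vote(prep.priors[(pack.subject_id, RIGHT)])] = RIGHT
        return out
    tables = _test_tables(prep, pack, atlas_only=(method.name == "svm_atlas"))
    return predict_segmentation(
        segmenter, (tables[LEFT], tables[RIGHT]), roi_l, roi_r, grid
    )


# --------------------------------------------------------------------------
# public experiment drivers


@dataclass
class ComparisonResult:
    """Per-subject Dice table, per-method summary, and raw segmentations."""

    table: pd.DataFrame
    summary: pd.DataFrame
    segmentations: dict  # (direction, method, subject_id) -> label volume

    def format_table(self) -> str:
        """Method-by-direction mean Dice, best-or-equivalent marked in *...*."""
        lines = []
        for direction, sub in self.summary.groupby("direction", sort=False):
            lines.append(f"direction {direction} (train->test)")
            for _, row in sub.iterrows():
                mark = f"*{row.mean_dice:.3f}*" if row.bold else f" {row.mean_dice:.3f} "
                lines.append(f"  {row.method:<18s} {mark}")
        return "\n".join(lines)


def _direction_slots(direction: str) -> tuple[str, str]:
    if len(direction) != 2 or any(c not in "AB" for c in direction):
        raise ValueError(f"direction must be two scanner slots like 'AB', got '{direction}'")
    return direction[0], direction[1]


def run_comparison(
    study: PhantomStudy,
    methods,
    config: ExperimentConfig | None = None,
    directions=("AB",),
) -> ComparisonResult:
    """Compare segmentation methods on a phantom study.

    For each direction (e.g. "AB": train on scanner A images, test on
    scanner B images) every method segments every test subject; the result
    table holds per-subject left/right/mean Dice, and the summary marks the
    best method plus all methods not significantly worse (signed-rank,
    alpha 0.05) in its ``bold`` column.
    """
    config = config or ExperimentConfig()
    methods = [MethodSpec(m) if isinstance(m, str) else m for m in methods]
    if not methods:
        raise ValueError("no methods requested")
    if any(m.name in _FST_METHODS for m in methods) and not study.pairs:
        raise ValueError("FST methods require a study with rescan pairs")

    rows, segs = [], {}
    for direction in directions:
        tr, te = _direction_slots(direction)
        prep = _prepare(study, config, tr, te)
        for method in methods:
            segmenter = None
            if method.name not in ("atlas_mv",):
                segmenter = _fit_method(prep, method)
            for pack in prep.test:
                pred = _predict_pack(prep, method, segmenter, pack)
                d_l = dice(pred == LEFT, pack.labels == LEFT)
                d_r = dice(pred == RIGHT, pack.labels == RIGHT)
                rows.append(
                    dict(
                        direction=direction,
                        method=method.name,
                        subject=pack.subject_id,
                        dice_left=d_l,
                        dice_right=d_r,
                        dice_mean=subject_mean_dice(d_l, d_r),
                    )
                )
                segs[(direction, method.name, pack.subject_id)] = pred

    table = pd.DataFrame(rows)
    summary = _summarize(table)
    return ComparisonResult(table, summary, segs)


def _summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Dice per method with the best-or-not-significantly-worse mark."""
    out = []
    for direction, sub in table.groupby("direction", sort=False):
        pivot = sub.pivot(index="subject", columns="method", values="dice_mean")
        means = pivot.mean(axis=0)
        best = means.idxmax()
        for method in sub["method"].unique():
            if method == best:
                bold = True
            else:
                res = paired_signed_rank(pivot[method].to_numpy(), pivot[best].to_numpy())
                bold = not res.significant
            out.append(
                dict(direction=direction, method=method, mean_dice=means[method], bold=bold)
            )
    return pd.DataFrame(out)


def sweep_k_n(
    study: PhantomStudy,
    k_values=(1,),
    n_values=(1,),
    config: ExperimentConfig | None = None,
    direction: str = "AB",
) -> pd.DataFrame:
    """Mean Dice of svm_fst per (k, N) cell, with the change vs (k=1, N=1).

    N selects the first N rescan pairs.  As an internal consistency check,
    the mean nearest-source distance of the training queries must be
    non-increasing in N (adding pairs can only bring neighbors closer).
    """
    config = config or ExperimentConfig()
    n_pairs = len(study.pairs)
    if max(n_values) > n_pairs:
        raise ValueError(f"N={max(n_values)} exceeds available pairs ({n_pairs})")
    tr, te = _direction_slots(direction)
    prep = _prepare(study, config, tr, te)

    # monotonicity of NN distances in N, on the pooled training ROI samples
    queries = []
    for pack in prep.train:
        roi = prep.rois[(pack.subject_id, LEFT)]
        queries.append(zscore_apply(pack.table_at(roi.data), prep.norm_src).values)
    q = np.vstack(queries)
    prev = np.inf
    for n_used in sorted(set(n_values)):
        model = prep.fst_model(1, n_used)
        d, _ = model._tree.query(q, k=1)
        mean_d = float(np.mean(d))
        if mean_d > prev + 1e-9:
            raise AssertionError("NN distance increased with N; correspondence pooling is broken")
        prev = mean_d

    def cell(k: int, n_used: int) -> float:
        res = run_comparison(
            study,
            [MethodSpec("svm_fst", k=k, n_pairs_used=n_used)],
            config,
            directions=(direction,),
        )
        return float(res.summary["mean_dice"].iloc[0])

    base = cell(1, 1)
    rows = []
    for k in k_values:
        for n_used in n_values:
            m = base if (k == 1 and n_used == 1) else cell(k, n_used)
            rows.append(dict(k=k, N=n_used, mean_dice=m, delta_vs_11=m - base))
    return pd.DataFrame(rows)


def rescan_reproducibility(
    study: PhantomStudy,
    train_scanner: str = "A",
    methods=("svm", "svm_fst"),
    config: ExperimentConfig | None = None,
) -> dict[str, BlandAltmanResult]:
    """Cross-scanner volume reproducibility on the rescan pairs.

    Both members of every rescan pair are segmented by the pipeline trained
    on ``train_scanner``; for FST methods the member on the other scanner
    is segmented after an FST fitted on the *other* pairs (leave-one-
    subject-out), mirroring the rescan cross-validation design.  Returns a
    Bland-Altman analysis of the paired segmented volumes per method; each
    hemisphere contributes one point (2 x n_pairs points).
    """
    config = config or ExperimentConfig()
    if train_scanner not in ("A", "B"):
        raise ValueError("train_scanner must be 'A' or 'B'")
    n_pairs = len(study.pairs)
    if n_pairs < 2:
        raise ValueError("rescan reproducibility needs at least 2 rescan pairs")
    if n_pairs < 5:
        warnings.warn(f"only {n_pairs} rescan pairs; Bland-Altman limits will be unstable",
                      stacklevel=2)
    tr = train_scanner
    te = "B" if tr == "A" else "A"

    # prep with pair members as the test records (segmented on the te slot);
    # a second prep reuses slot tr for the same-scanner members.
    prep_cross = _prepare(study, config, tr, te, test_records=study.pairs)
    prep_same = _prepare(study, config, tr, tr, test_records=study.pairs)

    out: dict[str, BlandAltmanResult] = {}
    for name in methods:
        spec = MethodSpec(name) if isinstance(name, str) else name
        # same-scanner member: FST tr->tr is the identity, so the plain
        # classifier applies for every method
        plain = None
        if spec.name != "atlas_mv":
            plain = _fit_method(prep_same, MethodSpec("svm_atlas" if spec.name == "svm_atlas" else "svm"))
        vol_a, vol_b = [], []
        for i, pack_same in enumerate(prep_same.test):
            pack_cross = prep_cross.test[i]
            if spec.name in _FST_METHODS:
                sub_spec = replace(spec, k=spec.k or config.k)
                model = prep_cross.fst_model(sub_spec.k, spec.n_pairs_used, exclude_pair=i)
                cross_prep_i = replace(prep_cross, _fst_cache={(sub_spec.k, len(study.pairs) if spec.n_pairs_used is None else spec.n_pairs_used, None): model})
                cross_seg = _fit_method(cross_prep_i, MethodSpec(spec.name, k=sub_spec.k, n_pairs_used=spec.n_pairs_used))
            elif spec.name == "atlas_mv":
                cross_seg = None
            else:
                cross_seg = _fit_method(prep_cross, spec)
            pred_same = _predict_pack(prep_same, MethodSpec("svm" if spec.name in _FST_METHODS else spec.name), plain, pack_same)
            pred_cross = _predict_pack(prep_cross, spec, cross_seg, pack_cross)
            pred_a = pred_same if tr == "A" else pred_cross
            pred_b = pred_cross if tr == "A" else pred_same
            for hemi, _ in _HEMIS:
                vol_a.append(volume_mm3(pred_a == hemi, study.spacing))
                vol_b.append(volume_mm3(pred_b == hemi, study.spacing))
        out[spec.name] = bland_altman(vol_a, vol_b)
    return out
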