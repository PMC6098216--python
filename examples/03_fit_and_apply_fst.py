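"""Fit a feature-space transformation from rescan pairs and apply it.

The FST pairs every brain voxel of a subject's two acquisitions in feature
space and transforms new samples by the robust-median (medoid) shift of
their k nearest source samples — an observed, not interpolated,
transformation.
"""

import numpy as np

import fstseg
from fstseg import BrainMask

study = fstseg.generate_study(fstseg.StudyConfig(), master_seed=3)

# standardized brain-mask feature tables for each side of each pair
src_tabs, tgt_tabs, masks = [], [], []
for p in study.pairs:
    m = p.anatomy.mask
    src_tabs.append(fstseg.appearance_features(fstseg.range_match(p.image_a, m), m, "A"))
    tgt_tabs.append(fstseg.appearance_features(fstseg.range_match(p.image_b, m), m, "B"))
    masks.append(m)
norm_a = fstseg.zscore_fit(src_tabs, scope="scanner A")
norm_b = fstseg.zscore_fit(tgt_tabs, scope="scanner B")

blocks = [
    fstseg.build_correspondence(
        fstseg.zscore_apply(s, norm_a), fstseg.zscore_apply(t, norm_b), m, p.subject_id
    )
    for s, t, m, p in zip(src_tabs, tgt_tabs, masks, study.pairs)
]
model = fstseg.fit_fst(blocks, k=1)
print(f"FST fitted: {model.n_pairs} voxel correspondences from {model.n_subjects} rescan pairs")

# transform a training image's brain voxels from scanner A's space to B's
rec = study.train[0]
train_tab = fstseg.appearance_features(
    fstseg.range_match(rec.images["A"], rec.anatomy.mask), rec.anatomy.mask, "A"
)
std = fstseg.zscore_apply(train_tab, norm_a)
moved = fstseg.apply_fst(model, std)
shift = np.linalg.norm(moved.values - std.values, axis=1)
print(f"mean transformation length: {shift.mean():.2f} standardized units "
      f"(0 would mean identical scanners)")
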