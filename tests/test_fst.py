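"""The feature-space transformation: correspondences, medoid, k-NN mapping."""

import numpy as np
import pytest

from fstseg import (
    BrainMask,
    CorrespondencePairs,
    FeatureTable,
    ImageVolume,
    apply_fst,
    apply_fst_intensity_only,
    build_correspondence,
    fit_fst,
    robust_median,
)
from fstseg.fst import FSTModel


def brute_force_medoid(vectors):
    """Exhaustive argmin of total Euclidean distance (lowest index wins)."""
    v = np.asarray(vectors, float)
    totals = np.array([np.linalg.norm(v - v[i], axis=1).sum() for i in range(len(v))])
    return v[int(np.argmin(totals))]


def brute_force_knn(sources, query, k):
    """k nearest rows by (distance, row index)."""
    d = np.linalg.norm(sources - query, axis=1)
    return np.lexsort((np.arange(len(d)), d))[:k]


def _table(values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or [f"f{i}" for i in range(values.shape[1])]
    ijk = np.column_stack([np.arange(values.shape[0])] * 3)
    return FeatureTable(values, ijk, names)


class TestRobustMedian:
    def test_single_vector(self):
        np.testing.assert_array_equal(robust_median([[3.0, 4.0]]), [3.0, 4.0])

    def test_three_vector_example(self):
        # totals: (0,0) -> 2; (1,0) and (0,1) -> 1 + sqrt(2)
        out = robust_median([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_permutation_invariance(self, rng):
        v = rng.normal(size=(7, 3))
        base = robust_median(v)
        for _ in range(5):
            perm = rng.permutation(7)
            np.testing.assert_array_equal(robust_median(v[perm]), base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            robust_median(np.empty((0, 3)))

    def test_selector_property_against_exhaustive_argmin(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 26))
            d = int(rng.integers(1, 13))
            v = rng.normal(size=(k, d))
            out = robust_median(v)
            assert any(np.array_equal(out, row) for row in v)
            np.testing.assert_array_equal(out, brute_force_medoid(v))


class TestBuildCorrespondence:
    def test_identical_images_pair_with_themselves(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 8)))
        mask = BrainMask(np.ones((8, 8, 8), bool))
        from fstseg import appearance_features

        t = appearance_features(vol, mask)
        pairs = build_correspondence(t, t, mask)
        np.testing.assert_array_equal(pairs.source_rows, pairs.target_rows)

    def test_one_pair_per_mask_voxel(self, rng):
        sel = np.zeros((10, 10, 10), bool)
        sel.ravel()[rng.choice(1000, 500, replace=False)] = True
        mask = BrainMask(sel)
        ijk = np.argwhere(sel)
        src = FeatureTable(rng.normal(size=(500, 2)), ijk, ["a", "b"])
        tgt = FeatureTable(rng.normal(size=(500, 2)), ijk, ["a", "b"])
        assert build_correspondence(src, tgt, mask).n_pairs == 500

    def test_missing_voxels_rejected(self, rng):
        sel = np.zeros((6, 6, 6), bool)
        sel[2:4, 2:4, 2:4] = True
        mask = BrainMask(sel)
        ijk = np.argwhere(sel)[:-1]  # drop one covered voxel
        t = FeatureTable(rng.normal(size=(len(ijk), 1)), ijk, ["f"])
        with pytest.raises(ValueError, match="missing"):
            build_correspondence(t, t, mask)

    def test_empty_mask_intersection_rejected(self):
        a = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = True
        b = np.zeros_like(a)
        b[5, 5, 5] = True
        # disjoint brain masks: the joint mask cannot be formed
        with pytest.raises(ValueError):
            BrainMask(BrainMask(a).intersection(BrainMask(b)))


class TestFitFst:
    def test_pooling_counts(self, rng):
        blocks = [
            CorrespondencePairs(rng.normal(size=(100, 3)), rng.normal(size=(100, 3)), str(i))
            for i in range(2)
        ]
        model = fit_fst(blocks, k=1)
        assert model.n_pairs == 200
        assert model.n_subjects == 2

    def test_invalid_k(self, rng):
        block = CorrespondencePairs(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            fit_fst(block, k=0)
        with pytest.raises(ValueError):
            fit_fst(block, k=11)

    def test_dimension_mismatch_across_blocks(self, rng):
        a = CorrespondencePairs(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        b = CorrespondencePairs(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            fit_fst([a, b])

    def test_duplicate_source_rows_allowed(self):
        src = np.zeros((4, 2))
        tgt = np.arange(8.0).reshape(4, 2)
        model = fit_fst(CorrespondencePairs(src, tgt), k=4)
        assert model.nearest_sources(np.zeros((1, 2))).shape == (1, 4)


class TestApplyFst:
    def test_query_on_stored_source_row_lands_on_paired_target(self, rng):
        src = rng.normal(size=(20, 3))
        tgt = rng.normal(size=(20, 3))
        model = fit_fst(CorrespondencePairs(src, tgt), k=1)
        out = apply_fst(model, _table(src[7]))
        np.testing.assert_allclose(out.values[0], tgt[7])

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_identity_when_target_equals_source(self, rng, k):
        rows = rng.normal(size=(50, 4))
        model = fit_fst(CorrespondencePairs(rows, rows.copy()), k=k)
        x = _table(rng.normal(size=(30, 4)))
        out = apply_fst(model, x)
        np.testing.assert_array_equal(out.values, x.values)
        np.testing.assert_array_equal(out.voxel_index, x.voxel_index)

    def test_k3_against_brute_force_oracle(self, rng):
        src = rng.normal(size=(5, 2))
        tgt = rng.normal(size=(5, 2))
        model = fit_fst(CorrespondencePairs(src, tgt), k=3)
        q = rng.normal(size=(1, 2))
        nn = brute_force_knn(src, q[0], 3)
        expected = q[0] + brute_force_medoid(tgt[nn] - src[nn])
        np.testing.assert_allclose(apply_fst(model, _table(q)).values[0], expected)

    def test_k_equals_m_gives_one_global_transformation(self, rng):
        src = rng.normal(size=(8, 2))
        tgt = rng.normal(size=(8, 2))
        model = fit_fst(CorrespondencePairs(src, tgt), k=8)
        x = rng.normal(size=(10, 2))
        out = apply_fst(model, _table(x))
        # all queries share the full candidate set, hence the same median shift
        shift = out.values - x
        np.testing.assert_allclose(shift, np.broadcast_to(shift[0], shift.shape))
        assert any(np.allclose(shift[0], t - s) for s, t in zip(src, tgt))

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_fst(CorrespondencePairs(rng.normal(size=(5, 3)), rng.normal(size=(5, 3))))
        with pytest.raises(ValueError, match="shared"):
            apply_fst(model, _table(rng.normal(size=(2, 2))))

    def test_nn_index_matches_brute_force(self, rng):
        for _ in range(30):
            m = int(rng.integers(5, 300))
            d = int(rng.integers(1, 8))
            k = int(rng.integers(1, min(m, 10) + 1))
            src = rng.normal(size=(m, d))
            model = fit_fst(CorrespondencePairs(src, rng.normal(size=(m, d))), k=k)
            q = rng.normal(size=(4, d))
            got = model.nearest_sources(q)
            for row, query in zip(got, q):
                np.testing.assert_array_equal(row, brute_force_knn(src, query, k))

    def test_save_load_round_trip(self, rng, tmp_path):
        model = fit_fst(
            CorrespondencePairs(rng.normal(size=(12, 3)), rng.normal(size=(12, 3))),
            k=2,
            feature_names=["a", "b", "c"],
        )
        path = str(tmp_path / "model.fst")
        model.save(path)
        loaded = FSTModel.load(path)
        np.testing.assert_array_equal(loaded.source_rows, model.source_rows)
        np.testing.assert_array_equal(loaded.target_rows, model.target_rows)
        assert loaded.k == 2 and loaded.feature_names == ["a", "b", "c"]
        q = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(loaded.nearest_sources(q), model.nearest_sources(q))


class TestApplyFstIntensityOnly:
    def _model_and_table(self, rng, identical=False):
        names = ["intensity", "aux"]
        src = rng.normal(size=(30, 2))
        tgt = src.copy() if identical else rng.normal(size=(30, 2))
        model = fit_fst(CorrespondencePairs(src, tgt), k=1, feature_names=names)
        shape = (4, 4, 4)
        sel = np.zeros(shape, bool)
        sel[1:3, 1:3, 1:3] = True
        ijk = np.argwhere(sel)
        vals = rng.normal(size=(len(ijk), 2))
        img = np.zeros(shape)
        img[tuple(ijk.T)] = vals[:, 0]
        return model, FeatureTable(vals, ijk, names), ImageVolume(img), src, tgt

    def test_identity_model_leaves_image_unchanged(self, rng):
        model, table, img, _, _ = self._model_and_table(rng, identical=True)
        out = apply_fst_intensity_only(model, table, img)
        np.testing.assert_array_equal(out.data, img.data)

    def test_stored_row_gets_paired_target_intensity(self, rng):
        model, table, img, src, tgt = self._model_and_table(rng)
        table.values[0] = src[4]
        img.data[tuple(table.voxel_index[0])] = src[4, 0]
        out = apply_fst_intensity_only(model, table, img)
        np.testing.assert_allclose(out.data[tuple(table.voxel_index[0])], tgt[4, 0])

    def test_matches_brute_force_intensity_component(self, rng):
        src = rng.normal(size=(5, 2))
        tgt = rng.normal(size=(5, 2))
        model = fit_fst(CorrespondencePairs(src, tgt), k=3, feature_names=["intensity", "aux"])
        vals = rng.normal(size=(3, 2))
        ijk = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        table = FeatureTable(vals, ijk, ["intensity", "aux"])
        img = ImageVolume(np.zeros((1, 1, 3)))
        img.data[0, 0, :] = vals[:, 0]
        out = apply_fst_intensity_only(model, table, img)
        for r in range(3):
            nn = brute_force_knn(src, vals[r], 3)
            expected = vals[r] + brute_force_medoid(tgt[nn] - src[nn])
            np.testing.assert_allclose(out.data[0, 0, r], expected[0])


class TestDistributionMapping:
    def test_affine_map_recovery_improves_with_m(self):
        # target = per-feature affine map g of source, exact correspondences:
        # the k=1 FST should converge on g as the pair count grows
        rng = np.random.default_rng(7)
        a = np.array([1.3, 0.7, 1.1])
        b = np.array([0.5, -0.2, 0.1])
        x = rng.normal(size=(400, 3))
        errors = []
        for m in (100, 1000, 10000):
            z = rng.normal(size=(m, 3))
            model = fit_fst(CorrespondencePairs(z, a * z + b), k=1)
            out = apply_fst(model, _table(x))
            errors.append(float(np.mean(np.abs(out.values - (a * x + b)))))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.05
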