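"""Atlas model: sparse storage round-trips, inpainting, grouping, warping."""
import numpy as np
import pytest

from histoseg.atlas import (AtlasValidationError, LabelGrouping, ProbabilisticAtlas,
                            ROIDescriptor, group_probabilities, load_atlas,
                            remove_and_inpaint, resample_probability_maps,
                            save_atlas)


def _uniform_atlas(p=0.5, shape=(8, 8, 8)):
    roi = ROIDescriptor(1, "all", (10, 20, 30), "c")
    probs = np.full(shape, p, dtype=np.float32)
    box = np.array([0, shape[0], 0, shape[1], 0, shape[2]])
    return ProbabilisticAtlas(shape, np.eye(4), 1.0, [(roi, box, probs)])


class TestRoundTrip:
    def test_uniform_atlas_round_trips_bit_exact(self, tmp_path):
        atlas = _uniform_atlas()
        save_atlas(atlas, tmp_path / "a")
        loaded = load_atlas(tmp_path / "a")
        np.testing.assert_array_equal(loaded.rois[0][2], atlas.rois[0][2])
        assert loaded.rois[0][0] == atlas.rois[0][0]
        np.testing.assert_array_equal(loaded.affine, atlas.affine)

    def test_phantom_round_trip_and_prob_sum(self, small_phantom, tmp_path):
        atlas, _ = small_phantom
        save_atlas(atlas, tmp_path / "p")
        loaded = load_atlas(tmp_path / "p")
        assert loaded.label_ids == atlas.label_ids
        for (_, b1, p1), (_, b2, p2) in zip(atlas.rois, loaded.rois):
            np.testing.assert_array_equal(b1, b2)
            np.testing.assert_array_equal(p1, p2)
        # per-voxel sum over ROIs never exceeds 1 (background is the residual)
        assert loaded.foreground_sum().max() <= 1 + 1e-6

    def test_zero_padded_boxes_are_retightened_on_load(self, tmp_path):
        shape = (10, 10, 10)
        probs = np.zeros((6, 6, 6), dtype=np.float32)
        probs[2:4, 2:4, 2:4] = 0.8  # interior block, zero margin around it
        roi = ROIDescriptor(3, "pad", (0, 0, 0), "c")
        atlas = ProbabilisticAtlas(shape, np.eye(4), 1.0,
                                   [(roi, np.array([1, 7, 1, 7, 1, 7]), probs)])
        save_atlas(atlas, tmp_path / "t")
        loaded = load_atlas(tmp_path / "t")
        _, box, cropped = loaded.rois[0]
        # brute-force nonzero extent of the dense map
        dense = atlas.dense_map(3)
        nz = np.nonzero(dense)
        expect = [nz[0].min(), nz[0].max() + 1, nz[1].min(), nz[1].max() + 1,
                  nz[2].min(), nz[2].max() + 1]
        assert box.tolist() == expect
        assert cropped.shape == (2, 2, 2)

    def test_missing_sidecar_is_format_error(self, tmp_path):
        from histoseg.atlas import AtlasFormatError
        save_atlas(_uniform_atlas(), tmp_path / "b")
        (tmp_path / "b" / "roi_1.json").unlink()
        with pytest.raises(AtlasFormatError):
            load_atlas(tmp_path / "b")

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(AtlasValidationError):
            _uniform_atlas(p=1.4).validate()


class TestRemoveAndInpaint:
    def test_single_survivor_absorbs_everything(self):
        shape = (6, 6, 6)
        p1 = np.full(shape, 0.4, np.float32)
        p2 = np.full(shape, 0.5, np.float32)
        box = np.array([0, 6, 0, 6, 0, 6])
        atlas = ProbabilisticAtlas(shape, np.eye(4), 1.0, [
            (ROIDescriptor(1, "a", tissue_class="c"), box, p1),
            (ROIDescriptor(2, "b", tissue_class="c"), box.copy(), p2)])
        out = remove_and_inpaint(atlas, {2})
        np.testing.assert_allclose(out.dense_map(1), 0.9, atol=1e-6)

    def test_zero_mass_removal_is_identity(self, small_phantom):
        atlas, _ = small_phantom
        d = ROIDescriptor(99, "empty", tissue_class="class_0")
        rois = [(r[0], r[1].copy(), r[2].copy()) for r in atlas.rois]
        rois.append((d, np.array([0, 1, 0, 1, 0, 1]), np.zeros((1, 1, 1), np.float32)))
        padded = ProbabilisticAtlas(atlas.grid_shape, atlas.affine,
                                    atlas.resolution, rois)
        out = remove_and_inpaint(padded, {99})
        assert out.label_ids == atlas.label_ids
        for lid in atlas.label_ids:
            np.testing.assert_allclose(out.dense_map(lid), atlas.dense_map(lid))

    def test_mass_conserved_and_matches_bruteforce(self, small_phantom):
        atlas, _ = small_phantom
        removed = {atlas.label_ids[len(atlas.label_ids) // 2]}
        before = atlas.foreground_sum()
        out = remove_and_inpaint(atlas, removed)
        after = out.foreground_sum()
        np.testing.assert_allclose(after, before, atol=1e-5)

        # brute-force oracle: for each voxel with removed mass, exhaustive
        # nearest-voxel search over surviving modal labels, lowest id on ties
        dense = {lid: atlas.dense_map(lid) for lid in atlas.label_ids}
        stack = np.stack([dense[lid] for lid in atlas.label_ids])
        modal = np.where(stack.max(0) > 0,
                         np.asarray(atlas.label_ids)[stack.argmax(0)], 0)
        surviving = [lid for lid in atlas.label_ids if lid not in removed]
        removed_mass = sum(dense[lid] for lid in removed)
        src = np.argwhere(np.isin(modal, surviving))
        expected = {lid: dense[lid].astype(float).copy() for lid in surviving}
        for vox in np.argwhere(removed_mass > 0):
            d2 = ((src - vox) ** 2).sum(1)
            cand = src[d2 == d2.min()]
            lid = min(modal[tuple(c)] for c in cand)
            expected[lid][tuple(vox)] += removed_mass[tuple(vox)]
        for lid in surviving:
            np.testing.assert_allclose(out.dense_map(lid), expected[lid], atol=1e-5)

    def test_removing_everything_raises(self, small_phantom):
        atlas, _ = small_phantom
        with pytest.raises(AtlasValidationError):
            remove_and_inpaint(atlas, set(atlas.label_ids))


class TestGrouping:
    def test_identity_and_all_in_one_groupings(self, small_phantom):
        atlas, _ = small_phantom
        one = LabelGrouping(["fg"], {lid: "fg" for lid in atlas.label_ids})
        maps = group_probabilities(atlas, one)
        np.testing.assert_allclose(maps["fg"], atlas.foreground_sum(), atol=1e-5)

        ident = LabelGrouping([f"r{lid}" for lid in atlas.label_ids],
                              {lid: f"r{lid}" for lid in atlas.label_ids})
        maps = group_probabilities(atlas, ident)
        for lid in atlas.label_ids:
            np.testing.assert_allclose(maps[f"r{lid}"], atlas.dense_map(lid))

    def test_grouping_conserves_mass(self, small_phantom):
        atlas, grouping = small_phantom
        maps = group_probabilities(atlas, grouping)
        total_c = sum(float(m.sum()) for m in maps.values())
        total_k = float(atlas.foreground_sum().sum())
        assert abs(total_c - total_k) <= 1e-5 * total_k

    def test_unmapped_label_is_an_error(self, small_phantom):
        atlas, _ = small_phantom
        bad = LabelGrouping(["c"], {atlas.label_ids[0]: "c"})
        with pytest.raises(AtlasValidationError):
            group_probabilities(atlas, bad)


class TestResample:
    def test_identity_warp_is_identity(self, small_phantom):
        atlas, grouping = small_phantom
        maps = group_probabilities(atlas, grouping)
        coords = np.indices(atlas.grid_shape, dtype=float)
        out = resample_probability_maps(maps, coords)
        for c in maps:
            assert np.abs(out[c] - maps[c]).max() < 1e-6

    def test_integer_translation_shifts_exactly(self, small_phantom):
        atlas, grouping = small_phantom
        maps = group_probabilities(atlas, grouping)
        coords = np.indices(atlas.grid_shape, dtype=float)
        coords[0] += 2.0  # sample from x+2: shifts content by -2
        out = resample_probability_maps(maps, coords)
        for c in maps:
            np.testing.assert_allclose(out[c][:-2], maps[c][2:], atol=1e-6)

    def test_warped_sums_stay_below_one(self, small_phantom, rng):
        atlas, grouping = small_phantom
        maps = group_probabilities(atlas, grouping)
        coords = np.indices(atlas.grid_shape, dtype=float)
        coords += rng.uniform(-1.5, 1.5, size=coords.shape)
        out = resample_probability_maps(maps, coords)
        total = sum(np.asarray(m, float) for m in out.values())
        assert total.max() <= 1 + 1e-5

    def test_nonfinite_coords_rejected(self, small_phantom):
        atlas, grouping = small_phantom
        maps = group_probabilities(atlas, grouping)
        coords = np.indices(atlas.grid_shape, dtype=float)
        coords[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            resample_probability_maps(maps, coords)
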