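"""EM over grouped classes, posterior redistribution, hard labels, volumes."""
import numpy as np
import pytest

from histoseg.atlas import LabelGrouping
from histoseg.em import (fit_gmm_em, hard_segmentation, redistribute_posteriors,
                         roi_volumes, working_resolution)
from histoseg.generative import GaussianParams


def _params(means, stds):
    classes = list(means)
    return GaussianParams(classes,
                          {c: np.array([1.0]) for c in classes},
                          {c: np.atleast_1d(np.asarray(means[c], float))
                           for c in classes},
                          {c: np.atleast_1d(np.asarray(stds[c], float))
                           for c in classes})


class TestFitGmmEm:
    def test_matching_init_is_a_fixed_point(self, rng):
        shape = (10, 10, 10)
        half = np.indices(shape)[0] >= 5
        x = np.where(half, 4.0, 2.0) + 0.0  # exactly at the class means
        priors = {"a": (~half).astype(float), "b": half.astype(float)}
        init = _params({"a": 2.0, "b": 4.0}, {"a": 0.5, "b": 0.5})
        params, _, hist = fit_gmm_em(x, priors, init, max_iter=1)
        assert params.means["a"][0] == pytest.approx(2.0, abs=1e-6)
        assert params.means["b"][0] == pytest.approx(4.0, abs=1e-6)

    def test_two_class_parameter_recovery(self, rng):
        shape = (24, 24, 24)
        half = np.indices(shape)[0] >= 12
        true_mu = {"a": 2.0, "b": 5.0}
        true_sd = {"a": 0.3, "b": 0.4}
        x = np.where(half, rng.normal(true_mu["b"], true_sd["b"], shape),
                     rng.normal(true_mu["a"], true_sd["a"], shape))
        soft = 0.5 + 0.4 * np.where(half, 1.0, -1.0)  # informative soft prior
        priors = {"a": 1 - soft, "b": soft}
        init = _params({"a": 2.5, "b": 4.5}, {"a": 0.6, "b": 0.6})
        params, resp, hist = fit_gmm_em(x, priors, init)
        for c in ("a", "b"):
            assert abs(params.means[c][0] - true_mu[c]) / true_mu[c] < 0.02
            assert abs(params.stds[c][0] - true_sd[c]) / true_sd[c] < 0.05
        # monotone mean log-likelihood
        h = np.asarray(hist)
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[:-1]))
        total = resp["a"] + resp["b"]
        assert np.abs(total - 1).max() < 1e-6

    def test_skip_subsampling_stable(self, rng):
        shape = (24, 24, 24)
        half = np.indices(shape)[0] >= 12
        x = np.where(half, rng.normal(5, 0.3, shape), rng.normal(2, 0.3, shape))
        priors = {"a": (~half).astype(float) * 0.9 + 0.05,
                  "b": half.astype(float) * 0.9 + 0.05}
        init = _params({"a": 2.4, "b": 4.6}, {"a": 0.5, "b": 0.5})
        p1, _, _ = fit_gmm_em(x, priors, init, skip=1)
        p2, _, _ = fit_gmm_em(x, priors, init, skip=2)
        for c in ("a", "b"):
            assert abs(p1.means[c][0] - p2.means[c][0]) / abs(p1.means[c][0]) < 0.01

    def test_empty_class_frozen_with_warning(self, rng):
        shape = (8, 8, 8)
        x = rng.normal(2, 0.3, shape)
        priors = {"a": np.ones(shape), "ghost": np.zeros(shape)}
        init = _params({"a": 2.0, "ghost": 9.0}, {"a": 0.5, "ghost": 0.5})
        with pytest.warns(UserWarning):
            params, _, _ = fit_gmm_em(x, priors, init, max_iter=3)
        assert params.means["ghost"][0] == 9.0


class TestRedistribute:
    def test_single_roi_class_gets_full_responsibility(self, rng):
        shape = (6, 6, 6)
        r = {"c": rng.uniform(0, 1, shape)}
        atlas_maps = {5: rng.uniform(0.1, 1, shape)}
        grouping = LabelGrouping(["c"], {5: "c"})
        fine = redistribute_posteriors(r, atlas_maps, grouping)
        np.testing.assert_allclose(fine[5], r["c"], atol=1e-6)

    def test_atlas_proportions_direct(self):
        shape = (2, 2, 2)
        r = {"c": np.full(shape, 0.8)}
        atlas_maps = {1: np.full(shape, 0.75), 2: np.full(shape, 0.25)}
        grouping = LabelGrouping(["c"], {1: "c", 2: "c"})
        fine = redistribute_posteriors(r, atlas_maps, grouping)
        np.testing.assert_allclose(fine[1], 0.6, atol=1e-6)
        np.testing.assert_allclose(fine[2], 0.2, atol=1e-6)

    def test_per_voxel_conservation_exhaustive(self, rng):
        shape = (7, 7, 7)
        classes = ["a", "b"]
        grouping = LabelGrouping(classes, {1: "a", 2: "a", 3: "b"})
        r = {c: rng.uniform(0, 0.5, shape) for c in classes}
        atlas_maps = {k: rng.uniform(0, 0.4, shape) for k in (1, 2, 3)}
        atlas_maps[2][0, 0, 0] = 0.0
        atlas_maps[1][0, 0, 0] = 0.0  # class a has zero atlas mass here
        fine = redistribute_posteriors(r, atlas_maps, grouping)
        got_a = fine[1] + fine[2]
        expect_a = np.where(atlas_maps[1] + atlas_maps[2] > 0, r["a"], 0.0)
        np.testing.assert_allclose(got_a, expect_a, atol=1e-6)
        np.testing.assert_allclose(fine[3],
                                   np.where(atlas_maps[3] > 0, r["b"], 0.0),
                                   atol=1e-6)


class TestHardAndVolumes:
    def test_single_roi_everywhere(self):
        shape = (4, 4, 4)
        fine = {3: np.ones(shape, np.float32)}
        hard = hard_segmentation(fine)
        np.testing.assert_array_equal(hard, 3)

    def test_tie_goes_to_lowest_label(self):
        shape = (3, 3, 3)
        fine = {5: np.full(shape, 0.5, np.float32),
                9: np.full(shape, 0.5, np.float32)}
        hard = hard_segmentation(fine)
        np.testing.assert_array_equal(hard, 5)

    def test_matches_bruteforce_argmax(self, rng):
        shape = (6, 6, 6)
        lids = [2, 4, 7]
        raw = rng.uniform(0, 0.5, (3, *shape))
        raw /= np.maximum(raw.sum(0), 1.0)[None]
        fine = {lid: raw[i].astype(np.float32) for i, lid in enumerate(lids)}
        hard = hard_segmentation(fine)
        bg = 1 - raw.sum(0)
        for _ in range(30):
            i, j, k = rng.integers(0, 6, 3)
            probs = {0: bg[i, j, k], **{lid: fine[lid][i, j, k] for lid in lids}}
            best = max(sorted(probs), key=lambda l: (probs[l], -l))
            # ties: lowest label, background wins exact ties with ROIs
            cand = [l for l in sorted(probs) if probs[l] == max(probs.values())]
            assert hard[i, j, k] == cand[0]

    def test_volume_arithmetic_and_linearity(self):
        shape = (10, 10, 10)
        p = np.zeros(shape, np.float32)
        p.reshape(-1)[:1000] = 1.0
        table = roi_volumes({1: p}, 0.4)
        assert table.volume_mm3.iloc[0] == pytest.approx(1000 * 0.4 ** 3)
        half = roi_volumes({1: p * 0.5}, 0.4)
        assert half.volume_mm3.iloc[0] == pytest.approx(table.volume_mm3.iloc[0] / 2)

    def test_working_resolution_rules(self):
        assert working_resolution("invivo", 1.0) == 0.4
        assert working_resolution("exvivo", 0.1) == 0.1
        assert working_resolution("exvivo", 0.5) == 0.2
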