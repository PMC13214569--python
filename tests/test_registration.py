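"""Registration components: similarity terms, affine init, Jacobian, warping."""
import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from histoseg.generative import membrane_energy
from histoseg.registration import (Deformation, RegistrationConfig, _smooth_vec,
                                   affine_initialize, jacobian_map, lncc,
                                   run_multiscale_registration, soft_dice)
from histoseg.types import ImageVolume


def _textured(shape, seed=0, sigma=2.0):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.standard_normal(shape), sigma)


class TestLncc:
    def test_self_similarity_is_one(self):
        img = _textured((20, 20, 20))
        assert lncc(img, img, 7) == pytest.approx(1.0, abs=1e-4)

    def test_affine_intensity_invariance(self):
        img = _textured((20, 20, 20))
        assert lncc(img, 3.0 * img + 7.0, 7) == pytest.approx(
            lncc(img, img, 7), abs=1e-3)
        assert lncc(img, -0.5 * img + 2.0, 7) == pytest.approx(
            lncc(img, img, 7), abs=1e-3)  # squared form: sign-blind too

    def test_independent_noise_scores_low(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((24, 24, 24))
        b = rng.standard_normal((24, 24, 24))
        assert lncc(a, b, 7) < 0.1


class TestSoftDice:
    def test_identical_soft_maps_are_one(self, rng):
        p = {1: rng.uniform(0, 1, (8, 8, 8)), 2: rng.uniform(0, 1, (8, 8, 8))}
        assert soft_dice(p, {k: v.copy() for k, v in p.items()}) == pytest.approx(
            1.0, abs=1e-6)

    def test_disjoint_binary_maps_are_zero(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[:3] = 1.0
        b[3:] = 1.0
        assert soft_dice({1: a}, {1: b}) == pytest.approx(0.0, abs=1e-9)

    def test_half_overlapping_cubes(self):
        p = np.zeros((8, 8, 8))
        q = np.zeros((8, 8, 8))
        p[0:4, 0:4, 0:4] = 1.0
        q[2:6, 0:4, 0:4] = 1.0
        assert soft_dice({1: p}, {1: q}) == pytest.approx(0.5, abs=1e-3)

    def test_matches_bruteforce_oracle(self, rng):
        p = {k: rng.uniform(0, 1, (6, 6, 6)) for k in (1, 2, 3)}
        q = {k: (rng.uniform(0, 1, (6, 6, 6)) > 0.5).astype(float) for k in (1, 2, 3)}
        vals = []
        for k in (1, 2, 3):
            vals.append(2 * (p[k] * q[k]).sum()
                        / ((p[k] ** 2).sum() + (q[k] ** 2).sum() + 1e-6))
        assert soft_dice(p, q) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_labels_skipped_and_all_empty_rejected(self):
        z = np.zeros((4, 4, 4))
        o = np.ones((4, 4, 4))
        assert soft_dice({1: o, 2: z}, {1: o, 2: z}) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            soft_dice({1: z}, {1: z})


class TestJacobian:
    def test_identity_is_one(self):
        det = jacobian_map(np.zeros((3, 8, 8, 8)))
        np.testing.assert_allclose(det, 1.0)
        assert np.abs(jacobian_map(np.zeros((3, 6, 6, 6)), log10=True)).max() < 1e-12

    def test_uniform_expansion_analytic(self):
        n = 10
        u = np.zeros((3, n, n, n))
        for c in range(3):
            u[c] = 0.1 * np.indices((n, n, n))[c]
        det = jacobian_map(u)
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], 1.1 ** 3, rtol=1e-9)


class TestAffineInit:
    @pytest.fixture(scope="class")
    def aligned_case(self, small_phantom):
        """Atlas protocol maps + an exactly-aligned coarse segmentation."""
        from histoseg.phantom import (corrupt_coarse_segmentation,
                                      phantom_protocol, sample_image)
        atlas, grouping = small_phantom
        _, truth = sample_image(atlas, grouping, max_displacement=1e-9, seed=3)
        r2p, names = phantom_protocol(atlas)
        coarse = corrupt_coarse_segmentation(truth.true_labels, r2p, names,
                                             0.0, 1, affine=atlas.affine)
        maps = {}
        for lid, pid in r2p.items():
            maps[pid] = maps.get(pid, 0) + atlas.dense_map(lid)
        return atlas, maps, coarse

    def test_identity_alignment(self, aligned_case):
        # coarse centroids jitter ~0.1 voxel because labels are stochastic
        # draws from the prior, so the fit is near- but not exactly identity
        atlas, maps, coarse = aligned_case
        A = affine_initialize(maps, atlas.affine, coarse.labels, coarse.affine)
        assert np.linalg.norm(A[:3, :3] - np.eye(3)) < 0.05
        assert np.linalg.norm(A[:3, 3]) < 0.25

    def test_translation_recovered(self, aligned_case):
        atlas, maps, coarse = aligned_case
        shifted = coarse.affine.copy()
        shifted[:3, 3] += [5.0, -3.0, 2.0]
        A = affine_initialize(maps, atlas.affine, coarse.labels, shifted)
        np.testing.assert_allclose(A[:3, 3], [5.0, -3.0, 2.0], atol=0.5)

    def test_isotropic_scale_recovered(self, aligned_case):
        atlas, maps, coarse = aligned_case
        scaled = coarse.affine.copy()
        scaled[:3, :3] *= 1.1
        A = affine_initialize(maps, atlas.affine, coarse.labels, scaled)
        s = np.linalg.norm(A[:3, :3], axis=0)
        np.testing.assert_allclose(s, 1.1, rtol=0.02)

    def test_too_few_structures_rejected(self, aligned_case):
        atlas, maps, coarse = aligned_case
        small = {k: maps[k] for k in list(maps)[:3]}
        labels = np.where(np.isin(coarse.labels, list(small)), coarse.labels, 0)
        with pytest.raises(ValueError):
            affine_initialize(small, atlas.affine, labels, coarse.affine)


class TestWarpField:
    def test_warp_smoothing_reduces_membrane_energy(self, rng):
        u = rng.standard_normal((3, 16, 16, 16))
        assert membrane_energy(_smooth_vec(u, 0.5)) <= membrane_energy(u)

    def test_deformation_validation(self):
        with pytest.raises(ValueError):
            Deformation(np.eye(4), np.full((3, 4, 4, 4), np.nan), np.eye(4))
        with pytest.raises(ValueError):
            Deformation(np.eye(4), np.zeros((4, 4, 4)), np.eye(4))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(cc_kernel_size=4)
        with pytest.raises(ValueError):
            RegistrationConfig(optimizer_lr=0.0)


class TestRunRegistration:
    def _small_problem(self, seed=0):
        shape = (24, 24, 24)
        img = _textured(shape, seed=seed, sigma=1.5)
        idx = np.indices(shape, dtype=float)
        mask = (((idx - 11.5) / 10.0) ** 2).sum(0) <= 1
        fixed = ImageVolume(np.where(mask, img, 0.0), np.eye(4), mask=mask)
        moving = ImageVolume(img, np.eye(4))
        return fixed, moving

    def test_identical_images_stay_put(self):
        shape = (24, 24, 24)
        img = _textured(shape, seed=0, sigma=1.5)
        idx = np.indices(shape, dtype=float)
        mask = (((idx - 11.5) / 10.0) ** 2).sum(0) <= 1
        fixed = ImageVolume(img, np.eye(4), mask=mask)
        moving = ImageVolume(img.copy(), np.eye(4))
        cfg = RegistrationConfig(iterations_per_level=20)
        d, diag = run_multiscale_registration(fixed, moving, {}, {}, np.eye(4), cfg)
        mag = np.sqrt((d.displacement ** 2).sum(0))
        assert mag[mask].mean() < 0.1
        assert diag["jacobian_positive_fraction"] > 0.999

    def test_determinism(self):
        fixed, moving = self._small_problem(seed=3)
        cfg = RegistrationConfig(iterations_per_level=15)
        d1, _ = run_multiscale_registration(fixed, moving, {}, {}, np.eye(4), cfg)
        d2, _ = run_multiscale_registration(fixed, moving, {}, {}, np.eye(4), cfg)
        assert np.abs(d1.displacement - d2.displacement).max() < 1e-5

    def test_small_translation_recovered(self):
        shape = (24, 24, 24)
        img = _textured(shape, seed=1, sigma=1.5)
        shifted = map_coordinates(img, np.indices(shape, float)
                                  + np.array([1.5, 0, 0]).reshape(3, 1, 1, 1),
                                  order=1, mode="nearest")
        idx = np.indices(shape, dtype=float)
        mask = (((idx - 11.5) / 9.0) ** 2).sum(0) <= 1
        fixed = ImageVolume(shifted, np.eye(4), mask=mask)
        moving = ImageVolume(img, np.eye(4))
        cfg = RegistrationConfig(iterations_per_level=60)
        d, _ = run_multiscale_registration(fixed, moving, {}, {}, np.eye(4), cfg)
        err = d.displacement - np.array([1.5, 0, 0]).reshape(3, 1, 1, 1)
        assert np.sqrt((err ** 2).sum(0))[mask].mean() < 0.75
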