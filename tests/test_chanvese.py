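import numpy as np
import pytest

from follicleseg.chanvese import (
    CVParams,
    DegenerateInitError,
    NumericalFailureError,
    energy_value,
    evolve,
    init_classical,
    init_from_mask,
    region_means,
    segment,
)


class TestInitFromMask:
    def test_disk_distance_geometry(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 10**2
        phi = init_from_mask(disk)
        assert phi[32, 32] == pytest.approx(10, abs=0.6)
        assert phi[0, 0] < 0
        assert ((phi > 0) == disk).all()

    def test_gradient_magnitude_near_one(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2
        phi = init_from_mask(disk)
        gy, gx = np.gradient(phi)
        mag = np.sqrt(gx**2 + gy**2)
        away = np.abs(phi) > 2
        assert np.median(mag[away]) == pytest.approx(1.0, abs=0.1)

    def test_degenerate_masks_raise(self):
        with pytest.raises(DegenerateInitError):
            init_from_mask(np.zeros((8, 8), dtype=bool))
        with pytest.raises(DegenerateInitError):
            init_from_mask(np.ones((8, 8), dtype=bool))


class TestInitClassical:
    def test_positive_region_is_inset_rectangle(self):
        phi = init_classical((100, 100))
        pos = phi > 0
        expect = np.zeros((100, 100), dtype=bool)
        expect[5:95, 5:95] = True
        assert (pos == expect).all()

    def test_flip_symmetry(self):
        phi = init_classical((80, 60))
        assert np.allclose(phi, phi[::-1, :])
        assert np.allclose(phi, phi[:, ::-1])

    def test_degenerate_inset_still_valid(self):
        phi = init_classical((100, 100), inset_frac=0.5)
        assert np.isfinite(phi).all() and (phi > 0).any()


class TestRegionMeans:
    def test_piecewise_constant_limit(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 15**2
        img = np.where(disk, 0.1, 0.9)
        phi = init_from_mask(disk) * 1000.0  # drive Heaviside to hard limit
        c1, c2 = region_means(img, phi)
        assert c1 == pytest.approx(0.1, abs=1e-3)
        assert c2 == pytest.approx(0.9, abs=1e-3)

    def test_constant_image(self):
        phi = init_classical((32, 32))
        c1, c2 = region_means(np.full((32, 32), 0.4), phi)
        assert c1 == pytest.approx(0.4, abs=1e-12)
        assert c2 == pytest.approx(0.4, abs=1e-12)

    def test_matches_direct_weighted_sums(self, rng):
        img = rng.random((8, 8))
        phi = rng.normal(size=(8, 8))
        c1, c2 = region_means(img, phi, epsilon=1.0)
        h = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / 1.0))
        assert c1 == pytest.approx((img * h).sum() / h.sum(), abs=1e-12)
        assert c2 == pytest.approx((img * (1 - h)).sum() / (1 - h).sum(), abs=1e-12)


class TestEvolve:
    def test_true_partition_is_fixed_point(self, disk_image):
        img, disk = disk_image
        st = evolve(img, init_from_mask(disk), CVParams())
        assert ((st.phi > 0) == disk).all()

    def test_pure_curvature_flow_shrinks_area(self, disk_image):
        _, disk = disk_image
        img = np.full(disk.shape, 0.5)
        phi = init_from_mask(disk)
        params = CVParams(n_iter=1, reinit_every=0)
        areas = []
        for _ in range(60):
            st = evolve(img, phi, params)
            phi = st.phi
            areas.append((phi > 0).sum())
        diffs = np.diff(areas)
        assert (diffs <= 0).all()
        assert areas[-1] < areas[0]

    def test_inversion_symmetry_with_lambda_swap(self, disk_image):
        img, disk = disk_image
        phi0 = init_from_mask(disk)
        a = evolve(img, phi0, CVParams(lambda1=1.0, lambda2=2.0, reinit_every=0, n_iter=60))
        b = evolve(1.0 - img, -phi0, CVParams(lambda1=2.0, lambda2=1.0, reinit_every=0, n_iter=60))
        assert ((a.phi > 0) == (b.phi < 0)).all()

    def test_translation_equivariance(self):
        h = w = 96
        rr, cc = np.mgrid[0:h, 0:w]
        disk = (rr - 40) ** 2 + (cc - 40) ** 2 <= 10**2
        img = np.where(disk, 0.2, 0.8)
        params = CVParams(n_iter=100)
        m0 = evolve(img, init_from_mask(disk), params).phi > 0
        dy, dx = 7, 5
        disk_s = np.roll(np.roll(disk, dy, axis=0), dx, axis=1)
        img_s = np.where(disk_s, 0.2, 0.8)
        m1 = evolve(img_s, init_from_mask(disk_s), params).phi > 0
        assert (np.roll(np.roll(m0, dy, axis=0), dx, axis=1) == m1).all()

    def test_zero_regularization_means_are_plain_averages(self, rng, disk_image):
        img, disk = disk_image
        noisy = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
        phi = init_from_mask(disk) * 1000.0
        st = evolve(noisy, phi, CVParams(mu=0.0, nu=0.0, n_iter=1, reinit_every=0))
        assert st.c1 == pytest.approx(noisy[disk].mean(), abs=1e-3)
        assert st.c2 == pytest.approx(noisy[~disk].mean(), abs=1e-3)

    def test_non_finite_input_raises_with_iteration(self, disk_image):
        img, disk = disk_image
        phi0 = init_from_mask(disk).astype(np.float64)
        phi0[0, 0] = np.inf
        with pytest.raises(NumericalFailureError):
            evolve(img, phi0, CVParams(n_iter=3))

    def test_energy_value_components(self, disk_image):
        img, disk = disk_image
        phi = init_from_mask(disk) * 1e3  # hard-limit Heaviside
        p = CVParams(mu=0.0, nu=0.0)
        e = energy_value(img, phi, 0.2, 0.8, p)
        # fidelity-only energy of the true partition vanishes in the sharp limit
        assert e < 1.0


class TestSegment:
    def test_binary_image_hybrid_exact(self):
        rr, cc = np.mgrid[0:96, 0:96]
        blobs = ((rr - 30) ** 2 + (cc - 30) ** 2 <= 12**2) | (
            (rr - 65) ** 2 + (cc - 60) ** 2 <= 9**2
        )
        img = np.where(blobs, 0, 255).astype(np.uint8)
        assert (segment(img, "hybrid", preprocessed=True) == blobs).all()

    def test_hybrid_fixed_point_when_otsu_seed_is_truth(self):
        from follicleseg.phantom import apply_preset, generate

        img, gt = generate(apply_preset("clean", seed=3))
        assert (segment(img, "hybrid", preprocessed=True) == gt).all()

    def test_noisy_disk_recovery(self):
        rng = np.random.default_rng(7)
        rr, cc = np.mgrid[0:96, 0:96]
        disk = (rr - 48) ** 2 + (cc - 48) ** 2 <= 20**2
        x = np.where(disk, 0.2, 0.8) + rng.normal(0, 0.1, (96, 96))
        img = np.clip(np.rint(x * 255), 0, 255).astype(np.uint8)
        mask = segment(img, "hybrid", preprocessed=True)
        tp = (mask & disk).sum()
        dice = 2 * tp / (mask.sum() + disk.sum())
        assert dice >= 0.95

    def test_foreground_is_darker_phase(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 14**2
        img = np.where(disk, 30, 220).astype(np.uint8)
        mask = segment(img, "hybrid", preprocessed=True)
        assert img[mask].mean() < img[~mask].mean()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInitError):
            segment(np.full((32, 32), 128, dtype=np.uint8), "hybrid", preprocessed=True)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            segment(np.zeros((32, 32), dtype=np.uint8), "banana")


def test_params_validation():
    with pytest.raises(ValueError):
        CVParams(mu=-1)
    with pytest.raises(ValueError):
        CVParams(lambda1=0)
    with pytest.raises(ValueError):
        CVParams(dt=0)
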