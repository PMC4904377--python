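"""Phantom generators, projection, and the Poisson/Gaussian noise models."""

import numpy as np
import pytest

import csetomo as cs
from csetomo.exceptions import DegenerateInputError, InvalidParameterError
from csetomo.phantoms import projected_background_level


SMALL_SPEC = cs.MembranePhantomSpec(
    dims=(48, 12, 48),
    n_shells=5,
    n_filled=7,
    semiaxis_range=(2.0, 14.0),
    shell_thickness_range=(1.0, 2.0),
    seed=11,
)


class TestMembranePhantom:
    def test_values_bounded_with_positive_background(self, tiny_membrane_volume):
        v = tiny_membrane_volume.voxels
        assert v.min() == pytest.approx(0.15)
        assert v.max() <= 1.0
        assert v.min() > 0

    def test_reproducible_and_seed_sensitive(self):
        a = cs.make_membrane_phantom(SMALL_SPEC)
        b = cs.make_membrane_phantom(SMALL_SPEC)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = cs.make_membrane_phantom(
            cs.MembranePhantomSpec(**{**SMALL_SPEC.__dict__, "seed": 12})
        )
        assert not np.array_equal(a.voxels, c.voxels)

    def test_spec_validation(self):
        with pytest.raises(InvalidParameterError):
            cs.MembranePhantomSpec(background=0.0)
        with pytest.raises(InvalidParameterError):
            cs.MembranePhantomSpec(semiaxis_range=(5.0, 5.0))

    def test_unplaceable_structures_rejected(self):
        spec = cs.MembranePhantomSpec(
            dims=(8, 8, 8), n_shells=1, n_filled=0, semiaxis_range=(50.0, 60.0)
        )
        with pytest.raises(InvalidParameterError):
            cs.make_membrane_phantom(spec)


class TestNanoparticlePhantom:
    def test_empty_request_gives_zero_slice(self):
        s = cs.make_nanoparticle_phantom((64, 64), 0, 0, seed=1)
        assert np.all(s.pixels == 0)

    def test_piecewise_constant_value_count(self):
        s = cs.make_nanoparticle_phantom((128, 128), 4, 2, seed=5)
        distinct = np.unique(s.pixels)
        assert len(distinct) <= 1 + 6

    def test_nanoparticle_sparser_than_membrane_in_identity_domain(self, tiny_membrane_volume):
        nano = cs.make_nanoparticle_phantom((64, 64), 3, 1, seed=2, radius_range=(4.0, 10.0))
        membrane_slice = tiny_membrane_volume.xz_slice(3).pixels
        r_nano = cs.compressibility_ratio(nano.pixels, 5.0, "identity")
        r_mem = cs.compressibility_ratio(membrane_slice, 5.0, "identity")
        assert r_nano < r_mem

    def test_overcrowding_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.make_nanoparticle_phantom((64, 64), 40, 0, seed=1, radius_range=(14.0, 16.0))


class TestSparsityOrdering:
    def test_membrane_between_nanoparticle_and_noise(self, tiny_membrane_volume):
        """The compressibility ordering underlying the CS argument:
        nanoparticle < membrane < pure noise, averaged per domain (membrane
        identity ratios after background subtraction, as in the evaluation
        protocol)."""
        rng = np.random.default_rng(0)
        nano = [
            cs.make_nanoparticle_phantom((48, 48), 3, 1, seed=s, radius_range=(3.0, 8.0)).pixels
            for s in range(3)
        ]
        mem = [tiny_membrane_volume.xz_slice(j).pixels[:48, :48] - 0.15 for j in range(3)]
        noise = [rng.normal(size=(48, 48)) for _ in range(3)]
        for domain in ("TV", "identity", "wavelet"):
            r = lambda group: np.mean(
                [cs.compressibility_ratio(x, 5.0, domain) for x in group]
            )
            assert r(nano) < r(mem) < r(noise)


class TestProjection:
    def test_zero_volume_projects_to_zero(self, coarse_angles):
        v = cs.Volume3D(np.zeros((16, 3, 16)))
        sinos = cs.project_volume(v, coarse_angles)
        assert len(sinos) == 3
        assert all(np.all(s.data == 0) for s in sinos)

    def test_single_slice_volume_matches_slice_projection(self, rng, coarse_angles):
        sl = rng.random((16, 16))
        v = cs.Volume3D(sl[:, None, :])
        sinos = cs.project_volume(v, coarse_angles)
        direct = cs.radon_forward(sl, coarse_angles)
        np.testing.assert_allclose(sinos[0].data, direct.data, atol=1e-10)

    def test_projection_conserves_slice_mass(self, rng, coarse_angles):
        # support inside the inscribed disc so no mass leaves the detector
        n = 24
        xx, zz = np.meshgrid(*(np.arange(n) - (n - 1) / 2,) * 2, indexing="ij")
        sl = np.where(xx**2 + zz**2 < 9**2, rng.random((n, n)), 0.0)
        v = cs.Volume3D(np.stack([sl, 0.5 * sl], axis=1))
        for j, s in enumerate(cs.project_volume(v, coarse_angles)):
            np.testing.assert_allclose(
                s.data.sum(axis=1), v.voxels[:, j, :].sum(), rtol=1e-4
            )


class TestNoiseModels:
    def test_zero_sinogram_nanoparticle_mode_passes_through(self, coarse_angles):
        y = cs.Sinogram(np.zeros((len(coarse_angles), 16)), coarse_angles)
        out = cs.add_poisson_gaussian_noise(y, cs.NoiseSpec(seed=1), "nanoparticle")
        assert np.all(out.data == 0)

    def test_high_rate_limit_recovers_input(self, rng, coarse_angles):
        data = rng.random((len(coarse_angles), 32)) + 0.5
        y = cs.Sinogram(data, coarse_angles)
        ns = cs.NoiseSpec(poisson_rate=1e9, gaussian_frac=0.0, seed=3)
        out = cs.add_poisson_gaussian_noise(y, ns, "nanoparticle")
        assert np.max(np.abs(out.data - data)) < 1e-3 * data.mean()

    def test_nanoparticle_noise_matches_closed_form_variance(self):
        # pooled variance of (noisy - clean) should equal
        # mean(y)^2 * (1/rate + gaussian_frac^2) for the scale-sample-rescale
        # Poisson stage plus the additive Gaussian stage
        angles = cs.make_uniform_angles(70, 2)
        phantom = cs.make_nanoparticle_phantom((160, 160), 4, 2, seed=8, radius_range=(8.0, 24.0))
        y = cs.radon_forward(phantom, angles)
        ns = cs.NoiseSpec(poisson_rate=5500.0, gaussian_frac=0.10, seed=7)
        out = cs.add_poisson_gaussian_noise(y, ns, "nanoparticle")
        diff = (out.data - y.data).ravel()
        n = diff.size
        assert n >= 10_000
        mean_y = y.data.mean()
        predicted = mean_y**2 * (1.0 / 5500.0 + 0.01)
        emp_var = diff.var()
        m4 = np.mean((diff - diff.mean()) ** 4)
        se = np.sqrt(max(m4 - emp_var**2, 0.0) / n)
        assert abs(emp_var - predicted) < 3 * se

    def test_membrane_calibration_closed_form(self, coarse_angles):
        c = 40.0
        y = cs.Sinogram(np.full((len(coarse_angles), 16), c), coarse_angles)
        s = cs.calibrate_membrane_noise(y, 0.1, 0.0)
        assert s == pytest.approx(1.0 / (0.1**2 * c))
        # doubling the target quarters the scale
        assert cs.calibrate_membrane_noise(y, 0.2, 0.0) == pytest.approx(s / 4.0)

    def test_membrane_noise_closure(self, tiny_membrane_volume):
        angles = cs.make_uniform_angles(70, 2)
        sl = tiny_membrane_volume.xz_slice(2)
        y = cs.radon_forward(sl, angles)
        bg = projected_background_level(sl.shape, angles, 0.15)
        ns = cs.NoiseSpec(target_frac=0.10, background_level=bg, seed=5)
        out = cs.add_poisson_gaussian_noise(y, ns, "membrane")
        achieved = np.std(out.data - y.data) / np.mean(y.data - bg)
        assert achieved == pytest.approx(0.10, rel=0.10)

    def test_noise_preserves_shape_and_angles(self, rng, coarse_angles):
        y = cs.Sinogram(rng.random((len(coarse_angles), 16)), coarse_angles)
        out = cs.add_poisson_gaussian_noise(y, cs.NoiseSpec(seed=0), "nanoparticle")
        assert out.data.shape == y.data.shape
        assert out.angles is y.angles

    def test_negative_sinogram_rejected(self, coarse_angles):
        y = cs.Sinogram(np.full((len(coarse_angles), 8), -1.0), coarse_angles)
        with pytest.raises(InvalidParameterError):
            cs.add_poisson_gaussian_noise(y, cs.NoiseSpec(), "nanoparticle")

    def test_degenerate_membrane_target_rejected(self, coarse_angles):
        y = cs.Sinogram(np.full((len(coarse_angles), 8), 2.0), coarse_angles)
        with pytest.raises(DegenerateInputError):
            cs.calibrate_membrane_noise(y, 0.1, 5.0)

    def test_seeded_reproducibility(self, rng, coarse_angles):
        y = cs.Sinogram(rng.random((len(coarse_angles), 16)) + 1.0, coarse_angles)
        a = cs.add_poisson_gaussian_noise(y, cs.NoiseSpec(seed=9), "nanoparticle")
        b = cs.add_poisson_gaussian_noise(y, cs.NoiseSpec(seed=9), "nanoparticle")
        np.testing.assert_array_equal(a.data, b.data)
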