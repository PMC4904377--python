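"""Split-Bregman CS-ET solver: presets, oracles and invariants."""

import numpy as np
import pytest

import csetomo as cs
from csetomo.exceptions import InvalidParameterError
from csetomo.geometry import radon_operator
from csetomo.solver import _split_bregman_batch


class TestWeightPresets:
    @pytest.mark.parametrize(
        "modality, k, nu, mults",
        [
            ("bright_field", 1, 5e-6, (1.2, 6, 4)),
            ("bright_field", 3, 1e-5, (1.2, 6, 4)),
            ("bright_field", 6, 1e-5, (1.2, 6, 4)),
            ("dark_field", 1, 1e-6, (4, 8, 10)),
            ("dark_field", 3, 1e-6, (6, 2, 6)),
            ("dark_field", 6, 1e-6, (4, 2, 4)),
        ],
    )
    def test_experimental_presets(self, modality, k, nu, mults):
        w = cs.default_weights(modality, k)
        assert w.nu == pytest.approx(nu)
        assert (w.lambda_tv, w.lambda_i, w.lambda_w) == pytest.approx(
            (nu * mults[0], nu * mults[1], nu * mults[2])
        )

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.default_weights("phase_contrast", 1)
        with pytest.raises(InvalidParameterError):
            cs.default_weights("bright_field", 2)

    def test_weight_validation(self):
        with pytest.raises(InvalidParameterError):
            cs.RegWeights(0.0)
        with pytest.raises(InvalidParameterError):
            cs.RegWeights(1.0, -0.1)

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            cs.SolverConfig(outer_iters=0)
        with pytest.raises(InvalidParameterError):
            cs.SolverConfig(cg_tol=0.0)
        with pytest.raises(InvalidParameterError):
            cs.SolverConfig(tv_mode="huber")


class TestSliceReconstruction:
    def test_zero_sinogram_gives_zero_image_and_traces(self, coarse_angles):
        y = cs.Sinogram(np.zeros((len(coarse_angles), 16)), coarse_angles)
        w = cs.RegWeights(1.0, 1.0, 1.0, 1.0)
        res = cs.cset_reconstruct_slice(y, (16, 16), w)
        assert np.all(res.image.pixels == 0)
        assert np.all(res.objective_trace == 0)
        assert np.all(res.data_residual_trace == 0)
        assert res.objective_trace.shape == (10,)

    def test_unregularized_solver_matches_least_squares_oracle(self, rng):
        angles = cs.make_uniform_angles(70, 2)
        f = rng.random((16, 16))
        y = cs.radon_forward(f, angles)
        cfg = cs.SolverConfig(outer_iters=1, inner_iters=1, cg_iters=2000, cg_tol=1e-14)
        res = cs.cset_reconstruct_slice(y, (16, 16), cs.RegWeights(1.0), cfg)
        A = radon_operator((16, 16), angles).matrix.toarray()
        f_ls, *_ = np.linalg.lstsq(A, y.data.ravel(), rcond=None)
        rel = np.linalg.norm(res.image.pixels.ravel() - f_ls) / np.linalg.norm(f_ls)
        assert rel < 1e-3

    def test_minimizer_invariant_under_common_weight_rescaling(self, rng, coarse_angles):
        y = cs.Sinogram(cs.radon_forward(rng.random((32, 32)), coarse_angles).data, coarse_angles)
        w = cs.RegWeights(1.0, 2.0, 0.5, 0.8)
        a = cs.cset_reconstruct_slice(y, (32, 32), w).image.pixels
        b = cs.cset_reconstruct_slice(y, (32, 32), w.scaled(10.0)).image.pixels
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-3

    def test_noiseless_two_disc_phantom_recovered(self):
        n = 32
        xx, zz = np.meshgrid(*(np.arange(n) - (n - 1) / 2,) * 2, indexing="ij")
        img = np.zeros((n, n))
        img[(xx + 6) ** 2 + (zz + 4) ** 2 < 5**2] = 1.0
        img[(xx - 5) ** 2 + (zz - 5) ** 2 < 6**2] = 0.6
        y = cs.radon_forward(img, cs.make_uniform_angles(70, 2))
        w = cs.RegWeights(1.0, 0.05, 0.0, 0.0)  # small TV weight
        res = cs.cset_reconstruct_slice(y, (n, n), w, cs.SolverConfig(cg_iters=30))
        rel_rmse = np.linalg.norm(res.image.pixels - img) / np.linalg.norm(img)
        assert rel_rmse < 0.05

    def test_noiseless_data_residual_strictly_below_initial(self, disc_slice, coarse_angles):
        y = cs.radon_forward(disc_slice, coarse_angles)
        w = cs.RegWeights(1.0, 5.0, 1.0, 1.0)
        res = cs.cset_reconstruct_slice(y, disc_slice.shape, w)
        assert res.data_residual_trace[-1] < np.linalg.norm(y.data)

    def test_deterministic_bitwise(self, rng, coarse_angles):
        y = cs.Sinogram(cs.radon_forward(rng.random((16, 16)), coarse_angles).data, coarse_angles)
        w = cs.RegWeights(1.0, 2.0, 0.5, 0.8)
        a = cs.cset_reconstruct_slice(y, (16, 16), w)
        b = cs.cset_reconstruct_slice(y, (16, 16), w)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.objective_trace, b.objective_trace)

    def test_inconsistent_shape_rejected(self, coarse_angles):
        y = cs.Sinogram(np.zeros((len(coarse_angles), 16)), coarse_angles)
        with pytest.raises(InvalidParameterError):
            cs.cset_reconstruct_slice(y, (32, 32), cs.RegWeights(1.0))


class _DenseOp:
    """Dense-matrix measurement operator for oracle harnesses."""

    def __init__(self, A):
        self.A = A

    def forward(self, F):
        return self.A @ F

    def adjoint(self, Y):
        return self.A.T @ Y


def _fista_lasso(A, y, nu, lam, iters=20000):
    """Proximal-gradient (FISTA) reference for min (nu/2)|Af-y|^2 + lam|f|_1."""
    L = nu * np.linalg.norm(A, 2) ** 2
    x = np.zeros(A.shape[1])
    z, t = x.copy(), 1.0
    for _ in range(iters):
        grad = nu * A.T @ (A @ z - y)
        step = z - grad / L
        xn = np.sign(step) * np.maximum(np.abs(step) - lam / L, 0)
        tn = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = xn + (t - 1) / tn * (xn - x)
        x, t = xn, tn
    return x


def test_identity_regularized_solver_matches_proximal_gradient(rng):
    # with only the identity l1 term and a single outer sweep the inner
    # iteration converges to the lasso solution on a dense random system
    A = rng.normal(size=(40, 64)) / 8
    x_true = np.where(rng.random(64) < 0.2, rng.normal(size=64), 0.0)
    y = A @ x_true + 0.01 * rng.normal(size=40)
    nu, lam = 1.0, 0.05
    cfg = cs.SolverConfig(outer_iters=1, inner_iters=400, cg_iters=100, cg_tol=1e-12)
    F, _, _ = _split_bregman_batch(
        _DenseOp(A), y.reshape(-1, 1), (8, 8), cs.RegWeights(nu, 0.0, lam, 0.0), cfg
    )
    ref = _fista_lasso(A, y, nu, lam)
    assert np.linalg.norm(F[:, 0] - ref) / np.linalg.norm(ref) < 1e-3


class TestQuadraticSubproblem:
    def test_recovers_preimage_of_dense_normal_operator(self, rng):
        angles = cs.AngleSet(np.array([-50.0, -10.0, 20.0, 65.0]))
        op = radon_operator((8, 8), angles)
        w = cs.RegWeights(0.7, 0.3, 0.2, 0.1)
        x = rng.normal(size=(8, 8))
        # rhs = Ax computed through the same operator pieces
        import csetomo.transforms as tr

        F = x.reshape(64, 1)
        rhs = w.nu * op.adjoint(op.forward(F))
        rhs += w.lambda_tv * (-tr.div2d(tr.grad2d(x.reshape(8, 8, 1)))).reshape(64, 1)
        rhs += (w.lambda_i + w.lambda_w) * F
        sol = cs.solve_quadratic_subproblem(
            rhs.reshape(8, 8), w, op, cfg=cs.SolverConfig(cg_iters=500, cg_tol=1e-14)
        )
        assert np.linalg.norm(sol - x) / np.linalg.norm(x) < 1e-4

    def test_zero_rhs_zero_warm_start_returns_zero(self):
        op = radon_operator((8, 8), cs.AngleSet(np.array([0.0, 45.0])))
        sol = cs.solve_quadratic_subproblem(np.zeros((8, 8)), cs.RegWeights(1.0, 1.0, 1.0, 1.0), op)
        assert np.all(sol == 0)

    def test_cg_residual_nonincreasing(self, rng):
        angles = cs.AngleSet(np.array([-50.0, -10.0, 20.0, 65.0]))
        op = radon_operator((8, 8), angles)
        w = cs.RegWeights(1.0, 0.5, 0.3, 0.0)
        rhs = rng.normal(size=(8, 8))
        import csetomo.transforms as tr

        def apply_A(v):
            F = v.reshape(64, 1)
            out = w.nu * op.adjoint(op.forward(F))
            out += w.lambda_tv * (-tr.div2d(tr.grad2d(v.reshape(8, 8, 1)))).reshape(64, 1)
            out += w.lambda_i * F
            return out.ravel()

        prev = np.inf
        for iters in (1, 3, 6, 12, 25, 50):
            sol = cs.solve_quadratic_subproblem(
                rhs, w, op, cfg=cs.SolverConfig(cg_iters=iters, cg_tol=1e-15)
            )
            r = np.linalg.norm(rhs.ravel() - apply_A(sol.ravel()))
            assert r <= prev + 1e-9
            prev = r

    def test_nonfinite_rhs_rejected(self):
        op = radon_operator((8, 8), cs.AngleSet(np.array([0.0])))
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(InvalidParameterError):
            cs.solve_quadratic_subproblem(bad, cs.RegWeights(1.0), op)


class TestVolumeReconstruction:
    def test_workers_do_not_change_results(self, tiny_membrane_volume, coarse_angles):
        sinos = cs.project_volume(tiny_membrane_volume, coarse_angles)
        w = cs.RegWeights(1.0, 5.0, 1.0, 1.0)
        cfg = cs.SolverConfig(outer_iters=2, inner_iters=3, cg_iters=5)
        v1, _ = cs.cset_reconstruct_volume(sinos, w, cfg, workers=1)
        v4, _ = cs.cset_reconstruct_volume(sinos, w, cfg, workers=4)
        assert np.array_equal(v1.voxels, v4.voxels)

    def test_zero_sinograms_give_zero_volume(self, coarse_angles):
        sinos = [cs.Sinogram(np.zeros((len(coarse_angles), 16)), coarse_angles) for _ in range(3)]
        vol, diags = cs.cset_reconstruct_volume(sinos, cs.RegWeights(1.0, 1.0, 0.0, 0.0))
        assert np.all(vol.voxels == 0)
        assert len(diags) == 3

    def test_heterogeneous_angle_sets_rejected(self, coarse_angles):
        other = cs.make_uniform_angles(70, 14)
        sinos = [
            cs.Sinogram(np.zeros((len(coarse_angles), 16)), coarse_angles),
            cs.Sinogram(np.zeros((len(other), 16)), other),
        ]
        with pytest.raises(InvalidParameterError):
            cs.cset_reconstruct_volume(sinos, cs.RegWeights(1.0))

    def test_volume_beats_wbp_on_undersampled_noiseless_phantom(self, tiny_membrane_volume):
        angles = cs.undersample_angles(cs.make_uniform_angles(70, 2), 6)
        sinos = cs.project_volume(tiny_membrane_volume, angles)
        w = cs.RegWeights(1.0, 60.0, 6.0, 10.0)
        vol, _ = cs.cset_reconstruct_volume(sinos, w, cs.SolverConfig(cg_iters=5))
        wbp = np.stack(
            [cs.wbp_reconstruct(s, (32, 32)).pixels for s in sinos], axis=1
        )
        truth = tiny_membrane_volume.voxels
        assert cs.rmse(vol.voxels, truth) < cs.rmse(wbp, truth)
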