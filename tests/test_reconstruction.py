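"""2D FEM forward model, adjoint Jacobian, Tikhonov inverse,
cross-validated hyperparameter and noise-based correction."""

import dataclasses

import numpy as np
import pytest

from eitproc.protocol import InjectionProtocol
from eitproc.reconstruction import (
    ForwardModel,
    Mesh2D,
    default_lambda_grid,
    disc_mesh,
    noise_correction,
    reconstruct,
    select_lambda_cv,
    tikhonov_inverse,
)


def element_neighbour_region(mesh, patch, extra_radius):
    cent = mesh.centroids()
    pc = cent[patch].mean(axis=0)
    return np.flatnonzero(np.linalg.norm(cent - pc, axis=1) < extra_radius)


class TestMesh:
    def test_degenerate_triangle_rejected(self):
        nodes = np.array([[0, 0], [1, 0], [2, 0], [0, 1]])
        with pytest.raises(ValueError, match="degenerate|clockwise"):
            Mesh2D(nodes, np.array([[0, 1, 2]]), np.array([0]))

    def test_clockwise_triangle_rejected(self):
        nodes = np.array([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError):
            Mesh2D(nodes, np.array([[0, 2, 1]]), np.array([0]))

    def test_text_file_round_trip(self, disc16, tmp_path):
        node_p, ele_p = tmp_path / "m.node", tmp_path / "m.ele"
        disc16.write(node_p, ele_p)
        back = Mesh2D.read(node_p, ele_p, disc16.electrode_nodes)
        np.testing.assert_allclose(back.nodes, disc16.nodes)
        np.testing.assert_array_equal(back.triangles, disc16.triangles)
        np.testing.assert_allclose(back.conductivity, disc16.conductivity)


class TestForwardSolve:
    def test_mirror_symmetry_on_homogeneous_disc(self, disc16, protocol16):
        """Injection through diametrically opposite electrodes on the x-axis:
        voltages are antisymmetric under the disc's mirror symmetry."""
        fm = ForwardModel(disc16, InjectionProtocol(((1, 9),), 16))
        v = fm.forward_solve((1, 9), 1.0)
        # electrode k at angle 2*pi*(k-1)/16; mirror in x maps k -> 18-k
        for e in range(2, 9):
            mirror = 18 - e
            assert abs(v[e - 1] - v[mirror - 1]) < 1e-10 * np.abs(v).max()

    def test_reciprocity_to_1e12(self, forward16, protocol16):
        v = forward16.boundary_voltages(1.0)
        scale = np.abs(v).max()
        for a, (i, j) in enumerate(protocol16.pairs):
            for b, (k, l) in enumerate(protocol16.pairs):
                if a >= b or not {i, j}.isdisjoint({k, l}):
                    continue
                v_ab = v[a, k - 1] - v[a, l - 1]
                v_ba = v[b, i - 1] - v[b, j - 1]
                assert abs(v_ab - v_ba) < 1e-12 * scale

    def test_doubling_conductivity_halves_voltages(self, disc16, protocol16):
        fm1 = ForwardModel(disc16, protocol16)
        mesh2 = Mesh2D(
            disc16.nodes, disc16.triangles, disc16.electrode_nodes,
            2.0 * disc16.conductivity,
        )
        fm2 = ForwardModel(mesh2, protocol16)
        np.testing.assert_allclose(
            fm2.boundary_voltages(1.0), 0.5 * fm1.boundary_voltages(1.0), rtol=1e-12
        )


class TestJacobian:
    def test_against_finite_difference_oracle(self, disc16, protocol16, jacobian16):
        """Every column of the adjoint Jacobian matches brute-force
        perturbation of that element's conductivity."""
        J = jacobian16 / 100e-6  # per unit current
        fm = ForwardModel(disc16, protocol16)
        v0 = fm.boundary_voltages(1.0).ravel()
        eps = 1e-6
        scale = np.abs(J).max()
        for e in range(disc16.n_elements):
            sigma = disc16.conductivity.copy()
            sigma[e] += eps
            fm_e = ForwardModel(
                Mesh2D(disc16.nodes, disc16.triangles, disc16.electrode_nodes, sigma),
                protocol16,
            )
            fd = (fm_e.boundary_voltages(1.0).ravel() - v0) / eps
            assert np.abs(fd - J[:, e]).max() < 1e-4 * scale

    def test_sensitivity_sum_identity(self, disc16, jacobian16, forward16):
        """sum_e J[m,e] sigma_e = -V_m for homogeneous conductivity."""
        v = forward16.boundary_voltages().ravel()
        lhs = jacobian16 @ disc16.conductivity
        np.testing.assert_allclose(lhs, -v, rtol=1e-10, atol=1e-15 * np.abs(v).max())

    def test_far_elements_less_sensitive_than_near(self, disc16, jacobian16):
        cent = disc16.centroids()
        m = 0  # first measurement row: pair (1,2)-ish drive, electrode 1
        e1 = disc16.nodes[disc16.electrode_nodes[0]]
        near = np.argmin(np.linalg.norm(cent - e1, axis=1))
        far = np.argmin(np.linalg.norm(cent, axis=1))  # centre of the disc
        assert abs(jacobian16[m, far]) < abs(jacobian16[m, near])


class TestTikhonov:
    def test_zero_data_zero_image(self, jacobian16):
        ds = tikhonov_inverse(jacobian16, np.zeros(jacobian16.shape[0]), 1e-3)
        np.testing.assert_allclose(ds, 0.0)

    def test_norm_shrinks_monotonically_with_lambda(self, jacobian16):
        rng = np.random.default_rng(0)
        dv = rng.standard_normal(jacobian16.shape[0]) * 1e-6
        scale = np.trace(jacobian16.T @ jacobian16)
        norms = [
            np.linalg.norm(tikhonov_inverse(jacobian16, dv, lam))
            for lam in scale * np.logspace(-8, 12, 11)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-6 * norms[0]

    def test_single_element_perturbation_localises(self, disc16, jacobian16):
        """Inverse crime: noise-free data from one perturbed element peaks at
        that element or an edge-sharing neighbour."""
        target = 100
        ds_true = np.zeros(disc16.n_elements)
        ds_true[target] = 0.1
        dv = jacobian16 @ ds_true
        lam = 1e-6 * np.trace(jacobian16.T @ jacobian16) / disc16.n_elements
        ds = tikhonov_inverse(jacobian16, dv, lam)
        best = int(np.argmax(np.abs(ds)))
        shared = len(set(disc16.triangles[target]) & set(disc16.triangles[best]))
        assert best == target or shared >= 2

    def test_inverse_is_linear(self, jacobian16):
        rng = np.random.default_rng(1)
        dv1 = rng.standard_normal(jacobian16.shape[0])
        dv2 = rng.standard_normal(jacobian16.shape[0])
        lam = 1e-4 * np.trace(jacobian16.T @ jacobian16) / jacobian16.shape[1]
        lhs = tikhonov_inverse(jacobian16, dv1 + dv2, lam)
        rhs = tikhonov_inverse(jacobian16, dv1, lam) + tikhonov_inverse(jacobian16, dv2, lam)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-7, atol=1e-9 * np.abs(lhs).max())

    def test_lambda_must_be_positive(self, jacobian16):
        with pytest.raises(ValueError):
            tikhonov_inverse(jacobian16, np.zeros(jacobian16.shape[0]), 0.0)


class TestLambdaCv:
    def test_noise_free_picks_smallest_lambdas(self, disc16, jacobian16):
        ds_true = np.zeros(disc16.n_elements)
        ds_true[60] = 0.1
        dv = jacobian16 @ ds_true
        grid = default_lambda_grid(jacobian16)
        lam, _ = select_lambda_cv(jacobian16, dv, grid, seed=0)
        assert lam <= grid[1]

    def test_noise_raises_lambda(self, disc16, jacobian16):
        ds_true = np.zeros(disc16.n_elements)
        ds_true[60] = 0.1
        dv0 = jacobian16 @ ds_true
        grid = default_lambda_grid(jacobian16)
        lam_clean, _ = select_lambda_cv(jacobian16, dv0, grid, seed=0)
        lams = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dv = dv0 + rng.normal(0, dv0.std(), dv0.shape)  # SNR 0 dB
            lam, _ = select_lambda_cv(jacobian16, dv, grid, seed=seed)
            lams.append(lam)
        assert np.median(lams) >= lam_clean

    def test_single_element_grid(self, jacobian16):
        lam, curve = select_lambda_cv(
            jacobian16, np.ones(jacobian16.shape[0]), np.array([0.5]), seed=0
        )
        assert lam == 0.5 and len(curve) == 1

    def test_fewer_measurements_than_folds_rejected(self):
        with pytest.raises(ValueError):
            select_lambda_cv(np.ones((4, 3)), np.ones(4), np.array([1.0]), k_folds=10)


class TestNoiseCorrection:
    def test_zero_noise_sd_rejected(self, jacobian16):
        with pytest.raises(ValueError):
            noise_correction(
                np.zeros(jacobian16.shape[1]), jacobian16,
                np.zeros(jacobian16.shape[0]), 1e-6,
            )

    def test_null_z_rate_matches_gaussian(self, jacobian16):
        """Pure measurement noise: ~0.27 % of elements exceed |z| = 3."""
        rng = np.random.default_rng(42)
        sd = np.full(jacobian16.shape[0], 1e-7)
        lam = 1e-4 * np.trace(jacobian16.T @ jacobian16) / jacobian16.shape[1]
        count = total = 0
        for _ in range(50):
            dv = rng.normal(0, sd)
            ds = tikhonov_inverse(jacobian16, dv, lam)
            _, z = noise_correction(ds, jacobian16, sd, lam)
            count += int((np.abs(z) > 3).sum())
            total += len(z)
        rate = count / total
        assert 0.0005 < rate < 0.008  # binomial band around 0.0027

    def test_perturbation_survives_background_suppressed(self, disc16, jacobian16):
        """Patch perturbation at 20 dB SNR: flagged elements concentrate
        within two element diameters of the patch (precision >= 0.8)."""
        rng = np.random.default_rng(7)
        cent = disc16.centroids()
        patch = np.flatnonzero(np.linalg.norm(cent - [0.04, 0.03], axis=1) < 0.02)
        ds_true = np.zeros(disc16.n_elements)
        ds_true[patch] = 1.0
        sig = jacobian16 @ ds_true
        noise_sd = np.sqrt((sig**2).mean()) / 10  # 20 dB
        region = element_neighbour_region(
            disc16, patch, 0.02 + 2 * disc16.element_diameter()
        )
        for seed in range(5):
            dv = sig + rng.normal(0, noise_sd, sig.shape)
            res = reconstruct(
                jacobian16, dv, noise_sd=np.full(len(dv), noise_sd), seed=seed
            )
            flagged = np.flatnonzero(res.corrected_delta_sigma != 0)
            assert len(flagged) > 0
            precision = np.isin(flagged, region).mean()
            assert precision >= 0.8
            assert np.isin(patch, flagged).all()


class TestHaemorrhageSanity:
    def test_sevenfold_increase_reconstructs_positive_at_site(self, disc16, protocol16, forward16, jacobian16):
        """Blood is ~7x more conductive than brain tissue; a 7x local
        increase must reconstruct with positive conductivity change at the
        site even though the change is far outside the linear regime."""
        cent = disc16.centroids()
        patch = np.flatnonzero(np.linalg.norm(cent - [0.05, 0.02], axis=1) < 0.02)
        sigma = disc16.conductivity.copy()
        sigma[patch] *= 7.0
        fm_p = ForwardModel(
            Mesh2D(disc16.nodes, disc16.triangles, disc16.electrode_nodes, sigma),
            protocol16,
        )
        dv = (fm_p.boundary_voltages() - forward16.boundary_voltages()).ravel()
        lam = 1e-4 * np.trace(jacobian16.T @ jacobian16) / disc16.n_elements
        ds = tikhonov_inverse(jacobian16, dv, lam)
        assert (ds[patch] > 0).all()
        assert int(np.argmax(ds)) in patch
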