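import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatedspect import recon
from gatedspect.acquisition import DetectorModel, forward_project
from gatedspect.recon import (
    GatedDynamicImage,
    build_bspline_basis,
    build_gate_system_matrix,
    evaluate_activity,
    mlem_spatiotemporal,
    postfilter,
    recon_ungated_4d,
)
from toyutil import disc_volume, full_sampling, simulate_gate, toy_detector, toy_mu


class TestBSplineBasis:
    def test_default_has_nine_bases(self):
        basis = build_bspline_basis()
        assert basis.n_basis == 9

    @given(st.floats(min_value=0.0, max_value=360.0))
    @settings(max_examples=50, deadline=None)
    def test_partition_of_unity(self, t):
        basis = build_bspline_basis()
        assert abs(basis(t).sum() - 1.0) < 1e-10

    def test_nonnegative_and_local_support(self):
        basis = build_bspline_basis()
        v = basis.design_matrix(np.linspace(0, 360, 200))
        assert np.all(v >= 0)
        # a basis anchored late in the study vanishes early on
        assert basis(5.0)[-1] == 0.0
        assert basis(355.0)[0] == 0.0
        assert np.all((v > 0).sum(axis=1) <= basis.order + 1)

    def test_times_outside_domain_rejected(self):
        basis = build_bspline_basis()
        with pytest.raises(ValueError):
            basis.design_matrix(np.array([-5.0]))
        with pytest.raises(ValueError):
            basis.design_matrix(np.array([400.0]))

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            build_bspline_basis(knot_times=[100.0, 50.0])
        with pytest.raises(ValueError):
            build_bspline_basis(knot_times=[0.0, 50.0])  # touches the boundary


class TestGateSystemMatrix:
    def test_matches_direct_forward_projection(self, rng):
        det = toy_detector()
        mu = 0.1 * rng.random((16, 16, 1)) + 0.05
        mat = build_gate_system_matrix((1, 1), np.array([30.0, 110.0]), mu, det, 4.4, frame_dt=0.5)
        vol = rng.random((16, 16, 1))
        direct = forward_project(vol, mu, 110.0, det, 4.4, dt=0.5)
        assert np.allclose(mat.forward(vol, mat.angle_index(110.0)), direct, rtol=1e-8)

    def test_adjoint_identity(self, rng):
        det = toy_detector()
        mu = toy_mu(level=0.1)
        mat = build_gate_system_matrix((1, 1), np.array([63.0]), mu, det, 4.4)
        x = rng.random((16, 16, 1))
        y = rng.random((24, 1))
        lhs = np.sum(mat.forward(x, 0) * y)
        rhs = np.sum(x * mat.adjoint(y, 0))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_zero_volume_zero_sinogram(self):
        mat = build_gate_system_matrix((1, 1), np.array([0.0]), toy_mu(), toy_detector(), 4.4)
        assert np.all(mat.forward(np.zeros((16, 16, 1)), 0) == 0)

    def test_empty_angle_set_rejected(self):
        with pytest.raises(ValueError):
            build_gate_system_matrix((1, 1), np.array([]), toy_mu(), toy_detector(), 4.4)


def _static_disc_problem(n_views=60, value=3.0, noisy=False, seed=0):
    det = toy_detector()
    mu = toy_mu(level=0.05)
    basis = build_bspline_basis(knot_times=[], domain=(0.0, 1.0), order=0)
    angles = np.arange(n_views) * (360.0 / n_views)
    mat = build_gate_system_matrix((1, 1), angles, mu, det, 4.4, frame_dt=1.0)
    truth = disc_volume(value=value)
    rng = np.random.default_rng(seed) if noisy else None
    gs = simulate_gate(mat, basis, lambda t: truth, np.full(n_views, 0.5), angles, rng=rng)
    return gs, mat, basis, truth


class TestMLEM:
    def test_loglikelihood_monotone(self):
        gs, mat, basis, _ = _static_disc_problem(noisy=True, seed=3)
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=25)
        ll = img.loglik[(1, 1)]
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_nonnegative_coefficients_and_activity(self):
        gs, mat, basis, _ = _static_disc_problem(noisy=True, seed=4)
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=10)
        assert np.all(img.coefficients[(1, 1)] >= 0)
        assert np.all(img.evaluate((1, 1), 0.5) >= 0)

    def test_zero_counts_drive_coefficients_to_zero(self):
        gs, mat, basis, _ = _static_disc_problem()
        for v in gs.gates.values():
            v.counts[:] = 0.0
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=3)
        assert np.all(img.evaluate((1, 1), 0.5)[mat.support] < 1e-10)

    def test_static_disc_recovered_within_5_percent(self):
        gs, mat, basis, truth = _static_disc_problem()
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=30)
        vol = img.evaluate((1, 1), 0.5)
        inside = truth[:, :, 0] > 0
        # interior mean (away from the blurred rim)
        from scipy.ndimage import binary_erosion

        core = binary_erosion(inside, iterations=2)
        assert vol[:, :, 0][core].mean() == pytest.approx(3.0, rel=0.05)

    def test_negative_counts_rejected(self):
        gs, mat, basis, _ = _static_disc_problem()
        next(iter(gs.gates.values())).counts[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=1)

    def test_em_matches_direct_ml_optimizer(self):
        """On a fully sampled noiseless toy (smooth blob over a warm
        background, 3 temporal bases), 200 EM iterations land on the
        maximum-likelihood solution found by a generic bounded optimizer
        to within 1% in the coefficients."""
        from scipy.optimize import minimize

        det = toy_detector(blur=False)
        mu = toy_mu(level=0.05)
        basis = build_bspline_basis(knot_times=[], domain=(0.0, 60.0), order=2)  # 3 bases
        angles_grid = np.arange(0, 360, 15.0)
        mat = build_gate_system_matrix((1, 1), angles_grid, mu, det, 4.4, frame_dt=1.0)

        tac = lambda t: 1.0 + t / 60.0
        c = 7.5
        xx, yy = np.meshgrid(np.arange(16) - c, np.arange(16) - c, indexing="ij")
        truth = (0.25 + np.exp(-(xx**2 + yy**2) / (2 * 2.5**2)))[:, :, None]
        times, angles = full_sampling(np.linspace(0, 60, 5), angles_grid)
        gs = simulate_gate(mat, basis, lambda t: truth * tac(t), times, angles)
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=200)
        em = img.coefficients[(1, 1)]

        views = gs.gates[(1, 1)]
        V = basis.design_matrix(views.t_start)
        aidx = [mat.angle_index(a) for a in views.angles]

        def nll(theta):
            coef = theta.reshape(em.shape)
            val, grad = 0.0, np.zeros_like(coef)
            for j in range(len(views.t_start)):
                x = np.tensordot(V[j], coef, axes=(0, 0))
                ybar = mat.forward(x, aidx[j]) + 1e-12
                y = views.counts[j]
                val -= float(np.sum(y * np.log(ybar) - ybar))
                g = mat.adjoint(1.0 - y / ybar, aidx[j])
                for n in range(basis.n_basis):
                    grad[n] += V[j, n] * g
            return val, grad.ravel()

        x0 = np.where(mat.support, 1.0, 0.0)[None] * np.ones((basis.n_basis, 1, 1, 1))
        res = minimize(
            nll, x0.ravel(), jac=True, method="L-BFGS-B",
            bounds=[(0, None)] * x0.size,
            options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
        )
        assert res.success
        opt = res.x.reshape(em.shape)
        assert np.abs(em - opt).max() / opt.max() < 0.01


class TestEvaluateActivity:
    def test_uniform_coefficients_give_uniform_volume(self):
        basis = build_bspline_basis()
        coeffs = np.full((9, 4, 4, 1), 2.5)
        img = GatedDynamicImage(basis=basis, voxel_size=4.4, coefficients={(1, 1): coeffs})
        for t in (0.0, 77.7, 360.0):
            assert np.allclose(evaluate_activity(img, (1, 1), t), 2.5, atol=1e-10)

    def test_continuous_across_knots(self, rng):
        basis = build_bspline_basis()
        coeffs = rng.random((9, 3, 3, 1))
        img = GatedDynamicImage(basis=basis, voxel_size=4.4, coefficients={(1, 1): coeffs})
        knot = 120.0
        left = img.evaluate((1, 1), knot - 1e-7)
        right = img.evaluate((1, 1), knot + 1e-7)
        assert np.allclose(left, right, atol=1e-5)

    def test_outside_domain_rejected(self):
        basis = build_bspline_basis()
        img = GatedDynamicImage(
            basis=basis, voxel_size=4.4, coefficients={(1, 1): np.ones((9, 2, 2, 1))}
        )
        with pytest.raises(ValueError):
            img.evaluate((1, 1), 400.0)

    def test_recovered_tac_tracks_simulated_tac(self):
        """Closed loop on the toy: the fitted spline activity at the disc
        center follows the simulated time course within 10% relative RMSE."""
        det = toy_detector()
        mu = toy_mu(level=0.05)
        basis = build_bspline_basis(knot_times=[15.0, 30.0], domain=(0.0, 60.0))
        angles_grid = np.arange(0, 360, 15.0)
        mat = build_gate_system_matrix((1, 1), angles_grid, mu, det, 4.4, frame_dt=1.0)
        tac = lambda t: 1.0 + np.sin(np.pi * t / 60.0)
        truth = disc_volume(radius=6.0, value=1.0)
        times, angles = full_sampling(np.linspace(0, 60, 13), angles_grid)
        gs = simulate_gate(mat, basis, lambda t: truth * tac(t), times, angles)
        img = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=50)
        t_eval = np.linspace(0, 60, 25)
        center = (slice(7, 9), slice(7, 9), 0)
        rec = np.array([img.evaluate((1, 1), t)[center].mean() for t in t_eval])
        ref = np.array([tac(t) for t in t_eval])
        rel_rmse = np.sqrt(np.mean((rec - ref) ** 2)) / ref.mean()
        assert rel_rmse < 0.10


class TestPostfilter:
    def test_delta_becomes_kernel_peak(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = postfilter(vol, voxel_size=4.4)
        sigma = 4.5 / (2 * np.sqrt(2 * np.log(2))) / 4.4
        w = np.exp(-np.arange(-4, 5) ** 2 / (2 * sigma**2))
        expected_peak = (w.max() / w.sum()) ** 3  # center weight of the 9-tap kernel
        assert out[7, 7, 7] == pytest.approx(expected_peak, rel=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=1e-3)

    def test_uniform_unchanged_away_from_edges(self):
        out = postfilter(np.full((20, 20, 20), 5.0), voxel_size=4.4)
        assert np.allclose(out[8:12, 8:12, 8:12], 5.0, rtol=1e-6)

    def test_total_activity_preserved_for_interior_source(self):
        vol = np.zeros((20, 20, 20))
        vol[8:12, 8:12, 8:12] = 2.0
        out = postfilter(vol, voxel_size=4.4)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-3)

    def test_kernel_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            postfilter(np.ones((4, 4, 4)), voxel_size=4.4)


class TestUngatedComparison:
    def test_static_case_gated_equals_ungated(self):
        """Without motion, pooling all frames changes nothing material."""
        gs, mat, basis, truth = _static_disc_problem()
        gated = mlem_spatiotemporal(gs, {(1, 1): mat}, basis, n_iter=20)
        views = gs.gates[(1, 1)]
        from gatedspect.acquisition import AcquisitionFrame

        frames = [
            AcquisitionFrame(views.counts[j], "corrected", 1, j, float(views.angles[j]),
                             float(views.t_start[j]), 1, 1)
            for j in range(views.n_views)
        ]
        ungated = recon_ungated_4d(frames, toy_mu(level=0.05), basis, toy_detector(), 4.4,
                                   n_iter=20, frame_dt=1.0)
        inside = truth[:, :, 0] > 0
        g = gated.evaluate((1, 1), 0.5)[:, :, 0][inside].mean()
        u = ungated.evaluate((0, 0), 0.5)[:, :, 0][inside].mean()
        assert u == pytest.approx(g, rel=0.02)

    def test_zero_iterations_returns_initialization(self):
        gs, mat, basis, _ = _static_disc_problem(n_views=4)
        views = gs.gates[(1, 1)]
        from gatedspect.acquisition import AcquisitionFrame

        frames = [
            AcquisitionFrame(views.counts[j], "corrected", 1, j, float(views.angles[j]),
                             float(views.t_start[j]), 1, 1)
            for j in range(views.n_views)
        ]
        img = recon_ungated_4d(frames, toy_mu(level=0.05), basis, toy_detector(), 4.4, n_iter=0)
        vol = img.evaluate((0, 0), 0.5)
        assert np.all((vol == 0.0) | (vol == 1.0))
        assert vol.max() == 1.0

    def test_moving_disc_gated_sharper_than_ungated(self):
        """A disc alternating between two positions: each gate resolves its
        own position, the ungated reconstruction smears across both."""
        det = toy_detector()
        mu = toy_mu(level=0.05)
        basis = build_bspline_basis(knot_times=[], domain=(0.0, 1.0), order=0)
        angles_grid = np.arange(0, 360, 12.0)
        shift = 3.0
        truths = {1: disc_volume(center=(-shift, 0), radius=4.0),
                  2: disc_volume(center=(+shift, 0), radius=4.0)}
        mats, gs_gates = {}, {}
        from gatedspect.gating import GatedSinogram

        all_frames = []
        from gatedspect.acquisition import AcquisitionFrame

        for g in (1, 2):
            mat = build_gate_system_matrix((g, 1), angles_grid, mu, det, 4.4, frame_dt=1.0)
            sub = simulate_gate(mat, basis, lambda t: truths[g],
                                np.full(angles_grid.size, 0.5), angles_grid)
            mats[(g, 1)] = mat
            gs_gates[(g, 1)] = sub.gates[(g, 1)]
            v = sub.gates[(g, 1)]
            all_frames += [
                AcquisitionFrame(v.counts[j], "corrected", 1, j, float(v.angles[j]),
                                 float(v.t_start[j]), g, 1)
                for j in range(v.n_views)
            ]
        gs = GatedSinogram(gates=gs_gates)
        gated = mlem_spatiotemporal(gs, mats, basis, n_iter=30)
        ungated = recon_ungated_4d(all_frames, mu, basis, det, 4.4, n_iter=30, frame_dt=1.0)

        def x_spread(vol):
            prof = np.clip(vol[:, :, 0], 0, None).sum(axis=1)
            xs = np.arange(prof.size)
            mean = (prof * xs).sum() / prof.sum()
            return np.sqrt((prof * (xs - mean) ** 2).sum() / prof.sum())

        spread_gated = x_spread(gated.evaluate((1, 1), 0.5))
        spread_ungated = x_spread(ungated.evaluate((0, 0), 0.5))
        assert spread_gated < spread_ungated


def test_image_hdf5_roundtrip(tmp_path, rng):
    basis = build_bspline_basis()
    coeffs = rng.random((9, 5, 4, 3))
    img = GatedDynamicImage(basis=basis, voxel_size=4.4,
                            coefficients={(2, 3): coeffs}, loglik={(2, 3): np.arange(4.0)})
    path = tmp_path / "recon.h5"
    recon.write_image(img, path)
    back = recon.read_image(path)
    assert back.basis.n_basis == 9
    assert np.allclose(back.coefficients[(2, 3)], coeffs, atol=1e-6)
    assert np.allclose(back.loglik[(2, 3)], np.arange(4.0))
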