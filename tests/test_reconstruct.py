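import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmri import phantom as ph
from csmri import reconstruct as rc
from csmri import sensing as sn
from csmri.sensing import fft2c, ifft2c


class TestTvSeminorm:
    def test_constant_image_zero(self):
        assert rc.tv_seminorm(np.full((8, 8), 3.7)) == 0.0
        assert rc.tv_seminorm(np.full((8, 8), 3.7), "anisotropic") == 0.0

    @pytest.mark.parametrize("flavor", ["anisotropic", "isotropic"])
    def test_1d_step_equals_height(self, flavor):
        row = np.zeros(16)
        row[8:] = 2.5
        assert rc.tv_seminorm(row, flavor) == pytest.approx(2.5)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.standard_normal((8, 8))
        aniso = 0.0
        iso = 0.0
        for i in range(8):
            for j in range(8):
                dy = img[i + 1, j] - img[i, j] if i < 7 else 0.0
                dx = img[i, j + 1] - img[i, j] if j < 7 else 0.0
                aniso += abs(dy) + abs(dx)
                iso += np.hypot(dy, dx)
        assert rc.tv_seminorm(img, "anisotropic") == pytest.approx(aniso, rel=1e-12)
        assert rc.tv_seminorm(img, "isotropic") == pytest.approx(iso, rel=1e-12)

    def test_nonfinite_rejected(self):
        img = np.ones((4, 4))
        img[1, 1] = np.nan
        with pytest.raises(ValueError):
            rc.tv_seminorm(img)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=-5, max_value=5), st.integers(min_value=0, max_value=2**31 - 1))
    def test_absolute_homogeneity(self, scale, seed):
        img = np.random.default_rng(seed).standard_normal((6, 6))
        assert rc.tv_seminorm(scale * img) == pytest.approx(abs(scale) * rc.tv_seminorm(img), abs=1e-9)


class TestProxAndGradientOperators:
    def test_divergence_is_negative_adjoint(self, rng):
        x = rng.standard_normal((7, 9))
        p = rng.standard_normal((2, 7, 9))
        lhs = np.sum(rc._gradient(x) * p)
        rhs = -np.sum(x * rc._divergence(p))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_prox_tv_optimality(self, rng):
        # prox output must beat nearby perturbations on the prox objective
        x = rng.standard_normal((12, 12))
        w = 0.3
        u = rc.prox_tv(x, w, n_iter=400)
        obj = w * rc.tv_seminorm(u) + 0.5 * np.linalg.norm(u - x) ** 2
        for _ in range(10):
            v = u + 0.01 * rng.standard_normal(u.shape)
            alt = w * rc.tv_seminorm(v) + 0.5 * np.linalg.norm(v - x) ** 2
            assert obj <= alt + 1e-8

    def test_soft_threshold(self):
        x = np.array([3.0, -0.5, 0.2, -4.0])
        np.testing.assert_allclose(rc.soft_threshold(x, 1.0), [2.0, 0.0, 0.0, -3.0])

    def test_haar_orthonormal(self, rng):
        x = rng.standard_normal((16, 16))
        w = rc.haar_transform(x, levels=2)
        assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(x), rel=1e-12)
        np.testing.assert_allclose(rc.haar_inverse(w, levels=2), x, atol=1e-12)


class TestReconstructL2:
    def test_full_mask_exact(self, head32):
        mask = sn.generate_mask(32, "full", 1.0)
        acq = ph.simulate_acquisition(head32, mask, 0.0)
        res = rc.reconstruct_l2(acq)
        err = np.linalg.norm(res.image.real - head32) / np.linalg.norm(head32)
        assert err <= 1e-8

    def test_explicit_matches_kkt_oracle(self, rng):
        theta = rng.standard_normal((32, 64))
        system = sn.SensingSystem(Pi=theta)
        b = system.forward(rng.standard_normal(64))
        res = rc.reconstruct_l2((system, b), signal_shape=(8, 8))
        # KKT oracle for min ||Gx||^2 s.t. theta x = b
        g = rc._difference_matrix((8, 8))
        kkt = np.block([[2 * g.T @ g, theta.T], [theta, np.zeros((32, 32))]])
        rhs = np.concatenate([np.zeros(64), b])
        oracle = np.linalg.lstsq(kkt, rhs, rcond=None)[0][:64]
        assert np.abs(res.image.ravel() - oracle).max() <= 1e-6
        assert res.data_residual <= 1e-8

    def test_zero_measurement_zero_image(self, rng):
        theta = rng.standard_normal((3, 9))
        system = sn.SensingSystem(Pi=theta)
        res = rc.reconstruct_l2((system, np.zeros(3)), signal_shape=(9,))
        assert np.abs(res.image).max() <= 1e-10

    def test_operator_mode_data_consistent(self, head32):
        mask = sn.generate_mask(32, "vd-random", 0.4, seed=2)
        acq = ph.simulate_acquisition(head32, mask, 0.0)
        res = rc.reconstruct_l2(acq)
        assert res.data_residual <= 1e-8 * np.linalg.norm(acq.measurements)


class TestReconstructL1Tv:
    def test_full_mask_exact(self, head32):
        mask = sn.generate_mask(32, "full", 1.0)
        acq = ph.simulate_acquisition(head32, mask, 0.0)
        res = rc.reconstruct_l1_tv(acq, lam=0.0, config=rc.SolverConfig(max_iterations=200))
        err = np.linalg.norm(res.image.real - head32) / np.linalg.norm(head32)
        assert err <= 1e-6

    def test_undersampled_beats_l2_and_recovers(self, head64):
        mask = sn.generate_mask(64, "vd-random", 0.3, seed=0)
        acq = ph.simulate_acquisition(head64, mask, 0.0, seed=0)
        res1 = rc.reconstruct_l1_tv(acq, lam=0.0)
        res2 = rc.reconstruct_l2(acq)
        e1 = np.linalg.norm(res1.image.real - head64) / np.linalg.norm(head64)
        e2 = np.linalg.norm(res2.image.real - head64) / np.linalg.norm(head64)
        assert e1 <= 0.02
        assert e1 < e2

    def test_matches_lp_oracle_1d(self):
        # piecewise-constant 1-D signal from variable-density Fourier samples;
        # oracle: the equality-constrained L1 program as a linear program
        from scipy.optimize import linprog

        from csmri._rng import substream

        n = 64
        x = np.zeros(n)
        x[10:22] = 1.0
        x[30:40] = -0.7
        x[50:55] = 0.5
        c0 = n // 2
        radius = np.abs(np.arange(n) - c0) / (n / 2)
        profile = np.power(np.maximum(1 - radius, 1e-3), 0.5) + 1e-3
        gen = substream(5, "mask1d")
        score = gen.random(n) / profile
        score[c0] = -1
        idx = np.sort(np.argsort(score)[:24])

        class Op1D:
            m = idx.size

            def forward(self, v):
                return fft2c(np.asarray(v).ravel())[idx]

            def adjoint(self, y):
                k = np.zeros(n, dtype=complex)
                k[idx] = y
                return ifft2c(k)

            def lipschitz(self):
                return 1.0

        op = Op1D()
        c = op.forward(x)
        config = rc.SolverConfig(max_iterations=4000, max_stages=20, prox_iterations=40,
                                 residual_rtol=1e-7, tolerance=1e-9)
        res = rc.reconstruct_l1_tv((op, c, (n,)), lam=0.0, config=config)
        tv_solver = rc.tv_seminorm(res.image)

        dft = np.column_stack([fft2c(np.eye(n)[:, j]) for j in range(n)])[idx, :]
        a_eq = np.hstack([np.vstack([dft.real, dft.imag]), np.zeros((2 * idx.size, n - 1))])
        b_eq = np.concatenate([c.real, c.imag])
        d = np.diff(np.eye(n), axis=0)
        a_ub = np.vstack([np.hstack([d, -np.eye(n - 1)]), np.hstack([-d, -np.eye(n - 1)])])
        cost = np.concatenate([np.zeros(n), np.ones(n - 1)])
        sol = linprog(cost, A_ub=a_ub, b_ub=np.zeros(2 * (n - 1)), A_eq=a_eq, b_eq=b_eq,
                      bounds=[(None, None)] * (2 * n - 1), method="highs")
        assert sol.status == 0
        assert abs(tv_solver - sol.fun) <= 1e-4

    def test_data_consistency_contract_noisy(self, head32):
        mask = sn.generate_mask(32, "vd-random", 0.4, seed=1)
        acq = ph.simulate_acquisition(head32, mask, noise_level=0.05, seed=1)
        lam = 0.05 * np.sqrt(mask.n_sampled)  # expected noise norm
        res = rc.reconstruct_l1_tv(acq, lam=lam)
        assert res.converged
        assert res.data_residual <= lam + 1e-9

    def test_zero_measurements_zero_image(self):
        mask = sn.generate_mask(16, "vd-random", 0.5, seed=0)
        acq = ph.simulate_acquisition(np.zeros((16, 16)), mask, 0.0)
        res = rc.reconstruct_l1_tv(acq, lam=0.0)
        assert np.abs(res.image).max() == 0.0

    def test_negative_lambda_raises(self, head32):
        mask = sn.generate_mask(32, "full", 1.0)
        acq = ph.simulate_acquisition(head32, mask, 0.0)
        with pytest.raises(ValueError):
            rc.reconstruct_l1_tv(acq, lam=-1.0)


class TestReconstructLagrangian:
    def test_vanishing_penalty_full_mask(self, head32):
        mask = sn.generate_mask(32, "full", 1.0)
        acq = ph.simulate_acquisition(head32, mask, 0.0)
        regs = rc.RegularizerSpec(terms=(("tv", 1e-9),))
        res = rc.reconstruct_lagrangian(acq, regs, rc.SolverConfig(max_iterations=300))
        err = np.linalg.norm(res.image.real - head32) / np.linalg.norm(head32)
        assert err <= 1e-4

    def test_l1_identity_matches_l0_support(self):
        from csmri import recovery_theory as rt
        from csmri.phantom import generate_sparse_signal

        rng = np.random.default_rng(1)
        theta = rng.standard_normal((6, 12))
        a0 = generate_sparse_signal(12, 2, seed=7)
        b = theta @ a0
        l0 = rt.l0_decode(b, theta, 2)
        system = sn.SensingSystem(Pi=theta)
        regs = rc.RegularizerSpec(terms=(("l1-identity", 0.01),))
        res = rc.reconstruct_lagrangian((system, b, (12,)), regs,
                                        rc.SolverConfig(max_iterations=5000, tolerance=1e-12))
        support = set(np.flatnonzero(np.abs(res.image) > 0.1 * np.abs(res.image).max()))
        assert support == set(l0.support)

    @pytest.mark.parametrize("terms", [
        (("tv", 0.01),),
        (("l1-wavelet", 0.005),),
        (("tv", 0.01), ("l2-tv", 0.001)),
    ])
    def test_objective_trace_monotone(self, head32, terms):
        mask = sn.generate_mask(32, "vd-random", 0.4, seed=3)
        acq = ph.simulate_acquisition(head32, mask, 0.0, seed=3)
        res = rc.reconstruct_lagrangian(acq, rc.RegularizerSpec(terms=terms),
                                        rc.SolverConfig(max_iterations=150))
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_l1tv_trace_monotone(self, head32):
        mask = sn.generate_mask(32, "vd-random", 0.4, seed=4)
        acq = ph.simulate_acquisition(head32, mask, 0.0, seed=4)
        res = rc.reconstruct_l1_tv(acq, lam=0.0)
        assert np.all(np.diff(res.objective_trace) <= 1e-10)

    def test_unsupported_term_rejected(self):
        with pytest.raises(ValueError):
            rc.RegularizerSpec(terms=(("l0-magic", 1.0),))
        with pytest.raises(ValueError):
            rc.RegularizerSpec(terms=())
        with pytest.raises(ValueError):
            rc.RegularizerSpec(terms=(("tv", -1.0),))


class TestSamplingFractionMonotonicity:
    def test_mean_psnr_nondecreasing_in_fraction(self, head32):
        # scaled-down instance of the fraction sweep (grid 32, 2 seeds)
        means = []
        for fraction in (0.2, 0.3, 0.5, 1.0):
            vals = []
            for seed in range(2):
                mask = sn.generate_mask(32, "vd-random", fraction, seed=seed)
                acq = ph.simulate_acquisition(head32, mask, 0.0, seed=seed)
                res = rc.reconstruct_l1_tv(acq, lam=0.0)
                vals.append(min(rc.evaluate(head32, res.image.real)["psnr"], 200.0))
            means.append(np.mean(vals))
        assert all(b >= a - 0.5 for a, b in zip(means, means[1:]))


class TestEvaluate:
    def test_identity(self, head32):
        m = rc.evaluate(head32, head32)
        assert m["relative_l2"] == 0.0
        assert m["ssim"] == pytest.approx(1.0)
        assert np.isinf(m["psnr"])

    def test_constant_offset_closed_form(self):
        ref = np.zeros((32, 32))
        ref[8:24, 8:24] = 1.0  # unit dynamic range
        m = rc.evaluate(ref, ref + 0.1)
        assert m["psnr"] == pytest.approx(20.0, abs=1e-9)

    def test_psnr_matches_formula_oracle(self, rng):
        ref = rng.random((16, 16))
        rec = ref + 0.05 * rng.standard_normal((16, 16))
        m = rc.evaluate(ref, rec)
        mse = np.mean((ref - rec) ** 2)
        expected = 10 * np.log10((ref.max() - ref.min()) ** 2 / mse)
        assert m["psnr"] == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            rc.evaluate(rng.random((8, 8)), rng.random((4, 4)))

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            rc.evaluate(np.ones((8, 8)), np.ones((8, 8)))
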