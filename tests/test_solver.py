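"""Three-level Bregman solver: update rules, limits, and end-to-end runs."""

import dataclasses

import numpy as np
import pytest

from trims.frames import haar_fixed_bank, init_adaptive_bank
from trims.phantoms import PhantomSpec, make_phantom, simulate_acquisition
from trims.sampling import (
    KSpaceData,
    MaskScheme,
    SamplingMask,
    apply_undersampling,
    forward_fourier,
    full_mask,
    inverse_fourier,
    make_variable_density_mask,
)
from trims.solver import (
    DivergenceError,
    ReconParams,
    TRIMSState,
    ddtf_reconstruct,
    shrink,
    trims_reconstruct,
    update_adaptive_bank,
    update_u_kspace,
    update_ua,
    update_v,
)


def random_state(rng, n=16, mask=None):
    """A TRIMSState filled with random iterates of consistent geometry."""
    wa, wb = haar_fixed_bank(), init_adaptive_bank(4)

    def cplx(shape):
        return rng.normal(size=shape) + 1j * rng.normal(size=shape)

    c = cplx((n, n))
    if mask is not None:
        c = np.where(mask.grid, c, 0.0)
    return TRIMSState(
        u=cplx((n, n)),
        ua=cplx((4, n, n)),
        v=cplx((16, 4, n, n)),
        c=c,
        d=cplx((4, n, n)),
        e=cplx((16, 4, n, n)),
        wa=wa,
        wb=wb,
    )


def normal_equation_residual(u, state, f, params):
    """||F_p^H(F_p u - f + c) + mu W_a^H(W_a u - u_a + d)|| (relative)."""
    mask = f.mask.grid
    data_term = inverse_fourier(
        np.where(mask, forward_fourier(u) - f.values + state.c, 0.0)
    )
    frame_term = state.wa.synthesize(state.wa.analyze(u) - state.ua + state.d)
    resid = np.linalg.norm(data_term + params.mu * frame_term)
    scale = np.linalg.norm(f.values) + params.mu * np.linalg.norm(state.ua) + 1e-300
    return resid / scale


class TestShrink:
    def test_real_examples(self):
        assert shrink(np.array(3.0), 1.0) == pytest.approx(2.0)
        assert shrink(np.array(-3.0), 1.0) == pytest.approx(-2.0)

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        assert np.array_equal(shrink(x, 0.0), x)

    def test_below_threshold_magnitudes_vanish(self):
        for theta in (0.0, 1.1, -2.5):
            assert shrink(np.array(0.5 * np.exp(1j * theta)), 1.0) == 0

    def test_phase_preserved_above_threshold(self, rng):
        x = 2.0 * np.exp(1j * rng.uniform(-np.pi, np.pi, size=50))
        y = shrink(x, 0.5)
        assert np.allclose(np.angle(y), np.angle(x))
        assert np.allclose(np.abs(y), 1.5)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(np.zeros(3), -0.1)


class TestUpdateUKspace:
    def test_normal_equation_residual_on_random_states(self, rng):
        n = 16
        for trial in range(5):
            mask = make_variable_density_mask(n, 2.0, seed=trial)
            state = random_state(rng, n, mask)
            f = apply_undersampling(
                rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), mask
            )
            params = ReconParams(alpha=1.0, mu=float(rng.uniform(0.1, 5.0)))
            u = update_u_kspace(state, f, params)
            assert normal_equation_residual(u, state, f, params) < 1e-8

    def test_on_off_omega_branch_structure(self, rng):
        n = 16
        mask = make_variable_density_mask(n, 2.0, seed=3)
        state = random_state(rng, n, mask)
        f = apply_undersampling(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), mask)
        params = ReconParams(alpha=1.0, mu=2.0)
        fu = forward_fourier(update_u_kspace(state, f, params))
        s = forward_fourier(state.wa.synthesize(state.ua - state.d))
        s0 = f.values - state.c
        expected = np.where(mask.grid, (s0 + params.mu * s) / (1 + params.mu), s)
        assert np.allclose(fu, expected, atol=1e-12)

    def test_empty_mask_returns_frame_synthesis(self, rng):
        n = 16
        empty = SamplingMask(np.zeros((n, n), bool), MaskScheme.RADIAL, np.inf)
        state = random_state(rng, n, empty)
        f = KSpaceData(np.zeros((n, n), complex), empty)
        u = update_u_kspace(state, f, ReconParams(alpha=1.0))
        expected = state.wa.synthesize(state.ua - state.d)
        assert np.allclose(u, expected, atol=1e-10)

    def test_small_mu_limit_enforces_measured_data(self, rng):
        """With mu -> 0 (coupling off) the sampled K-space is set to f - c."""
        n = 16
        mask = make_variable_density_mask(n, 2.0, seed=1)
        state = random_state(rng, n, mask)
        state.c = np.zeros_like(state.c)
        f = apply_undersampling(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), mask)
        u = update_u_kspace(state, f, ReconParams(alpha=1.0, mu=1e-12))
        fu = forward_fourier(u)
        assert np.allclose(fu[mask.grid], f.values[mask.grid], atol=1e-9)

    def test_geometry_mismatch_rejected(self, rng):
        state = random_state(rng, 16)
        f = apply_undersampling(np.zeros((32, 32), complex), full_mask(32))
        with pytest.raises(ValueError):
            update_u_kspace(state, f, ReconParams(alpha=1.0))


class TestUpdateUa:
    def test_large_mu_limit(self, rng):
        state = random_state(rng, 16)
        ua = update_ua(state, ReconParams(alpha=1.0, mu=1e12))
        expected = state.wa.analyze(state.u) + state.d
        assert np.allclose(ua, expected, atol=1e-9)

    def test_vanishing_terms_give_zero(self, rng):
        state = random_state(rng, 16)
        state.e = state.v.copy()  # v - e = 0
        state.d = -state.wa.analyze(state.u)  # W_a u + d = 0
        ua = update_ua(state, ReconParams(alpha=1.0, mu=1.0))
        assert np.abs(ua).max() < 1e-12

    def test_minimizes_mid_objective_against_perturbations(self, rng):
        state = random_state(rng, 16)
        params = ReconParams(alpha=1.0, mu=0.7)
        ua = update_ua(state, params)

        def objective(candidate):
            t1 = np.linalg.norm(state.wa.analyze(state.u) - candidate + state.d) ** 2
            t2 = np.linalg.norm(state.wb.analyze(candidate) - state.v + state.e) ** 2
            return params.mu * t1 + t2

        best = objective(ua)
        for _ in range(20):
            noise = rng.normal(size=ua.shape) + 1j * rng.normal(size=ua.shape)
            assert objective(ua + 0.1 * noise) >= best - 1e-9


class TestUpdateV:
    def test_large_alpha_inverse_mode_disables_sparsification(self, rng):
        state = random_state(rng, 16)
        v = update_v(state, ReconParams(alpha=1e15, mu=1.0))
        assert np.allclose(v, state.wb.analyze(state.ua) + state.e, atol=1e-10)

    def test_zero_inputs_give_zero(self, rng):
        state = random_state(rng, 16)
        state.ua = np.zeros_like(state.ua)
        state.e = np.zeros_like(state.e)
        assert np.all(update_v(state, ReconParams(alpha=1.0, mu=1.0)) == 0)

    def test_scaled_alpha_mode_matches_scalar_closed_form(self, rng):
        state = random_state(rng, 16)
        alpha = 0.8
        params = ReconParams(alpha=alpha, mu=1.0, shrink_threshold_mode="scaled_alpha")
        v = update_v(state, params)
        w = state.wb.analyze(state.ua) + state.e
        mag = np.abs(w)
        expected = np.where(mag > alpha / 2, (1 - (alpha / 2) / np.where(mag > 0, mag, 1)) * w, 0)
        assert np.allclose(v, expected, atol=1e-12)


class TestUpdateAdaptiveBank:
    def test_exact_targets_are_a_fixed_point(self, rng):
        state = random_state(rng, 16)
        state.e = np.zeros_like(state.e)
        state.v = state.wb.analyze(state.ua)
        new = update_adaptive_bank(state, ReconParams(alpha=1.0))
        assert np.abs(new.matrix - state.wb.matrix).max() < 1e-8

    def test_objective_does_not_increase(self, rng):
        from trims.frames import extract_patches

        state = random_state(rng, 16)
        patches = np.hstack([extract_patches(ch, 4) for ch in state.ua])
        targets = (state.v - state.e).reshape(16, -1)
        before = np.linalg.norm(state.wb.matrix @ patches - targets)
        new = update_adaptive_bank(state, ReconParams(alpha=1.0))
        after = np.linalg.norm(new.matrix @ patches - targets)
        assert after <= before + 1e-12

    def test_degenerate_zero_ua_keeps_bank(self, rng):
        state = random_state(rng, 16)
        state.ua = np.zeros_like(state.ua)
        state.v = np.zeros_like(state.v)
        state.e = np.zeros_like(state.e)
        with pytest.warns(RuntimeWarning):
            new = update_adaptive_bank(state, ReconParams(alpha=1.0))
        assert new is state.wb


class TestReconstruction:
    def test_full_mask_noiseless_exact_recovery_both_paths(self, small_phantom):
        """With the sparsity penalty off (threshold -> 0) the exact image is a
        fixed point of the whole scheme: one outer iteration is lossless."""
        f = simulate_acquisition(small_phantom, full_mask(64))
        params = ReconParams(alpha=1e12, n_outer=1)
        for method in (trims_reconstruct, ddtf_reconstruct):
            res = method(f, params, ground_truth=small_phantom)
            err = np.linalg.norm(res.image - small_phantom) / np.linalg.norm(small_phantom)
            assert err <= 1e-6

    def test_metrics_trace_deterministic_across_runs(self, small_phantom):
        mask = make_variable_density_mask(64, 4.0, seed=2)
        f = simulate_acquisition(small_phantom, mask)
        params = ReconParams(n_outer=2, n_mid=1, n_inner=2)
        a = trims_reconstruct(f, params, ground_truth=small_phantom)
        b = trims_reconstruct(f, params, ground_truth=small_phantom)
        assert a.metrics_trace == b.metrics_trace
        assert np.array_equal(a.image, b.image)

    def test_phase_rotation_equivariance(self, rng):
        """reconstruct(e^{i phi} f) = e^{i phi} reconstruct(f): every operator
        is phase-equivariant and the learned filters are real."""
        img = make_phantom(PhantomSpec(n=32, seed=6))
        mask = make_variable_density_mask(32, 2.0, seed=6)
        f = simulate_acquisition(img, mask)
        phi = 0.9
        rotated = KSpaceData(np.exp(1j * phi) * f.values, mask)
        params = ReconParams(n_outer=2, n_mid=1, n_inner=2)
        res = trims_reconstruct(f, params)
        res_rot = trims_reconstruct(rotated, params)
        err = np.linalg.norm(res_rot.image - np.exp(1j * phi) * res.image)
        assert err < 1e-8 * np.linalg.norm(res.image)

    def test_large_alpha_keeps_v_tracking_coefficients(self, small_phantom):
        """alpha -> infinity (threshold 0) reduces the inner level to exact
        frame-coefficient tracking: the e Bregman variable never moves."""
        mask = make_variable_density_mask(64, 3.0, seed=4)
        f = simulate_acquisition(small_phantom, mask)
        res = trims_reconstruct(f, ReconParams(alpha=1e14, n_outer=2, n_mid=1, n_inner=3))
        assert np.abs(res.state.e).max() < 1e-10

    def test_bregman_restores_data_consistency(self, small_phantom):
        """Outer Bregman iterations drive || F_p u - f || / || f || below 1e-3
        on a 64x64 phantom at 40% sampling."""
        mask = make_variable_density_mask(64, 2.5, seed=8)
        f = simulate_acquisition(small_phantom, mask)
        params = ReconParams(n_outer=30, n_mid=2, n_inner=3, tol=0.0)
        res = trims_reconstruct(f, params, ground_truth=small_phantom)
        assert res.metrics_trace[-1]["data_residual"] < 1e-3

    def test_ddtf_learns_sixty_four_8x8_filters(self, small_phantom):
        mask = make_variable_density_mask(64, 2.0, seed=1)
        f = simulate_acquisition(small_phantom, mask)
        res = ddtf_reconstruct(f, ReconParams(n_outer=1, n_mid=1, n_inner=1))
        assert (res.state.wb.m, res.state.wb.p) == (64, 8)

    def test_ddtf_metrics_trace_matches_trims_schema(self, small_phantom):
        mask = make_variable_density_mask(64, 2.0, seed=1)
        f = simulate_acquisition(small_phantom, mask)
        params = ReconParams(n_outer=1, n_mid=1, n_inner=1)
        t = trims_reconstruct(f, params, ground_truth=small_phantom)
        d = ddtf_reconstruct(f, params, ground_truth=small_phantom)
        assert set(t.metrics_trace[0]) == set(d.metrics_trace[0])

    def test_divergence_guard_names_level_and_iteration(self, small_phantom):
        mask = make_variable_density_mask(64, 2.0, seed=0)
        values = np.where(mask.grid, np.nan + 0j, 0.0)
        f = KSpaceData(values, mask)
        with pytest.raises(DivergenceError, match=r"outer=1"):
            trims_reconstruct(f, ReconParams(alpha=1.0, n_outer=1))

    def test_result_image_is_state_u(self, small_phantom):
        f = simulate_acquisition(small_phantom, full_mask(64))
        res = trims_reconstruct(f, ReconParams(alpha=100.0, n_outer=1, n_mid=1, n_inner=1))
        assert res.image is res.state.u


class TestReconParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -1.0},
            {"mu": 0.0},
            {"n_outer": 0},
            {"filter_update_every": 0},
            {"shrink_threshold_mode": "bogus"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReconParams(**kwargs)
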