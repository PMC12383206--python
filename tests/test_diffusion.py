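"""Schedule algebra, forward process, losses, guidance and samplers."""

import numpy as np
import pytest

from cardiacdiff import diffusion as df
from cardiacdiff.diffusion import (NoiseSchedule, cfg_combine, ddim_sample,
                                   ddim_timesteps, ddpm_step, forward_diffuse,
                                   iterate_forward, make_schedule, predict_x0,
                                   schedule_from_alphas, simple_loss)


class TestSchedule:
    def test_injected_alphas_products(self):
        sched = schedule_from_alphas([0.9, 0.8])
        assert sched.alpha_bar(1) == pytest.approx(0.9, abs=1e-15)
        assert sched.alpha_bar(2) == pytest.approx(0.72, abs=1e-15)

    def test_degenerate_no_noise_schedule(self):
        sched = make_schedule(T=1, beta_start=0.0, beta_end=0.0)
        assert sched.alpha_bar(1) == pytest.approx(1.0, abs=1e-9)

    def test_alpha_bar_matches_extended_precision_product(self):
        """ᾱ_1000 from cumprod agrees with an independent long-double loop."""
        sched = make_schedule(T=1000, beta_start=1e-4, beta_end=0.02)
        betas = np.linspace(1e-4, 0.02, 1000, dtype=np.longdouble)
        prod = np.longdouble(1.0)
        for b in betas:
            prod *= (np.longdouble(1.0) - b)
        rel = abs(sched.alpha_bar(1000) - float(prod)) / float(prod)
        assert rel < 1e-12

    def test_alpha_bar_strictly_decreasing_and_consistent(self):
        sched = make_schedule(T=500)
        ab = sched.alpha_bars
        assert np.all(np.diff(ab) < 0)
        ratios = ab[1:] / ab[:-1]
        assert np.allclose(ratios, sched.alphas[1:], rtol=1e-12, atol=0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(T=10, beta_start=0.5, beta_end=0.1)
        with pytest.raises(ValueError):
            make_schedule(T=10, beta_start=0.1, beta_end=1.5)
        with pytest.raises(ValueError):
            make_schedule(T=0)
        with pytest.raises(ValueError):
            make_schedule(T=10, kind="cosine")

    def test_timestep_range_checked(self):
        sched = make_schedule(T=10)
        with pytest.raises(ValueError):
            sched.alpha(0)
        with pytest.raises(ValueError):
            sched.alpha_bar(11)


class TestForwardProcess:
    def test_zero_noise_scales_by_sqrt_alpha_bar(self):
        sched = schedule_from_alphas([0.9, 0.8])
        y0 = np.arange(6.0).reshape(2, 3)
        yt = forward_diffuse(y0, 2, np.zeros_like(y0), sched)
        assert np.allclose(yt, np.sqrt(0.72) * y0, atol=1e-12)

    def test_zero_signal_scales_noise(self):
        sched = schedule_from_alphas([0.9, 0.8])
        eps = np.random.default_rng(0).standard_normal((4, 4))
        yt = forward_diffuse(np.zeros((4, 4)), 2, eps, sched)
        assert np.allclose(yt, np.sqrt(1 - 0.72) * eps, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        sched = make_schedule(T=5)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((2, 2)), 1, np.zeros((3, 3)), sched)

    def test_marginal_moments_monte_carlo(self):
        """Empirical mean/variance of y_t match √ᾱ·y0 and 1−ᾱ (4 SE)."""
        sched = make_schedule(T=100)
        t = int(np.argmin(np.abs(sched.alpha_bars - 0.5))) + 1
        ab = sched.alpha_bar(t)
        rng = np.random.default_rng(42)
        y0 = np.array([0.3, -0.7, 1.0, 0.0])
        n = 10_000
        draws = forward_diffuse(y0, t, rng.standard_normal((n, 4)), sched)
        var = 1 - ab
        se_mean = np.sqrt(var / n)
        assert np.all(np.abs(draws.mean(0) - np.sqrt(ab) * y0) < 4 * se_mean)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(draws.var(0, ddof=1) - var) < 4 * se_var)

    def test_iterate_forward_matches_closed_form_noiseless(self):
        sched = make_schedule(T=10)
        y0 = np.random.default_rng(1).standard_normal((3, 3))
        zeros = [np.zeros((3, 3))] * 7
        yt = iterate_forward(y0, 7, zeros, sched)
        assert np.allclose(yt, forward_diffuse(y0, 7, np.zeros((3, 3)), sched), atol=1e-12)

    def test_iterate_forward_single_step(self):
        sched = make_schedule(T=4)
        y0 = np.random.default_rng(2).standard_normal((2, 2))
        eps = np.random.default_rng(3).standard_normal((2, 2))
        assert np.allclose(iterate_forward(y0, 1, [eps], sched),
                           forward_diffuse(y0, 1, eps, sched), atol=1e-12)

    def test_iterate_forward_hand_expansion(self):
        """Three nested affine steps agree with explicit algebraic expansion."""
        sched = schedule_from_alphas([0.9, 0.8, 0.7])
        y0 = 0.5
        e = [0.1, -0.2, 0.3]
        y = np.float64(y0)
        expected = y0
        for i, a in enumerate([0.9, 0.8, 0.7]):
            expected = np.sqrt(a) * expected + np.sqrt(1 - a) * e[i]
        got = iterate_forward(np.array(y0), 3, [np.array(x) for x in e], sched)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_iterate_forward_wrong_length(self):
        sched = make_schedule(T=5)
        with pytest.raises(ValueError):
            iterate_forward(np.zeros(2), 3, [np.zeros(2)] * 2, sched)


class TestPredictX0:
    def test_exact_inversion(self):
        sched = make_schedule(T=50)
        rng = np.random.default_rng(0)
        y0 = rng.standard_normal((5, 5)).astype(np.float32)
        for t in (1, 25, 50):
            eps = rng.standard_normal((5, 5)).astype(np.float32)
            yt = forward_diffuse(y0, t, eps, sched)
            assert np.abs(predict_x0(yt, eps, t, sched) - y0).max() < 1e-5

    def test_zero_eps_estimate(self):
        sched = schedule_from_alphas([0.36])
        yt = np.array([1.2, -0.6])
        assert np.allclose(predict_x0(yt, np.zeros(2), 1, sched), yt / 0.6, atol=1e-12)

    def test_formula_direct(self):
        sched = schedule_from_alphas([0.6, 0.6])  # alpha_bar(2) = 0.36
        rng = np.random.default_rng(7)
        yt = rng.standard_normal(8)
        eh = rng.standard_normal(8)
        expected = (yt - np.sqrt(1 - 0.36) * eh) / np.sqrt(0.36)
        assert np.allclose(predict_x0(yt, eh, 2, sched), expected, atol=1e-12)


class TestDdpmStep:
    def test_pure_rescale_when_eps_and_noise_zero(self):
        sched = make_schedule(T=10)
        yt = np.random.default_rng(0).standard_normal((3, 3))
        out = ddpm_step(yt, np.zeros((3, 3)), 5, np.zeros((3, 3)), sched)
        assert np.allclose(out, yt / np.sqrt(sched.alpha(5)), atol=1e-12)

    def test_final_step_ignores_noise(self):
        sched = make_schedule(T=10)
        rng = np.random.default_rng(1)
        yt = rng.standard_normal((3, 3))
        eh = rng.standard_normal((3, 3))
        z = rng.standard_normal((3, 3))
        assert np.array_equal(ddpm_step(yt, eh, 1, z, sched),
                              ddpm_step(yt, eh, 1, np.zeros((3, 3)), sched))

    def test_formula_direct(self):
        alphas = [0.9, 0.5 / 0.9]  # alpha_bar(2) = 0.5, alpha(2) = 0.5/0.9
        sched = schedule_from_alphas(alphas)
        a, ab, sig = alphas[1], 0.5, sched.sigma(2)
        rng = np.random.default_rng(2)
        yt, eh, z = (rng.standard_normal(6) for _ in range(3))
        expected = (yt - (1 - a) / np.sqrt(1 - ab) * eh) / np.sqrt(a) + sig * z
        assert np.allclose(ddpm_step(yt, eh, 2, z, sched), expected, atol=1e-12)

    def test_out_of_range_t(self):
        sched = make_schedule(T=4)
        with pytest.raises(ValueError):
            ddpm_step(np.zeros(2), np.zeros(2), 5, np.zeros(2), sched)


class TestDdim:
    def test_deterministic_given_seed(self):
        sched = make_schedule(T=50)
        zero = lambda y, t, c=None: np.zeros_like(y)
        a = ddim_sample(zero, sched, n_steps=10, eta=0.0, shape=(2, 1, 4, 4), seed=9)
        b = ddim_sample(zero, sched, n_steps=10, eta=0.0, shape=(2, 1, 4, 4), seed=9)
        assert np.array_equal(a, b)

    def test_zero_denoiser_closed_form(self):
        """With ε̂≡0, η=0 each step multiplies by √(ᾱ_prev/ᾱ_t): the product
        telescopes to 1/√ᾱ_T."""
        sched = make_schedule(T=40)
        zero = lambda y, t, c=None: np.zeros_like(y)
        out = ddim_sample(zero, sched, n_steps=8, eta=0.0, shape=(1, 1, 3, 3), seed=4)
        init = np.random.default_rng(4).standard_normal((1, 1, 3, 3)).astype(np.float32)
        expected = init / np.sqrt(sched.alpha_bar(sched.T))
        assert np.allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_full_length_eta1_matches_ancestral(self):
        """η=1 DDIM over all T steps with posterior variances reproduces the
        ancestral chain when the same per-step noise is injected."""
        T = 12
        sched = make_schedule(T=T, sigma_kind="posterior")
        rng = np.random.default_rng(5)
        init = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        zs = [rng.standard_normal((1, 1, 4, 4)).astype(np.float32) for _ in range(T)]
        zero = lambda y, t, c=None: np.zeros_like(y)
        got = ddim_sample(zero, sched, n_steps=T, eta=1.0, shape=init.shape, seed=0,
                          noise_sequence=zs, init_noise=init)
        y = init.astype(np.float64)
        for i, t in enumerate(range(T, 0, -1)):
            z = zs[i] if t > 1 else np.zeros_like(init)
            y = ddpm_step(y, np.zeros_like(y), t, z, sched)
        assert np.abs(got - y).max() < 1e-6

    def test_n_steps_validation(self):
        sched = make_schedule(T=10)
        with pytest.raises(ValueError):
            ddim_timesteps(10, 11)
        assert list(ddim_timesteps(10, 10)) == list(range(10, 0, -1))


class TestLossAndGuidance:
    def test_simple_loss_examples(self):
        x = np.random.default_rng(0).standard_normal((4, 4))
        assert simple_loss(x, x) == 0.0
        assert simple_loss(np.zeros((2, 2)), np.ones((2, 2))) == 1.0

    def test_simple_loss_hand_summed(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        expected = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 16
        assert simple_loss(a, b) == pytest.approx(expected, abs=1e-12)

    def test_simple_loss_nonnegative_property(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.standard_normal(9), rng.standard_normal(9)
            assert simple_loss(a, b) >= 0
        assert simple_loss(a, a) == 0.0

    def test_cfg_combine(self):
        rng = np.random.default_rng(1)
        u, c = rng.standard_normal(5), rng.standard_normal(5)
        assert np.allclose(cfg_combine(u, c, 1.0), c, atol=1e-12)
        assert np.allclose(cfg_combine(u, c, 0.0), u, atol=1e-12)
        assert np.allclose(cfg_combine(np.zeros(3), np.full(3, 2.0), 2.0),
                           np.full(3, 4.0), atol=1e-12)
        with pytest.raises(ValueError):
            cfg_combine(u, c, -0.5)
        with pytest.raises(ValueError):
            cfg_combine(u, c[:3], 1.0)


class TestScheduleProperties:
    def test_alpha_bar_consistency_property(self):
        """For arbitrary valid alpha sequences, ᾱ is strictly decreasing and
        ᾱ_t/ᾱ_{t−1} recovers α_t."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.lists(st.floats(0.1, 0.999), min_size=1, max_size=30))
        def inner(alphas):
            sched = schedule_from_alphas(alphas)
            for t in range(1, sched.T + 1):
                assert sched.alpha_bar(t) == pytest.approx(
                    sched.alpha_bar(t - 1) * sched.alpha(t), rel=1e-12)
                assert sched.alpha_bar(t) < sched.alpha_bar(t - 1)

        inner()

    def test_scaled_schedule_preserves_terminal_noise(self):
        """Shortened chains keep ᾱ_T within the reference order of magnitude
        (the unscaled T=200 chain would be off by four orders)."""
        ref = make_schedule(T=1000)
        for T in (100, 200, 500):
            short = df.scaled_schedule(T)
            ratio = short.alpha_bar(T) / ref.alpha_bar(1000)
            assert 0.3 < ratio < 3.0
        assert np.allclose(df.scaled_schedule(1000).alpha_bars, ref.alpha_bars)
        unscaled = make_schedule(T=200)
        assert unscaled.alpha_bar(200) / ref.alpha_bar(1000) > 1e3
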