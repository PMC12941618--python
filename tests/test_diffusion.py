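"""Diffusion algebra: schedule, forward/inverse maps, posterior, sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgad import (
    build_schedule,
    confidence,
    estimate_clean,
    forward_diffuse,
    perturb_interpolated,
    posterior_step,
    reverse_sample,
)


# ---------------------------------------------------------------------------
# schedule


class TestSchedule:
    def test_single_step_closed_form(self):
        s = build_schedule(1, 0.1, 0.1)
        assert s.alpha_bar == pytest.approx([0.9])
        assert s.posterior_var == pytest.approx([0.0])

    def test_alpha_bar_matches_bruteforce_product(self):
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.001, 0.2, size=10)
        s = build_schedule(10, betas.min(), betas.max())
        # independent cumulative-product loop on the schedule's own betas
        prod, expected = 1.0, []
        for b in s.beta:
            prod *= 1.0 - b
            expected.append(prod)
        np.testing.assert_allclose(s.alpha_bar, expected, atol=1e-12)

    def test_alpha_bar_strictly_decreasing_and_in_unit_interval(self):
        s = build_schedule(100, 1e-4, 0.05)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert np.all((s.alpha_bar > 0) & (s.alpha_bar < 1))

    def test_posterior_var_below_beta_and_degenerate_first_step(self):
        s = build_schedule(50, 1e-3, 0.1)
        assert s.posterior_var[0] == 0.0
        assert np.all(s.posterior_var <= s.beta + 1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(T=0), dict(T=5, beta_start=0.0), dict(T=5, beta_start=0.5, beta_end=0.2),
         dict(T=5, beta_end=1.0), dict(T=5, kind="cosine")],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        full = dict(T=5, beta_start=0.01, beta_end=0.02, kind="linear")
        full.update(kwargs)
        with pytest.raises(ValueError):
            build_schedule(**full)


# ---------------------------------------------------------------------------
# confidence


class TestConfidence:
    def test_uniform_one_hot_and_generic(self):
        assert confidence(np.full(4, 0.25)) == pytest.approx(0.25)
        assert confidence(np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)
        assert confidence(np.array([0.7, 0.2, 0.1])) == pytest.approx(0.7)

    def test_batch_input_gives_per_sample_scores(self):
        p = np.array([[0.5, 0.5], [0.9, 0.1]])
        np.testing.assert_allclose(confidence(p), [0.5, 0.9])

    def test_rejects_unnormalized_and_negative(self):
        with pytest.raises(ValueError):
            confidence(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            confidence(np.array([-0.1, 1.1]))

    def test_bounds_hold_for_random_softmax_vectors(self, rng):
        for _ in range(50):
            k = rng.integers(2, 9)
            p = rng.dirichlet(np.ones(k))
            c = confidence(p)
            assert 1.0 / k - 1e-12 <= c <= 1.0


# ---------------------------------------------------------------------------
# forward / inverse


@pytest.fixture(scope="module")
def sched():
    return build_schedule(20, 1e-3, 0.2)


class TestForwardDiffuse:
    def test_worked_example(self):
        s = build_schedule(1, 0.36, 0.36)  # abar = 0.64
        y_t = forward_diffuse(
            np.array([1.0, 0.0]), 1, 0.5, np.array([1.0, 1.0]),
            np.array([0.5, 0.5]), s,
        )
        np.testing.assert_allclose(y_t, [1.28, 0.48], atol=1e-12)

    def test_full_confidence_kills_noise(self, sched, rng):
        y0 = rng.standard_normal(3)
        y_t = forward_diffuse(y0, 5, 1.0, rng.standard_normal(3), np.zeros(3), sched)
        np.testing.assert_allclose(y_t, np.sqrt(sched.abar(5)) * y0, atol=1e-12)

    def test_zero_confidence_reduces_to_plain_ddpm_marginal(self, sched, rng):
        y0, eps = rng.standard_normal(4), rng.standard_normal(4)
        y_t = forward_diffuse(y0, 7, 0.0, eps, np.zeros(4), sched)
        abar = sched.abar(7)
        np.testing.assert_allclose(
            y_t, np.sqrt(abar) * y0 + np.sqrt(1 - abar) * eps, atol=1e-12
        )

    def test_step_out_of_range_and_length_mismatch(self, sched):
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(2), 0, 0.5, np.zeros(2), np.zeros(2), sched)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(2), 21, 0.5, np.zeros(2), np.zeros(2), sched)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(2), 1, 0.5, np.zeros(3), np.zeros(2), sched)

    def test_noise_magnitude_monotone_in_confidence(self, sched, rng):
        """Distance to the noiseless state shrinks as confidence rises, zero at c=1."""
        y0, eps, g = rng.standard_normal(3), rng.standard_normal(3), rng.standard_normal(3)
        t, abar = 9, sched.abar(9)
        dists = []
        for c in np.linspace(0, 1, 11):
            y_t = forward_diffuse(y0, t, c, eps, g, sched)
            dists.append(np.linalg.norm(y_t - np.sqrt(abar) * y0 - (1 - abar) * g))
        assert np.all(np.diff(dists) <= 1e-12)
        assert dists[-1] == pytest.approx(0.0, abs=1e-12)


class TestPerturbInterpolated:
    def test_endpoints(self, rng):
        y_pred, y0, eps = rng.standard_normal(3), rng.standard_normal(3), rng.standard_normal(3)
        np.testing.assert_allclose(perturb_interpolated(y_pred, y0, 0.0, 1.0, eps), y0)
        np.testing.assert_allclose(perturb_interpolated(y_pred, y0, 1.0, 1.0, eps), y_pred)

    def test_worked_example(self):
        out = perturb_interpolated(
            np.array([0.0, 1.0]), np.array([1.0, 0.0]), 0.5, 0.5, np.array([2.0, 2.0])
        )
        np.testing.assert_allclose(out, [1.5, 1.5])

    def test_rejects_time_outside_unit_interval(self):
        with pytest.raises(ValueError):
            perturb_interpolated(np.zeros(2), np.zeros(2), 1.5, 0.5, np.zeros(2))


class TestEstimateClean:
    def test_inverts_worked_forward_example(self):
        s = build_schedule(1, 0.36, 0.36)
        y0_hat = estimate_clean(
            np.array([1.28, 0.48]), 1, 0.5, np.array([1.0, 1.0]),
            np.array([0.5, 0.5]), s,
        )
        np.testing.assert_allclose(y0_hat, [1.0, 0.0], atol=1e-12)

    def test_full_confidence_ignores_noise_prediction(self, sched, rng):
        y_t, g = rng.standard_normal(3), rng.standard_normal(3)
        a = estimate_clean(y_t, 4, 1.0, rng.standard_normal(3), g, sched)
        b = estimate_clean(y_t, 4, 1.0, rng.standard_normal(3), g, sched)
        abar = sched.abar(4)
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a, (y_t - (1 - abar) * g) / np.sqrt(abar))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_identity(self, sched, seed):
        """estimate_clean o forward_diffuse is the identity on y0."""
        r = np.random.default_rng(seed)
        K = int(r.integers(2, 8))
        y0, eps, g = r.standard_normal((3, K))
        c = float(r.uniform(0, 1))
        t = int(r.integers(1, sched.T + 1))
        y_t = forward_diffuse(y0, t, c, eps, g, sched)
        np.testing.assert_allclose(
            estimate_clean(y_t, t, c, eps, g, sched), y0, atol=1e-9
        )


# ---------------------------------------------------------------------------
# reverse transition


def _textbook_posterior_mean(y0_hat, y_t, t, s):
    """Independent two-coefficient DDPM posterior mean (guidance-free oracle)."""
    beta = s.beta[t - 1]
    abar = s.alpha_bar[t - 1]
    abar_prev = s.alpha_bar[t - 2] if t > 1 else 1.0
    c0 = np.sqrt(abar_prev) * beta / (1 - abar)
    c1 = np.sqrt(1 - beta) * (1 - abar_prev) / (1 - abar)
    return c0 * y0_hat + c1 * y_t


class TestPosteriorStep:
    def test_first_step_returns_clean_estimate_regardless_of_noise(self, sched, rng):
        y0_hat = rng.standard_normal(4)
        out = posterior_step(
            y0_hat, rng.standard_normal(4), 1, rng.standard_normal(4),
            rng.standard_normal(4), sched,
        )
        np.testing.assert_allclose(out, y0_hat, atol=1e-12)

    def test_matches_textbook_ddpm_without_guidance(self, sched, rng):
        for _ in range(50):
            t = int(rng.integers(1, sched.T + 1))
            y0_hat, y_t = rng.standard_normal((2, 3))
            out = posterior_step(y0_hat, y_t, t, np.zeros(3), np.zeros(3), sched)
            np.testing.assert_allclose(
                out, _textbook_posterior_mean(y0_hat, y_t, t, sched), atol=1e-10
            )

    def test_noiseless_chain_consistent_with_forward_marginals(self, sched, rng):
        """At c=1 the posterior step maps the forward state at t to that at t-1."""
        y0, g = rng.standard_normal((2, 3))
        for t in range(2, sched.T + 1):
            y_t = forward_diffuse(y0, t, 1.0, np.zeros(3), g, sched)
            y_prev = forward_diffuse(y0, t - 1, 1.0, np.zeros(3), g, sched)
            stepped = posterior_step(y0, y_t, t, g, np.zeros(3), sched)
            np.testing.assert_allclose(stepped, y_prev, atol=1e-10)

    def test_step_out_of_range(self, sched):
        with pytest.raises(ValueError):
            posterior_step(np.zeros(2), np.zeros(2), 0, np.zeros(2), np.zeros(2), sched)


# ---------------------------------------------------------------------------
# full reverse sampler


class TestReverseSample:
    def test_deterministic_given_seed(self, sched, rng):
        g = rng.standard_normal(3)
        probs = np.array([0.6, 0.3, 0.1])
        den = lambda y, t, rho, gd: np.zeros(3)
        a, ta = reverse_sample(None, g, den, probs, sched, seed=7, return_trajectory=True)
        b, tb = reverse_sample(None, g, den, probs, sched, seed=7, return_trajectory=True)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ta, tb)

    def test_zero_denoiser_zero_guidance_is_affine_contraction(self, sched):
        """With denoiser = 0, guidance = 0, c = 1 the chain is a deterministic
        affine recursion of the initial state; verify against an independent
        replay of the update equations."""
        probs = np.array([1.0, 0.0])
        y_init = np.array([0.7, -0.4])
        final, traj = reverse_sample(
            None, np.zeros(2), lambda y, t, r, g: np.zeros(2), probs, sched,
            seed=0, y_init=y_init, return_trajectory=True,
        )
        y = y_init.copy()
        states = [y.copy()]
        for t in range(sched.T, 0, -1):
            abar = sched.alpha_bar[t - 1]
            y0h = y / np.sqrt(abar)
            y = _textbook_posterior_mean(y0h, y, t, sched)
            states.append(y.copy())
        np.testing.assert_allclose(traj, states, atol=1e-12)
        np.testing.assert_allclose(final, states[-1], atol=1e-12)

    def test_oracle_denoiser_recovers_planted_clean_vector(self, sched, rng):
        """A denoiser that reports the noise actually present in y_t (computable
        from the planted y0) drives the chain back to y0 exactly."""
        K = 4
        y0 = np.eye(K)[1]
        g = rng.standard_normal(K)
        probs = np.full(K, 1.0 / K)  # c = 1/K, strong noise retained
        c = 1.0 / K

        def oracle(y_t, t, rho, gd):
            abar = sched.alpha_bar[t - 1]
            return (y_t - np.sqrt(abar) * y0 - (1 - abar) * gd) / (
                (1 - c) * np.sqrt(1 - abar)
            )

        y_T = forward_diffuse(y0, sched.T, c, rng.standard_normal(K), g, sched)
        final, _ = reverse_sample(None, g, oracle, probs, sched, seed=5, y_init=y_T)
        np.testing.assert_allclose(final, y0, atol=1e-6)

    def test_denoiser_length_contract(self, sched):
        with pytest.raises(ValueError):
            reverse_sample(
                None, np.zeros(3), lambda y, t, r, g: np.zeros(4),
                np.array([0.5, 0.3, 0.2]), sched, seed=0,
            )
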