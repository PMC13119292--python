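"""aisPLS components: trimmed stats, curvature discriminant, weights,
smoothing-vector update, termination, post-processing, and the full loop."""

import numpy as np
import pytest
from scipy.special import expit

from aispls.adaptive import (
    AisplsConfig,
    ResidualStats,
    aispls_correct,
    aispls_weights,
    converged,
    curvature_ratio,
    postprocess_nonnegative,
    trimmed_stats,
    update_lambda,
)
from aispls.simulate import simulate_dataset


class TestTrimmedStats:
    def test_degenerate_identical_values(self):
        stats = trimmed_stats(np.full(20, -2.5))
        assert stats.m == -2.5
        assert stats.sigma == 0.0
        assert stats.n_removed == 0

    def test_outlier_removed_matches_manual_filtering(self, rng):
        inliers = rng.normal(0.0, 1.0, size=100)
        data = np.concatenate([inliers, [-50.0]])
        stats = trimmed_stats(data)
        # manual single-pass 3-sigma filter as the oracle
        m0, s0 = np.mean(data), np.std(data)
        kept = data[np.abs(data - m0) <= 3 * s0]
        assert stats.m == pytest.approx(np.mean(kept), rel=1e-12)
        assert stats.sigma == pytest.approx(np.std(kept), rel=1e-12)
        assert stats.n_removed == data.size - kept.size

    def test_symmetric_data_trims_symmetrically(self, rng):
        half = rng.normal(0, 1, size=500)
        data = np.concatenate([half, -half])
        stats = trimmed_stats(data)
        removed_low = np.sum(data[np.abs(data - np.mean(data)) > 3 * np.std(data)] < 0)
        removed_high = stats.n_removed - removed_low
        assert removed_low == removed_high

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trimmed_stats(np.array([]))

    def test_threshold_definition(self):
        stats = ResidualStats(m=-3.0, sigma=2.0, n_inliers=10, n_removed=0)
        assert stats.threshold == 3.0 + 4.0


class TestCurvatureRatio:
    def test_identical_curvature_gives_unity(self, rng):
        y = rng.normal(size=50).cumsum()
        q = curvature_ratio(y, y, q_floor=0.01, q_ceil=10.0)
        interior = q[1:-1]
        assert np.allclose(interior, 1.0)

    def test_straight_fit_hits_floor(self, rng):
        y = rng.normal(0, 1, size=60) + np.sin(np.linspace(0, 6, 60))
        z = np.linspace(0, 1, 60)  # zero second difference
        q = curvature_ratio(z, y, q_floor=0.01, q_ceil=1.0)
        assert np.allclose(q, 0.01)

    def test_matches_explicit_convolution_oracle(self, rng):
        from aispls.smoother import SmootherProblem, whittaker_solve

        y = rng.normal(size=80).cumsum()
        z = whittaker_solve(SmootherProblem(y, np.ones(80), 1e7, 2))
        q = curvature_ratio(z, y, q_floor=1e-9, q_ceil=1e9)
        d2z = np.convolve(z, [1, -2, 1], mode="valid")
        d2y = np.convolve(y, [1, -2, 1], mode="valid")
        oracle = np.abs(d2z) / np.maximum(np.abs(d2y), 1e-12)
        assert np.allclose(q[1:-1], oracle)
        assert q[0] == q[1] and q[-1] == q[-2]

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            curvature_ratio(np.ones(2), np.ones(2))


class TestAisplsWeights:
    def _stats(self):
        return ResidualStats(m=-1.0, sigma=0.5, n_inliers=50, n_removed=0)

    def test_half_weight_exactly_at_threshold(self):
        stats = self._stats()
        y = np.array([0.0, 0.0, 0.0])
        z = y - np.array([stats.threshold, -1.0, 0.1])  # d = thr, -1, 0.1
        w = aispls_weights(y, z, t=3, stats=stats, q=np.ones(3))
        assert w[0] == pytest.approx(0.5, abs=1e-12)

    def test_below_fit_gets_full_weight(self, rng):
        stats = self._stats()
        y = rng.normal(size=30)
        z = y + np.abs(rng.normal(size=30)) + 0.1  # y < z everywhere
        w = aispls_weights(y, z, t=5, stats=stats, q=np.ones(30))
        assert np.all(w == 1.0)

    def test_peak_rejection_sharpens_with_iteration(self):
        stats = self._stats()
        d = stats.threshold + 0.3
        y = np.array([d, 0.0, 0.0])
        z = np.zeros(3)
        weights = [aispls_weights(y, z, t, stats, np.ones(3))[0] for t in (1, 2, 5, 20)]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_small_q_saturates_mid_branch_toward_one(self):
        stats = self._stats()
        d = 0.5 * stats.threshold
        y = np.array([d, d, 0.0])
        z = np.zeros(3)
        w = aispls_weights(y, z, 2, stats, q=np.array([1e-6, 1.0, 1.0]))
        assert w[0] > w[1]  # noise-like point kept closer to 1
        assert w[0] == pytest.approx(1.0, abs=1e-6)

    def test_zero_sigma_degenerates_to_hard_threshold(self):
        stats = ResidualStats(m=-1.0, sigma=0.0, n_inliers=5, n_removed=0)
        y = np.array([2.0, 0.5, -1.0])
        z = np.zeros(3)
        w = aispls_weights(y, z, 1, stats, np.ones(3))
        assert list(w) == [0.0, 1.0, 1.0]  # d=2 >= thr=1 -> 0; d=0.5 < thr -> 1

    def test_reduces_to_arpls_rule_without_refinements(self, rng):
        """With trimming off, q = 1 and t = 1 the weight rule is arPLS."""
        from aispls.classic import _arpls_weights

        d = rng.normal(-0.5, 2.0, size=300)
        d_minus = d[d <= 0]
        stats = ResidualStats(
            m=float(np.mean(d_minus)),
            sigma=float(np.std(d_minus)),
            n_inliers=d_minus.size,
            n_removed=0,
        )
        y = d.copy()
        z = np.zeros_like(d)
        w_ais = aispls_weights(y, z, t=1, stats=stats, q=np.ones_like(d))
        w_ar = _arpls_weights(d)
        same = d != 0  # the d == 0 boundary belongs to different branches
        assert np.allclose(w_ais[same], w_ar[same], atol=1e-15)

    def test_rejects_nonpositive_iteration(self):
        with pytest.raises(ValueError):
            aispls_weights(np.zeros(3), np.zeros(3), 0, self._stats(), np.ones(3))


class TestUpdateLambda:
    def _stats(self):
        return ResidualStats(m=-1.0, sigma=0.5, n_inliers=10, n_removed=0)

    def test_uniform_relaxation_when_all_below_threshold(self):
        lam = np.full(5, 1e7)
        d = np.full(5, -0.5)
        out = update_lambda(lam, d, self._stats(), beta=2.0)
        assert np.allclose(out, 5e6)

    def test_repeated_growth_is_exponential_until_cap(self):
        stats = self._stats()
        lam = np.array([1e7])
        d = np.array([stats.threshold + 1.0])
        for k in range(1, 25):
            lam = update_lambda(lam, d, stats, beta=2.0, lam_max=1e12)
            assert lam[0] == pytest.approx(min(1e7 * 2.0**k, 1e12))

    def test_clamped_to_floor(self):
        lam = np.full(3, 10.0)
        d = np.full(3, -1.0)
        out = update_lambda(lam, d, self._stats(), beta=2.0, lam_min=10.0)
        assert np.all(out == 10.0)

    def test_beta_of_one_rejected(self):
        with pytest.raises(ValueError):
            update_lambda(np.ones(3), np.zeros(3), self._stats(), beta=1.0)
        with pytest.raises(ValueError):
            AisplsConfig(beta=1.0)


class TestConverged:
    def test_iteration_cap_forces_true(self):
        assert converged(np.ones(10), np.full(5, -10.0), t=200, T=200, delta=1e-3)

    def test_empty_negative_residuals_converge(self):
        assert converged(np.ones(10), np.array([]), t=1, T=200, delta=1e-3)

    def test_just_above_tolerance_is_not_converged(self):
        y = np.ones(1000)
        d_minus = np.array([-0.0011 * np.sum(np.abs(y))])
        assert not converged(y, d_minus, t=5, T=200, delta=1e-3)

    def test_just_below_tolerance_is_converged(self):
        y = np.ones(1000)
        d_minus = np.array([-0.0009 * np.sum(np.abs(y))])
        assert converged(y, d_minus, t=5, T=200, delta=1e-3)


class TestPostprocess:
    def test_negatives_zeroed_peak_flank_survives(self):
        out, zeroed = postprocess_nonnegative(np.array([-1.0, -2.0, 5.0, 6.0, 7.0]), sigma=10.0)
        assert list(out) == [0.0, 0.0, 5.0, 6.0, 7.0]
        assert list(zeroed) == [True, True, False, False, False]

    def test_nonnegative_input_unchanged(self):
        x = np.array([0.0, 1.0, 0.5, 2.0])
        out, zeroed = postprocess_nonnegative(x, sigma=1.0)
        assert np.array_equal(out, x)
        assert not zeroed.any()

    def test_small_nonmonotone_blip_after_negative_run_is_zeroed(self):
        # hand-traceable 10-point fixture: the 0.3 blip at index 3 follows a
        # negative point, is below sigma, steps < sigma, and its 3-point
        # window (0.3, 0.4, 0.2) is not monotone -> zeroed
        x = np.array([1.0, -0.2, -0.5, 0.3, 0.4, 0.2, -0.1, 3.0, 4.0, 5.0])
        out, zeroed = postprocess_nonnegative(x, sigma=0.6)
        assert out[3] == 0.0 and zeroed[3]
        assert out[7] == 3.0  # rising peak flank survives (window monotone)
        assert np.all(out >= 0)

    def test_blip_larger_than_sigma_survives(self):
        x = np.array([-0.5, 2.0, 2.1, 1.9, 0.0])
        out, _ = postprocess_nonnegative(x, sigma=0.5)
        assert out[1] == 2.0

    def test_short_vector_skips_window_rule(self):
        out, _ = postprocess_nonnegative(np.array([-1.0, 0.5]), sigma=10.0)
        assert list(out) == [0.0, 0.5]


class TestAisplsCorrect:
    def test_noiseless_benchmark_baseline_recovery(self):
        # residual error is the unresolvable smooth pedestal of Lorentzian
        # tails; bound frozen from the noise-free oracle run
        sim = simulate_dataset(float("inf"))
        res = aispls_correct(sim.composite)
        rmse = float(np.sqrt(np.mean((res.baseline - sim.baseline) ** 2)))
        assert rmse < 2.5

    def test_flat_spectrum_corrects_to_zero(self):
        res = aispls_correct(np.full(300, 25.0))
        assert np.allclose(res.baseline, 25.0, atol=1e-6)
        assert np.allclose(res.corrected, 0.0, atol=1e-6)

    def test_corrected_nonnegative_after_postprocess(self, sim20):
        res = aispls_correct(sim20.composite)
        assert res.postprocessed
        assert np.all(res.corrected >= 0)

    def test_weights_and_lambda_bounded_every_iteration(self, sim20):
        config = AisplsConfig()
        res = aispls_correct(sim20.composite, config)
        for rec in res.trace.records:
            assert -1e-12 <= rec.weight_min <= rec.weight_max <= 1 + 1e-12
            assert config.effective_lam_min - 1e-6 <= rec.lam_min
            assert rec.lam_max <= config.lam_max * (1 + 1e-12)

    def test_iteration_cap_respected(self, sim20):
        res = aispls_correct(sim20.composite, AisplsConfig(T=15))
        assert res.n_iterations <= 15

    def test_deterministic_given_input(self, sim20):
        r1 = aispls_correct(sim20.composite)
        r2 = aispls_correct(sim20.composite)
        assert np.array_equal(r1.baseline, r2.baseline)
        assert np.array_equal(r1.corrected, r2.corrected)

    def test_no_postprocess_keeps_raw_subtraction(self, sim20):
        res = aispls_correct(sim20.composite, AisplsConfig(postprocess=False))
        assert not res.postprocessed
        assert np.allclose(res.corrected, sim20.composite - res.baseline)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            aispls_correct(np.array([1.0, np.inf, 2.0]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AisplsConfig(lam0=-1.0)
        with pytest.raises(ValueError):
            AisplsConfig(delta=2.0)
        with pytest.raises(ValueError):
            AisplsConfig(T=0)
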