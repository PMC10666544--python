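"""Synthetic-control estimation: weights, ridge correction, intervals, placebos."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import airsynth as ax
from airsynth.ascm import RidgeAugmentedSCM


def simplex_grid_oracle(Y0, y1, step=0.001):
    """Exhaustive search over the 3-simplex at the given step."""
    best, best_val = None, np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for a in ticks:
        # vectorize over b for speed
        b = np.arange(0, 1 - a + step / 2, step)
        c = 1.0 - a - b
        gammas = np.stack([np.full_like(b, a), b, c], axis=1)
        resid = y1[None, :] - gammas @ Y0
        vals = (resid**2).sum(axis=1)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best_val, best = float(vals[i]), gammas[i]
    return best


class TestScmWeights:
    def test_exact_match_corner(self):
        rng = np.random.default_rng(1)
        Y0 = rng.normal(50, 8, (4, 6))
        gamma = ax.fit_scm_weights(Y0, Y0[2].copy())
        np.testing.assert_allclose(gamma, [0, 0, 1, 0], atol=1e-6)

    def test_mean_target_gives_uniform(self):
        rng = np.random.default_rng(2)
        Y0 = rng.normal(50, 8, (3, 5))
        gamma = ax.fit_scm_weights(Y0, Y0.mean(axis=0))
        np.testing.assert_allclose(gamma, 1 / 3, atol=2e-3)
        oracle = simplex_grid_oracle(Y0, Y0.mean(axis=0))
        np.testing.assert_allclose(gamma, oracle, atol=2e-3)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_simplex_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y0 = rng.integers(1, 9, size=(3, 4)).astype(float)
        y1 = rng.integers(1, 9, size=4).astype(float)
        gamma = ax.fit_scm_weights(Y0, y1)
        oracle = simplex_grid_oracle(Y0, y1)
        np.testing.assert_allclose(gamma, oracle, atol=2e-3)

    def test_missing_and_shape_errors(self):
        Y0 = np.ones((3, 4))
        with pytest.raises(ValueError, match="missing"):
            ax.fit_scm_weights(np.where(np.eye(3, 4) > 0, np.nan, Y0), np.ones(4))
        with pytest.raises(ValueError):
            ax.fit_scm_weights(Y0, np.ones(3))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_simplex_feasibility_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        t = int(rng.integers(2, 12))
        Y0 = rng.normal(50, 10, (n, t))
        y1 = rng.normal(50, 10, t)
        gamma = ax.fit_scm_weights(Y0, y1)
        assert (gamma >= 0).all()
        assert gamma.sum() == pytest.approx(1.0, abs=1e-8)
        # fitted weights cannot do worse than uniform weights
        rmse = np.sqrt(np.mean((y1 - Y0.T @ gamma) ** 2))
        rmse_u = np.sqrt(np.mean((y1 - Y0.mean(axis=0)) ** 2))
        assert rmse <= rmse_u + 1e-6


class TestRidgeOutcome:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(7)
        Y0_pre = rng.normal(40, 10, (5, 8))
        Y0_post = rng.normal(40, 10, (5, 6))
        lam = 3.7
        eta, chosen = ax.fit_ridge_outcome(Y0_pre, Y0_post, lambda_grid=[lam])
        assert chosen == lam
        Xc = Y0_pre - Y0_pre.mean(axis=0, keepdims=True)
        # independent closed form, one solve per post week
        for s in range(Y0_post.shape[1]):
            want = np.linalg.solve(
                Xc.T @ Xc + lam * np.eye(8), Xc.T @ Y0_post[:, s]
            )
            np.testing.assert_allclose(eta[s], want, atol=1e-8)

    def test_replicated_column_reproduced_at_lambda_zero(self):
        rng = np.random.default_rng(8)
        Y0_pre = rng.normal(40, 10, (6, 4))  # full column rank when centered
        Y0_post = Y0_pre[:, -1:].copy()
        eta, lam = ax.fit_ridge_outcome(Y0_pre, Y0_post, lambda_grid=[0.0])
        assert lam == 0.0
        np.testing.assert_allclose(eta[0], [0, 0, 0, 1], atol=1e-8)

    def test_singular_at_zero_falls_back(self):
        rng = np.random.default_rng(9)
        Y0_pre = rng.normal(40, 10, (4, 8))  # centered rank 3 < 8 columns
        Y0_post = rng.normal(40, 10, (4, 3))
        with pytest.warns(UserWarning, match="singular"):
            _, lam = ax.fit_ridge_outcome(Y0_pre, Y0_post, lambda_grid=[0.0, 2.5])
        assert lam == 2.5

    def test_infinite_penalty_shrinks_eta(self):
        rng = np.random.default_rng(10)
        Y0_pre = rng.normal(40, 10, (5, 8))
        Y0_post = rng.normal(40, 10, (5, 4))
        eta, _ = ax.fit_ridge_outcome(Y0_pre, Y0_post, lambda_grid=[1e12])
        assert np.linalg.norm(eta) < 1e-6

    def test_needs_three_controls(self):
        with pytest.raises(ValueError, match=">= 3"):
            ax.fit_ridge_outcome(np.ones((2, 4)), np.ones((2, 2)))


class TestAscmEstimate:
    def _system(self, seed=11, n=3, t0=4, t1=3):
        rng = np.random.default_rng(seed)
        return (
            rng.normal(50, 5, (n, t0)),
            rng.normal(50, 5, (n, t1)),
            rng.normal(50, 5, t0),
        )

    def test_exact_prefit_needs_no_correction(self):
        Y0_pre, Y0_post, _ = self._system()
        gamma = np.array([0.2, 0.5, 0.3])
        y1 = Y0_pre.T @ gamma  # lies exactly on the simplex combination
        eta = np.random.default_rng(0).normal(size=(3, 4))
        fit = ax.ascm_estimate(Y0_pre, Y0_post, y1, gamma, eta)
        np.testing.assert_allclose(
            fit.counterfactual.to_numpy(), fit.scm_counterfactual.to_numpy(), atol=1e-6
        )
        assert fit.pre_rmse == pytest.approx(0.0, abs=1e-9)

    def test_zero_eta_reduces_to_scm(self):
        Y0_pre, Y0_post, y1 = self._system(12)
        gamma = np.full(3, 1 / 3)
        fit = ax.ascm_estimate(Y0_pre, Y0_post, y1, gamma, np.zeros((3, 4)))
        np.testing.assert_allclose(
            fit.counterfactual.to_numpy(), fit.scm_counterfactual.to_numpy()
        )

    def test_hand_computed_three_control_case(self):
        Y0_pre = np.array([[1.0, 2, 3, 4], [2, 2, 2, 2], [4, 3, 2, 1]])
        Y0_post = np.array([[5.0, 6], [2, 2], [1, 0]])
        y1 = np.array([2.0, 2, 3, 3])
        gamma = np.array([0.5, 0.25, 0.25])
        eta = np.array([[0.1, 0.0, -0.1, 0.2], [0.0, 0.3, 0.0, 0.0]])
        fit = ax.ascm_estimate(Y0_pre, Y0_post, y1, gamma, eta)
        # independent arithmetic with explicit loops
        scm_post = [sum(gamma[i] * Y0_post[i, s] for i in range(3)) for s in range(2)]
        imb = [y1[t] - sum(gamma[i] * Y0_pre[i, t] for i in range(3)) for t in range(4)]
        want = [scm_post[s] + sum(eta[s, t] * imb[t] for t in range(4)) for s in range(2)]
        np.testing.assert_allclose(fit.counterfactual.to_numpy()[-2:], want, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        Y0_pre = rng.normal(50, 6, (6, 10))
        Y0_post = rng.normal(50, 6, (6, 5))
        y1 = rng.normal(50, 6, 10)
        est = RidgeAugmentedSCM(lambda_grid=[1.0]).fit(Y0_pre, y1, Y0_post)
        shifted = RidgeAugmentedSCM(lambda_grid=[1.0]).fit(
            Y0_pre + 100.0, y1 + 100.0, Y0_post + 100.0
        )
        np.testing.assert_allclose(
            shifted.counterfactual_.to_numpy(),
            est.counterfactual_.to_numpy() + 100.0,
            atol=1e-6,
        )

    def test_infinite_lambda_limit_is_scm(self):
        rng = np.random.default_rng(14)
        Y0_pre = rng.normal(50, 6, (6, 10))
        Y0_post = rng.normal(50, 6, (6, 5))
        y1 = rng.normal(50, 6, 10)
        est = RidgeAugmentedSCM(lambda_grid=[1e14]).fit(Y0_pre, y1, Y0_post)
        np.testing.assert_allclose(
            est.counterfactual_.to_numpy(),
            est.scm_counterfactual_.to_numpy(),
            atol=1e-6,
        )

    def test_prefit_dominance_attribute(self):
        rng = np.random.default_rng(15)
        Y0_pre = rng.normal(50, 6, (8, 12))
        Y0_post = rng.normal(50, 6, (8, 6))
        y1 = rng.normal(50, 6, 12)
        est = RidgeAugmentedSCM().fit(Y0_pre, y1, Y0_post)
        assert est.pre_rmse_ <= est.pre_rmse_uniform_ + 1e-9


class TestJackknifePlus:
    def test_refuses_below_five_controls(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError, match="5"):
            ax.jackknife_plus(
                rng.normal(size=(4, 6)), rng.normal(size=(4, 3)),
                rng.normal(size=6), lam=1.0,
            )

    def test_degenerate_identical_controls_zero_width(self):
        row_pre = np.linspace(40, 50, 8)
        row_post = np.linspace(50, 45, 4)
        Y0_pre = np.tile(row_pre, (6, 1))
        Y0_post = np.tile(row_post, (6, 1))
        lo, hi = ax.jackknife_plus(Y0_pre, Y0_post, row_pre.copy(), lam=1.0)
        np.testing.assert_allclose(lo, row_post, atol=1e-8)
        np.testing.assert_allclose(hi, row_post, atol=1e-8)

    def test_zero_weight_control_has_no_scm_influence(self):
        rng = np.random.default_rng(17)
        Y0_pre = rng.normal(50, 5, (6, 10))
        y1 = Y0_pre[:5].mean(axis=0)  # far from control 5 shifted away
        Y0_pre[5] += 200.0
        Y0_post = rng.normal(50, 5, (6, 4))
        gamma = ax.fit_scm_weights(Y0_pre, y1)
        assert gamma[5] == pytest.approx(0.0, abs=1e-8)
        gamma_red = ax.fit_scm_weights(Y0_pre[:5], y1)
        np.testing.assert_allclose(
            Y0_post.T @ gamma, Y0_post[:5].T @ gamma_red, atol=1e-5
        )

    def test_interval_brackets_counterfactual_on_smooth_system(self):
        rng = np.random.default_rng(18)
        base = np.sin(np.linspace(0, 3, 16))[None, :] * 10 + 50
        Y0 = base + rng.normal(0, 1.0, (8, 16))
        y1 = base[0] + rng.normal(0, 1.0, 16)
        est = RidgeAugmentedSCM().fit(Y0[:, :10], y1[:10], Y0[:, 10:])
        lo, hi = est.conformal_interval()
        cf = est.counterfactual_.to_numpy()[10:]
        assert (lo.to_numpy() <= cf + 1e-9).all() and (cf <= hi.to_numpy() + 1e-9).all()


class TestPlacebo:
    def _weekly_system(self, effect, seed=0, n=10, t0=20, t1=12):
        rng = np.random.default_rng(seed)
        season = 50 + 8 * np.sin(np.linspace(0, 2 * np.pi, t0 + t1))
        Y0 = season[None, :] + rng.normal(0, 1.5, (n, t0 + t1))
        y1 = season + rng.normal(0, 1.5, t0 + t1)
        y1[t0:] += effect
        return Y0[:, :t0], Y0[:, t0:], y1[:t0], y1[t0:]

    def test_strong_effect_ranks_first(self):
        Y0_pre, Y0_post, y1_pre, y1_post = self._weekly_system(effect=10.0, seed=21)
        res = ax.placebo_scan(Y0_pre, Y0_post, y1_pre, y1_post)
        assert res.pseudo_p == pytest.approx(1 / 11)
        assert res.treated_mean_effect == pytest.approx(10.0, abs=1.5)
        assert len(res.placebo_mean_effects) == 10

    def test_placebo_pool_excludes_pseudo_treated_unit(self):
        Y0_pre, Y0_post, y1_pre, y1_post = self._weekly_system(effect=0.0, seed=22)
        res = ax.placebo_scan(Y0_pre, Y0_post, y1_pre, y1_post)
        assert 0 < res.pseudo_p <= 1
        assert res.placebo_effects.shape == (10, 12)

    def test_too_few_controls_refused(self):
        Y0_pre, Y0_post, y1_pre, y1_post = self._weekly_system(effect=0.0, n=4)
        with pytest.raises(ValueError, match=">= 5"):
            ax.placebo_scan(Y0_pre, Y0_post, y1_pre, y1_post)
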