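"""Ridge-augmented synthetic control estimation with finite-sample intervals.

The synthetic control method (SCM) reproduces a treated unit's pre-treatment
outcome trajectory with a convex combination of control units; the weighted
combination of the controls' post-treatment outcomes is the counterfactual.
The ridge-augmented variant (ASCM) additionally fits, across control units,
a ridge regression of each post-period outcome on the centered pre-period
outcomes and uses it to correct the SCM estimate for whatever pre-treatment
imbalance the simplex weights could not remove::

    cf(s) = gamma' Y0_post[:, s]  +  (y1_pre - Y0_pre' gamma)' eta_s
    eta_s = (X'X + lambda I)^-1 X' y_s,   X = Y0_pre centered over controls

With an exact pre-fit the correction vanishes and ASCM equals SCM; as
``lambda`` grows the correction shrinks to zero, so SCM is the infinite-
penalty limit. ``lambda`` is selected by leave-one-control-out cross-
validation of the augmented prediction.

Pointwise uncertainty comes from the Jackknife+ procedure: each control is
left out in turn, the model refit, and the counterfactual interval at each
post week is built from the leave-one-out counterfactuals offset by the
leave-one-out pre-period RMSE, using the finite-sample order-statistic
quantile convention. Inference against the sharp null uses in-place placebo
tests: every control is pretended to be treated and the treated unit's
heating-period mean effect is ranked among the placebo effects.

All solvers are deterministic; identical inputs give identical output bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AscmFit",
    "PlaceboResult",
    "RidgeAugmentedSCM",
    "fit_scm_weights",
    "fit_ridge_outcome",
    "ascm_estimate",
    "jackknife_plus",
    "placebo_scan",
    "default_lambda_grid",
]


# --------------------------------------------------------------- simplex QP
def _polish_support(G, f, gamma, support, tol):
    """Re-solve on the final support without the tie-break ridge.

    Removes the (tiny) bias the scaled tie-break introduces, so vertex
    solutions (single-control matches) come out exact. Falls back to the
    ridged solution if the unridged system is degenerate or leaves the
    simplex face.
    """
    n = len(gamma)
    k = int(support.sum())
    if k == 0:
        return gamma
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = 2.0 * G[np.ix_(support, support)]
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([-f[support], [1.0]])
    try:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return gamma
    cand = np.zeros(n)
    cand[support] = sol[:k]
    if (cand < -tol).any() or abs(cand.sum() - 1.0) > 1e-8:
        return gamma
    cand = np.maximum(cand, 0.0)
    cand /= cand.sum()
    # accept only if it does not worsen the unridged objective
    def ss(w):
        return float(w @ G @ w + f @ w)
    return cand if ss(cand) <= ss(gamma) + tol * max(1.0, abs(ss(gamma))) else gamma


def fit_scm_weights(
    Y0_pre: np.ndarray,
    y1_pre: np.ndarray,
    l2: float = 1e-8,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> np.ndarray:
    """Simplex-constrained least-squares weights for the synthetic unit.

    Minimizes ``||y1_pre - Y0_pre' gamma||^2 + l2 ||gamma||^2`` subject to
    ``gamma >= 0`` and ``sum(gamma) = 1`` with a primal active-set method on
    the KKT system; the tiny ridge term breaks ties so the solution is
    unique. Convergence is verified against the KKT conditions at ``tol``.

    Parameters
    ----------
    Y0_pre : (n_controls, n_pre) array
        Control outcomes, one row per control unit.
    y1_pre : (n_pre,) array
        Treated unit's pre-treatment outcomes.
    """
    Y0 = np.asarray(Y0_pre, dtype=float)
    y1 = np.asarray(y1_pre, dtype=float)
    if Y0.ndim != 2 or y1.ndim != 1 or Y0.shape[1] != y1.shape[0]:
        raise ValueError(f"shape mismatch: Y0 {Y0.shape}, y1 {y1.shape}")
    n = Y0.shape[0]
    if n < 2 or Y0.shape[1] < 2:
        raise ValueError("need >= 2 controls and >= 2 pre periods")
    if np.isnan(Y0).any() or np.isnan(y1).any():
        raise ValueError("missing entries must be imputed before fitting")

    G = Y0 @ Y0.T
    # tie-break ridge, scaled to the data so it stays tiny but effective
    ridge = l2 * max(1.0, float(np.trace(G)) / n)
    H = 2.0 * (G + ridge * np.eye(n))
    f = -2.0 * (Y0 @ y1)
    scale = max(1.0, np.abs(H).max(), np.abs(f).max())

    # primal active-set method: keep gamma feasible, track active bounds
    gamma = np.full(n, 1.0 / n)
    active = np.zeros(n, dtype=bool)

    def eqp_direction(mask_active: np.ndarray):
        """Step to the minimizer restricted to inactive coords, and mu."""
        freem = ~mask_active
        k = int(freem.sum())
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = H[np.ix_(freem, freem)]
        K[:k, k] = 1.0
        K[k, :k] = 1.0
        rhs = np.concatenate([-f[freem], [1.0]])
        sol = np.linalg.solve(K, rhs)
        target = np.zeros(n)
        target[freem] = sol[:k]
        return target - gamma, float(sol[k])

    for _ in range(max_iter):
        d, mu = eqp_direction(active)
        if np.abs(d).max() <= tol:
            grad = H @ gamma + f
            lam = grad + mu  # bound multipliers on the active set
            if active.any() and (lam[active] < -tol * scale).any():
                release = int(np.argmin(np.where(active, lam, np.inf)))
                active[release] = False
                continue
            gamma = np.maximum(gamma, 0.0)
            gamma /= gamma.sum()
            support = gamma > tol
            stat = np.abs(lam[support]).max() if support.any() else 0.0
            if stat > 10 * tol * scale:
                raise RuntimeError(
                    f"simplex QP failed KKT check: stationarity {stat:.2e} "
                    f"(scale {scale:.2e}), support size {int(support.sum())}"
                )
            return _polish_support(G, f, gamma, support, tol)
        blocking = (~active) & (d < -tol)
        if blocking.any():
            ratios = np.where(blocking, -gamma / np.where(d < 0, d, -1.0), np.inf)
            alpha = min(1.0, float(ratios.min()))
        else:
            alpha = 1.0
        gamma = gamma + alpha * d
        if alpha < 1.0:
            hit = int(np.argmin(ratios))
            gamma[hit] = 0.0
            active[hit] = True
    raise RuntimeError(f"simplex QP did not converge in {max_iter} iterations")


def default_lambda_grid(Y0_pre: np.ndarray, size: int = 10) -> np.ndarray:
    """Log-spaced ridge penalties scaled to the centered Gram diagonal."""
    X = np.asarray(Y0_pre, float)
    Xc = X - X.mean(axis=0, keepdims=True)
    scale = float(np.mean(np.sum(Xc**2, axis=0)))
    scale = scale if scale > 0 else 1.0
    return scale * np.logspace(-3, 3, size)


def _ridge_eta(Xc: np.ndarray, Y0_post: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge coefficients, one row per post period."""
    T0 = Xc.shape[1]
    A = Xc.T @ Xc + lam * np.eye(T0)
    B = Xc.T @ Y0_post  # (T0, T1)
    if lam == 0:
        # may be singular; use least-squares pseudo-solution
        eta, *_ = np.linalg.lstsq(A, B, rcond=None)
    else:
        eta = np.linalg.solve(A, B)
    return eta.T  # (T1, T0)


def _augmented_cf(
    Y0_pre: np.ndarray, Y0_post: np.ndarray, y1_pre: np.ndarray,
    gamma: np.ndarray, eta: np.ndarray,
) -> np.ndarray:
    imbalance = y1_pre - Y0_pre.T @ gamma
    return Y0_post.T @ gamma + eta @ imbalance


def fit_ridge_outcome(
    Y0_pre: np.ndarray,
    Y0_post: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Ridge outcome model with leave-one-control-out penalty selection.

    For each candidate ``lambda``, every control unit is held out in turn,
    SCM weights and ridge coefficients are refit on the remainder, and the
    held-out unit's post outcomes are predicted with the augmented
    counterfactual formula; the ``lambda`` with the smallest summed squared
    CV error wins. Returns ``(eta, lambda)`` with ``eta`` of shape
    ``(n_post, n_pre)``.
    """
    Y0_pre = np.asarray(Y0_pre, float)
    Y0_post = np.asarray(Y0_post, float)
    n = Y0_pre.shape[0]
    if n < 3:
        raise ValueError("ridge CV needs >= 3 controls")
    if Y0_post.shape[0] != n:
        raise ValueError("pre and post control matrices disagree on units")
    grid = default_lambda_grid(Y0_pre) if lambda_grid is None else np.asarray(
        lambda_grid, float
    )
    if (grid < 0).any():
        raise ValueError("ridge penalties must be >= 0")
    if (grid == 0).any():
        Xc0 = Y0_pre - Y0_pre.mean(axis=0, keepdims=True)
        A0 = Xc0.T @ Xc0
        if np.linalg.matrix_rank(A0) < A0.shape[0]:
            positive = grid[grid > 0]
            if positive.size == 0:
                raise ValueError(
                    "lambda=0 is singular here and the grid has no positive value"
                )
            warnings.warn(
                "singular system at lambda=0; falling back to smallest positive "
                "grid value"
            )
            grid = positive

    # per-held-out-unit pieces that do not depend on lambda
    loo = []
    for i in range(n):
        keep = np.arange(n) != i
        gam = fit_scm_weights(Y0_pre[keep], Y0_pre[i])
        loo.append((keep, gam))

    best_lam, best_err = None, np.inf
    for lam in grid:
        err = 0.0
        for i, (keep, gam) in enumerate(loo):
            Xi = Y0_pre[keep]
            Xc = Xi - Xi.mean(axis=0, keepdims=True)
            try:
                eta_i = _ridge_eta(Xc, Y0_post[keep], lam)
            except np.linalg.LinAlgError:
                err = np.inf
                break
            cf = _augmented_cf(Xi, Y0_post[keep], Y0_pre[i], gam, eta_i)
            err += float(np.sum((Y0_post[i] - cf) ** 2))
        if err < best_err:
            best_err, best_lam = err, float(lam)
    if best_lam is None:
        raise RuntimeError("ridge CV failed for every penalty in the grid")

    Xc = Y0_pre - Y0_pre.mean(axis=0, keepdims=True)
    eta = _ridge_eta(Xc, Y0_post, best_lam)
    return eta, best_lam


@dataclass
class AscmFit:
    """One treated unit x heating-year augmented synthetic control fit."""

    gamma: np.ndarray
    lam: float
    eta: np.ndarray
    counterfactual: pd.Series  # pre + post weeks
    scm_counterfactual: pd.Series
    pre_rmse: float
    pre_rmse_uniform: float
    control_ids: list[str] = field(default_factory=list)
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None

    def to_dict(self) -> dict:
        out = {
            "gamma": dict(zip(self.control_ids, np.round(self.gamma, 10).tolist()))
            if self.control_ids
            else self.gamma.tolist(),
            "lambda": self.lam,
            "pre_rmse": self.pre_rmse,
            "pre_rmse_uniform": self.pre_rmse_uniform,
            "counterfactual": {
                str(k.date()): float(v) for k, v in self.counterfactual.items()
            },
        }
        if self.ci_lower is not None:
            out["ci_lower"] = {str(k.date()): float(v) for k, v in self.ci_lower.items()}
            out["ci_upper"] = {str(k.date()): float(v) for k, v in self.ci_upper.items()}
        return out


def ascm_estimate(
    Y0_pre: np.ndarray,
    Y0_post: np.ndarray,
    y1_pre: np.ndarray,
    gamma: np.ndarray,
    eta: np.ndarray,
    lam: float = np.nan,
    pre_index=None,
    post_index=None,
    control_ids: list[str] | None = None,
) -> AscmFit:
    """Assemble the augmented counterfactual and pre-fit diagnostics.

    ``counterfactual`` covers pre weeks (the SCM fit path — the ridge
    correction applies only after treatment begins) followed by the
    corrected post weeks; ``scm_counterfactual`` is the uncorrected weighted
    average throughout. ``pre_rmse_uniform`` uses equal weights ``1/n`` and
    upper-bounds ``pre_rmse`` of the fitted weights.
    """
    Y0_pre = np.asarray(Y0_pre, float)
    Y0_post = np.asarray(Y0_post, float)
    y1_pre = np.asarray(y1_pre, float)
    gamma = np.asarray(gamma, float)
    n = Y0_pre.shape[0]
    if Y0_post.shape[0] != n or gamma.shape[0] != n:
        raise ValueError("unit dimension mismatch")
    if eta.shape != (Y0_post.shape[1], Y0_pre.shape[1]):
        raise ValueError(
            f"eta must be (n_post, n_pre) = {(Y0_post.shape[1], Y0_pre.shape[1])}"
        )
    scm_pre = Y0_pre.T @ gamma
    scm_post = Y0_post.T @ gamma
    cf_post = _augmented_cf(Y0_pre, Y0_post, y1_pre, gamma, eta)
    uniform = np.full(n, 1.0 / n)
    pre_rmse = float(np.sqrt(np.mean((y1_pre - scm_pre) ** 2)))
    pre_rmse_uniform = float(np.sqrt(np.mean((y1_pre - Y0_pre.T @ uniform) ** 2)))
    if pre_index is None:
        pre_index = pd.RangeIndex(len(y1_pre))
        post_index = pd.RangeIndex(len(y1_pre), len(y1_pre) + Y0_post.shape[1])
    idx = pre_index.append(post_index)
    return AscmFit(
        gamma=gamma,
        lam=float(lam),
        eta=np.asarray(eta, float),
        counterfactual=pd.Series(np.concatenate([scm_pre, cf_post]), index=idx),
        scm_counterfactual=pd.Series(np.concatenate([scm_pre, scm_post]), index=idx),
        pre_rmse=pre_rmse,
        pre_rmse_uniform=pre_rmse_uniform,
        control_ids=list(control_ids) if control_ids else [],
    )


class RidgeAugmentedSCM(BaseEstimator):
    """Sklearn-style ridge-augmented synthetic control estimator.

    Parameters
    ----------
    lambda_grid : array-like or None
        Candidate ridge penalties; ``None`` uses 10 log-spaced values scaled
        by the centered pre-period Gram diagonal.
    alpha : float
        Miscoverage level of the Jackknife+ pointwise intervals.
    l2 : float
        Tie-breaking ridge added to the simplex weight QP.

    Attributes (after ``fit``)
    --------------------------
    gamma_, lambda_, eta_, counterfactual_, scm_counterfactual_,
    pre_rmse_, pre_rmse_uniform_, fit_ : :class:`AscmFit`
    """

    def __init__(self, lambda_grid=None, alpha: float = 0.05, l2: float = 1e-8):
        self.lambda_grid = lambda_grid
        self.alpha = alpha
        self.l2 = l2

    @staticmethod
    def _coerce(Y0_pre, y1_pre, Y0_post):
        if isinstance(Y0_pre, pd.DataFrame):
            ids = list(Y0_pre.index)
            pre_index = pd.DatetimeIndex(Y0_pre.columns)
            post_index = pd.DatetimeIndex(Y0_post.columns)
            return (
                Y0_pre.to_numpy(float),
                np.asarray(y1_pre, float),
                Y0_post.to_numpy(float),
                ids, pre_index, post_index,
            )
        return (
            np.asarray(Y0_pre, float),
            np.asarray(y1_pre, float),
            np.asarray(Y0_post, float),
            None, None, None,
        )

    def fit(self, Y0_pre, y1_pre, Y0_post) -> "RidgeAugmentedSCM":
        """Fit weights and outcome model; rows of Y0_* are control units."""
        A, y1, B, ids, pre_idx, post_idx = self._coerce(Y0_pre, y1_pre, Y0_post)
        gamma = fit_scm_weights(A, y1, l2=self.l2)
        eta, lam = fit_ridge_outcome(A, B, self.lambda_grid)
        fit = ascm_estimate(
            A, B, y1, gamma, eta, lam,
            pre_index=pre_idx, post_index=post_idx, control_ids=ids or [],
        )
        self.gamma_ = gamma
        self.lambda_ = lam
        self.eta_ = eta
        self.counterfactual_ = fit.counterfactual
        self.scm_counterfactual_ = fit.scm_counterfactual
        self.pre_rmse_ = fit.pre_rmse
        self.pre_rmse_uniform_ = fit.pre_rmse_uniform
        self.fit_ = fit
        self._data_ = (A, y1, B, pre_idx, post_idx)
        return self

    def predict(self) -> pd.Series:
        """Counterfactual trajectory over pre + post weeks."""
        return self.counterfactual_

    def conformal_interval(self) -> tuple[pd.Series, pd.Series]:
        """Jackknife+ pointwise intervals; also stored on ``fit_``."""
        A, y1, B, pre_idx, post_idx = self._data_
        lo, hi = jackknife_plus(
            A, B, y1, lam=self.lambda_, alpha=self.alpha, l2=self.l2
        )
        index = post_idx if post_idx is not None else pd.RangeIndex(
            len(y1), len(y1) + B.shape[1]
        )
        self.fit_.ci_lower = pd.Series(lo, index=index)
        self.fit_.ci_upper = pd.Series(hi, index=index)
        return self.fit_.ci_lower, self.fit_.ci_upper


def jackknife_plus(
    Y0_pre: np.ndarray,
    Y0_post: np.ndarray,
    y1_pre: np.ndarray,
    lam: float,
    alpha: float = 0.05,
    l2: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Jackknife+ pointwise (1 - alpha) intervals for the counterfactual.

    Each control ``i`` is deleted in turn and the ASCM refit (the ridge
    penalty is kept at the full-fit value so refits stay deterministic and
    cheap); the leave-one-out counterfactual ``cf_-i(s)`` is offset by the
    leave-one-out pre-period RMSE ``R_i`` and the interval at week ``s`` is
    built from the order statistics of ``cf_-i(s) -/+ R_i`` at the
    finite-sample Jackknife+ ranks (upper rank ``ceil((1-alpha)(n+1))``,
    clamped to the sample when it exceeds ``n``).
    """
    Y0_pre = np.asarray(Y0_pre, float)
    Y0_post = np.asarray(Y0_post, float)
    y1_pre = np.asarray(y1_pre, float)
    n = Y0_pre.shape[0]
    if n < 5:
        raise ValueError(f"Jackknife+ interval undefined for {n} < 5 controls")
    cfs = np.empty((n, Y0_post.shape[1]))
    res = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        gam = fit_scm_weights(Y0_pre[keep], y1_pre, l2=l2)
        Xi = Y0_pre[keep]
        Xc = Xi - Xi.mean(axis=0, keepdims=True)
        eta_i = _ridge_eta(Xc, Y0_post[keep], lam)
        cfs[i] = _augmented_cf(Xi, Y0_post[keep], y1_pre, gam, eta_i)
        res[i] = np.sqrt(np.mean((y1_pre - Xi.T @ gam) ** 2))

    k_hi = int(np.ceil((1 - alpha) * (n + 1)))
    k_hi = min(k_hi, n)
    k_lo = max(n + 1 - int(np.ceil((1 - alpha) * (n + 1))), 1)
    lower = np.sort(cfs - res[:, None], axis=0)[k_lo - 1]
    upper = np.sort(cfs + res[:, None], axis=0)[k_hi - 1]
    return lower, upper


@dataclass
class PlaceboResult:
    """In-place placebo scan over the control pool."""

    treated_effect: pd.Series
    treated_mean_effect: float
    placebo_effects: pd.DataFrame  # one row per placebo unit, post weeks
    placebo_mean_effects: pd.Series
    pseudo_p: float


def placebo_scan(
    Y0_pre,
    Y0_post,
    y1_pre,
    y1_post,
    lambda_grid=None,
    control_ids: list[str] | None = None,
) -> PlaceboResult:
    """Rank the treated effect among in-place placebo effects.

    The treated unit is fit against all controls; then each control unit in
    turn is pretended to be treated (same calendar) and fit against the
    remaining controls. Effects are factual minus counterfactual means over
    the post (heating) weeks, and::

        pseudo_p = (1 + #{placebos with |effect| >= |treated effect|}) / (n + 1)
    """
    est = RidgeAugmentedSCM(lambda_grid=lambda_grid)
    A, y1, B, ids, pre_idx, post_idx = est._coerce(Y0_pre, y1_pre, Y0_post)
    n = A.shape[0]
    if n < 5:
        raise ValueError(f"placebo scan needs >= 5 controls, got {n}")
    ids = ids or (control_ids or [f"unit{i}" for i in range(n)])
    y1_post = np.asarray(y1_post, float)

    est.fit(A, y1, B)
    post_index = post_idx if post_idx is not None else pd.RangeIndex(B.shape[1])
    cf_post = est.counterfactual_.to_numpy()[A.shape[1]:]
    treated_effect = pd.Series(y1_post - cf_post, index=post_index)
    treated_mean = float(treated_effect.mean())

    rows, means = [], []
    for i in range(n):
        keep = np.arange(n) != i
        sub = RidgeAugmentedSCM(lambda_grid=lambda_grid).fit(
            A[keep], A[i], B[keep]
        )
        cf_i = sub.counterfactual_.to_numpy()[A.shape[1]:]
        eff = B[i] - cf_i
        rows.append(eff)
        means.append(float(np.mean(eff)))
    placebo_effects = pd.DataFrame(rows, index=ids, columns=post_index)
    placebo_means = pd.Series(means, index=ids)
    exceed = int((np.abs(placebo_means.to_numpy()) >= abs(treated_mean)).sum())
    pseudo_p = (1 + exceed) / (n + 1)
    return PlaceboResult(
        treated_effect=treated_effect,
        treated_mean_effect=treated_mean,
        placebo_effects=placebo_effects,
        placebo_mean_effects=placebo_means,
        pseudo_p=pseudo_p,
    )
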