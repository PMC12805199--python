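"""Multi-group two-parameter logistic (2PL) model with impact.

The probability that a respondent with latent trait ``theta`` from group s
answers item j correctly is ``expit(a[j,s] * theta - b[j,s])``, where
``a`` is the slope and ``b`` the negative intercept.  The latent trait is
Normal(mu[s], sigma2[s]) per group ("impact"); group 1 is fixed at mean 0,
variance 1 for identification.  The marginal likelihood integrates the
trait out with Gauss-Hermite quadrature, and estimation proceeds by EM:
the E-step yields a posterior table over quadrature nodes per respondent,
the impact M-step is closed-form, and each item's 2S-dimensional block is
updated by L-BFGS on the posterior-weighted Bernoulli log-loss plus the
ADMM quadratic coupling term.

Missing responses are handled missing-at-random: every sum runs over
observed entries only, so sparse adaptive-test matrices are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

from .penalty import diff_matrix

__all__ = [
    "VARIANCE_FLOOR",
    "ModelParams",
    "QuadratureGrid",
    "irf",
    "build_quadrature",
    "log_marginal_likelihood",
    "estep_posteriors",
    "mstep_impact",
    "item_block_objective",
    "update_items",
]

#: lower bound on group latent variances; prevents collapse in tiny groups
VARIANCE_FLOOR = 1e-4


@dataclass
class ModelParams:
    """Item and impact parameters of the multi-group 2PL.

    ``a`` and ``b`` are (J, S): one slope / negative intercept per item and
    group.  ``mu`` and ``sigma2`` are the per-group latent means and
    variances; the first group is pinned at (0, 1).
    """

    a: np.ndarray
    b: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.validate()

    def validate(self):
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same shape")
        S = self.a.shape[1]
        if self.mu.shape != (S,) or self.sigma2.shape != (S,):
            raise ValueError("mu/sigma2 must have one entry per group")
        if self.mu[0] != 0.0 or self.sigma2[0] != 1.0:
            raise ValueError("group 1 must have mu=0, sigma2=1 (identification)")
        if (self.sigma2 < VARIANCE_FLOOR).any():
            raise ValueError(f"sigma2 below the variance floor {VARIANCE_FLOOR}")
        for arr in (self.a, self.b, self.mu, self.sigma2):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite parameter value")

    @property
    def n_items(self) -> int:
        return self.a.shape[0]

    @property
    def n_groups(self) -> int:
        return self.a.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(self.a.copy(), self.b.copy(),
                           self.mu.copy(), self.sigma2.copy())


@dataclass
class QuadratureGrid:
    """Per-group quadrature nodes and weights, shapes (S, K).

    Weights are positive and sum to one within each group; nodes are
    strictly increasing.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have the same shape")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        if np.abs(self.weights.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("weights must sum to 1 per group")
        if (np.diff(self.nodes, axis=1) <= 0).any():
            raise ValueError("nodes must be strictly increasing")

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)


def irf(theta, a, b):
    """Item response function: P(correct) = expit(a * theta - b)."""
    return expit(np.asarray(a) * theta - b)


def build_quadrature(mu, sigma2, K: int) -> QuadratureGrid:
    """Gauss-Hermite rule affinely mapped to Normal(mu[s], sigma2[s]).

    Uses the probabilists' rule: nodes ``mu + sqrt(sigma2) * x`` with
    weights normalized to sum to one per group.
    """
    if K < 2:
        raise ValueError("need at least 2 quadrature nodes")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    if (sigma2 <= 0).any():
        raise ValueError("sigma2 must be positive")
    x, w = np.polynomial.hermite_e.hermegauss(K)
    w = w / w.sum()
    nodes = mu[:, None] + np.sqrt(sigma2)[:, None] * x[None, :]
    weights = np.tile(w, (len(mu), 1))
    return QuadratureGrid(nodes, weights)


def _loglik_by_node(data, params: ModelParams, grid: QuadratureGrid) -> np.ndarray:
    """(N, K) matrix of log p(observed responses of i | theta at node k)."""
    cache = data._cache()
    N = data.n_respondents
    K = grid.nodes.shape[1]
    L = np.empty((N, K))
    for s, rows in enumerate(cache["rows"]):
        if rows.size == 0:
            continue
        # z[k, j] = a[j, s] * node[s, k] - b[j, s]
        z = grid.nodes[s][:, None] * params.a[:, s][None, :] - params.b[:, s][None, :]
        logp = log_expit(z)
        log1mp = log_expit(-z)
        L[rows] = cache["y1"][rows] @ logp.T + cache["y0"][rows] @ log1mp.T
    return L


def _joint_log_by_node(data, params, grid):
    L = _loglik_by_node(data, params, grid)
    return L + grid.log_weights[data.groups]


def log_marginal_likelihood(data, params: ModelParams, grid: QuadratureGrid) -> float:
    """Quadrature approximation of the log marginal likelihood.

    Products run over observed items only; a respondent with no observed
    responses would contribute exactly zero (such rows are excluded by the
    :class:`~pairdif.data.ResponseData` invariants anyway).
    """
    val = float(logsumexp(_joint_log_by_node(data, params, grid), axis=1).sum())
    if not np.isfinite(val):
        raise FloatingPointError("non-finite marginal likelihood (degenerate grid?)")
    return val


def estep_posteriors(data, params: ModelParams, grid: QuadratureGrid) -> np.ndarray:
    """Posterior probability of each quadrature node per respondent.

    Row i is proportional to prior weight times the conditional likelihood
    of respondent i's observed responses; rows sum to one.  Accumulation is
    in log space with per-row max subtraction.
    """
    post, _ = _posterior_and_loglik(data, params, grid)
    return post


def _posterior_and_loglik(data, params, grid):
    joint = _joint_log_by_node(data, params, grid)
    norm = logsumexp(joint, axis=1, keepdims=True)
    post = np.exp(joint - norm)
    return post, float(norm.sum())


def mstep_impact(post: np.ndarray, grid: QuadratureGrid, data) -> tuple:
    """Closed-form impact update from the E-step posterior table.

    For each group s >= 2, the new mean is the average posterior mean of
    theta over the group's respondents and the new variance the average
    posterior second central moment about that mean.  Group 1 stays at
    (0, 1); variances are clamped at the floor.
    """
    cache = data._cache()
    S = data.n_groups
    mu = np.zeros(S)
    sigma2 = np.ones(S)
    for s in range(1, S):
        rows = cache["rows"][s]
        pm = post[rows] @ grid.nodes[s]
        mu[s] = pm.mean()
        second = post[rows] @ (grid.nodes[s] - mu[s]) ** 2
        sigma2[s] = max(second.mean(), VARIANCE_FLOOR)
    return mu, sigma2


def _posterior_counts(post, data, K):
    """Pseudo-counts r1/r0 with shape (S, K, J): posterior-weighted numbers
    of correct / incorrect responses at each node, per group and item."""
    cache = data._cache()
    S, J = data.n_groups, data.n_items
    r1 = np.zeros((S, K, J))
    r0 = np.zeros((S, K, J))
    for s, rows in enumerate(cache["rows"]):
        if rows.size == 0:
            continue
        r1[s] = post[rows].T @ cache["y1"][rows]
        r0[s] = post[rows].T @ cache["y0"][rows]
    return r1, r0


def item_block_objective(x, r1_j, r0_j, nodes, delta_a_j, delta_b_j,
                         u_a_j, u_b_j, rho, D):
    """Penalized expected complete-data loss for one item block.

    ``x`` concatenates the item's slopes and negative intercepts across the
    S groups.  The value is the posterior-weighted Bernoulli log-loss over
    nodes (pseudo-counts ``r1_j``/``r0_j`` of shape (S, K)) plus the ADMM
    quadratic ``(rho/2) ||D a - delta + u||^2`` for both kinds; the exact
    gradient with respect to all 2S entries is returned alongside.
    """
    S = nodes.shape[0]
    a = x[:S]
    b = x[S:]
    z = nodes * a[:, None] - b[:, None]  # (S, K)
    val = -(r1_j * log_expit(z) + r0_j * log_expit(-z)).sum()
    resid = r1_j - (r1_j + r0_j) * expit(z)
    ga = -(resid * nodes).sum(axis=1)
    gb = resid.sum(axis=1)
    ra = D @ a - delta_a_j + u_a_j
    rb = D @ b - delta_b_j + u_b_j
    val += 0.5 * rho * (ra @ ra + rb @ rb)
    ga += rho * (D.T @ ra)
    gb += rho * (D.T @ rb)
    return val, np.concatenate([ga, gb])


def update_items(params: ModelParams, post: np.ndarray, grid: QuadratureGrid,
                 pairs, rho: float, data, lbfgs_iters: int = 20) -> ModelParams:
    """One inexact M-step over all item blocks.

    Each item's 2S parameters are refined by a warm-started L-BFGS-B run on
    :func:`item_block_objective`.  A block is only accepted if its objective
    did not increase; on a line-search failure the previous values are kept
    and a warning is issued.
    """
    S, J = data.n_groups, data.n_items
    K = grid.nodes.shape[1]
    r1, r0 = _posterior_counts(post, data, K)
    D = diff_matrix(S) if S > 1 else np.zeros((0, S))
    if S > 1:
        da, db, ua, ub = pairs.delta_a, pairs.delta_b, pairs.u_a, pairs.u_b
    else:
        z = np.zeros((J, 0))
        da = db = ua = ub = z
    new = params.copy()
    for j in range(J):
        x0 = np.concatenate([params.a[j], params.b[j]])
        args = (r1[:, :, j], r0[:, :, j], grid.nodes,
                da[j], db[j], ua[j], ub[j], rho, D)
        f0, _ = item_block_objective(x0, *args)
        res = minimize(item_block_objective, x0, args=args, jac=True,
                       method="L-BFGS-B", options={"maxiter": lbfgs_iters})
        if np.isfinite(res.fun) and res.fun <= f0:
            new.a[j] = res.x[:S]
            new.b[j] = res.x[S:]
        else:
            warnings.warn(f"item {j + 1}: M-step line search failed; keeping "
                          "previous block values", RuntimeWarning)
    return new
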