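"""DC / ADMM solver for the group-pairwise TLP-penalized 2PL fit.

The nonconvex TLP objective is attacked with an outer
difference-of-convex (DC) loop that freezes binary majorization weights
from the current difference parameters, and an inner ADMM loop that
alternates (i) one EM cycle for the model parameters (E-step, closed-form
impact update, per-item L-BFGS block updates on the augmented objective),
(ii) the closed-form soft-threshold update of the difference parameters
and (iii) the scaled-dual update.  The algorithm is warm-started from a
pure-LP run (tau = inf), whose convex penalty makes it easy to solve from
a neutral start.

Convergence requires the absolute change of every model and difference
parameter (duals excluded) to fall below ``tol``, with stable outer
weights; constraint feasibility ``max |difference - delta|`` is reported
separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logit

from .penalty import (PairState, TuningConfig, dc_weights, delta_update,
                      diff_matrix, dual_update, penalty_total)
from .twopl import (ModelParams, build_quadrature, mstep_impact,
                    _posterior_and_loglik, update_items)

__all__ = ["SolverOptions", "FitResult", "initialize", "fit_single",
           "check_convergence", "default_rho"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverOptions:
    """Iteration controls for the DC/ADMM solver.

    ``tol`` is the convergence tolerance on the maximum absolute parameter
    change, ``max_outer`` the DC iteration cap, ``max_inner`` the ADMM cap
    per DC iteration, ``lbfgs_iters`` the per-item M-step cap and ``K`` the
    number of quadrature nodes.
    """

    tol: float = 1e-4
    max_outer: int = 20
    max_inner: int = 500
    lbfgs_iters: int = 20
    K: int = 21
    seed: int = 0
    verbose: int = 0

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if min(self.max_outer, self.max_inner, self.lbfgs_iters, self.K) < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class FitResult:
    """Outcome of a single (lam, tau) fit."""

    params: ModelParams
    pairs: PairState
    loglik: float
    objective_trace: list
    converged: bool
    n_outer: int
    n_inner: int
    feasibility_gap: float
    tuning: TuningConfig
    message: str = ""


def default_rho(N: int) -> float:
    """Default ADMM penalty parameter: N / 10 on the total-likelihood scale."""
    return N / 10.0


def _neutral_start(data) -> tuple:
    """Neutral starting point: a=1, b from pooled proportions, no impact."""
    J, S = data.n_items, data.n_groups
    mask = data.mask
    y = np.nan_to_num(data.responses, nan=0.0)
    p = (y * mask).sum(axis=0) / mask.sum(axis=0)
    p = np.clip(p, 0.01, 0.99)
    b0 = -logit(p)
    params = ModelParams(np.ones((J, S)), np.tile(b0[:, None], (1, S)),
                         np.zeros(S), np.ones(S))
    return params, PairState.zeros(J, S)


def initialize(data, tuning: TuningConfig, opts: SolverOptions) -> tuple:
    """LP warm start: run the solver once with tau = inf from a neutral start.

    When the requested tau is already infinite the neutral start is
    returned directly (no double LP run).
    """
    params, pairs = _neutral_start(data)
    if math.isinf(tuning.tau):
        return params, pairs
    lp = _fit_from(params, pairs, data, replace(tuning, tau=math.inf), opts)
    if not lp.converged:
        logger.warning("LP initialization did not converge; using last iterate")
    lp.pairs.w_a[:] = 1.0
    lp.pairs.w_b[:] = 1.0
    return lp.params, lp.pairs


def _snapshot(params, pairs):
    return (params.a.copy(), params.b.copy(), params.mu.copy(),
            params.sigma2.copy(), pairs.delta_a.copy(), pairs.delta_b.copy())


def check_convergence(old, new, tol: float) -> bool:
    """True iff every entry of {a, b, mu, sigma2, delta} moved < tol.

    ``old`` and ``new`` are (params, pairs) tuples; scaled duals are
    auxiliary and deliberately excluded.
    """
    so = old if isinstance(old, tuple) and len(old) == 6 else _snapshot(*old)
    sn = new if isinstance(new, tuple) and len(new) == 6 else _snapshot(*new)
    return all(np.abs(a - b).max() < tol if a.size else True
               for a, b in zip(so, sn))


def _fit_from(params, pairs, data, tuning: TuningConfig, opts: SolverOptions) -> FitResult:
    lam, tau, rho = tuning.lam, tuning.tau, tuning.rho
    # with no penalty there is nothing to split: the quadratic coupling is
    # dropped and the loop reduces to plain EM (the free-per-group model is
    # impact-unidentified, so a proximal term would alter the limit point)
    rho_item = 0.0 if lam == 0 else rho
    S = data.n_groups
    D = diff_matrix(S)
    params = params.copy()
    pairs = pairs.copy()
    trace = []
    n_inner_total = 0
    converged = False
    n_outer = 0
    for outer in range(opts.max_outer):
        n_outer = outer + 1
        pairs = dc_weights(pairs, tau)
        w_a, w_b = pairs.w_a.copy(), pairs.w_b.copy()
        inner_done = False
        for _ in range(opts.max_inner):
            old = _snapshot(params, pairs)
            grid = build_quadrature(params.mu, params.sigma2, opts.K)
            post, ll = _posterior_and_loglik(data, params, grid)
            trace.append(-ll + penalty_total(params, lam, tau))
            if not np.isfinite(trace[-1]):
                raise FloatingPointError(
                    f"divergent objective at DC iteration {n_outer}, "
                    f"ADMM iteration {n_inner_total}: objective={trace[-1]}, "
                    f"mu={params.mu}, sigma2={params.sigma2}")
            params.mu, params.sigma2 = mstep_impact(post, grid, data)
            params = update_items(params, post, grid, pairs, rho_item, data,
                                  opts.lbfgs_iters)
            diff_a = params.a @ D.T
            diff_b = params.b @ D.T
            pairs.delta_a = delta_update(diff_a, pairs.u_a, w_a, lam, rho)
            pairs.delta_b = delta_update(diff_b, pairs.u_b, w_b, lam, rho)
            pairs.u_a = dual_update(pairs.u_a, diff_a, pairs.delta_a)
            pairs.u_b = dual_update(pairs.u_b, diff_b, pairs.delta_b)
            n_inner_total += 1
            if opts.verbose:
                gap = max(np.abs(diff_a - pairs.delta_a).max(),
                          np.abs(diff_b - pairs.delta_b).max())
                logger.info("outer %d inner %d objective %.6f gap %.2e",
                            n_outer, n_inner_total, trace[-1], gap)
            if check_convergence(old, _snapshot(params, pairs), opts.tol):
                inner_done = True
                break
        refreshed = dc_weights(pairs, tau)
        stable = (np.array_equal(refreshed.w_a, w_a)
                  and np.array_equal(refreshed.w_b, w_b))
        if inner_done and stable:
            converged = True
            break
    grid = build_quadrature(params.mu, params.sigma2, opts.K)
    _, loglik = _posterior_and_loglik(data, params, grid)
    trace.append(-loglik + penalty_total(params, lam, tau))
    diff_a = params.a @ D.T
    diff_b = params.b @ D.T
    gap = float(max(np.abs(diff_a - pairs.delta_a).max(initial=0.0),
                    np.abs(diff_b - pairs.delta_b).max(initial=0.0)))
    return FitResult(params=params, pairs=pairs, loglik=float(loglik),
                     objective_trace=trace, converged=converged,
                     n_outer=n_outer, n_inner=n_inner_total,
                     feasibility_gap=gap, tuning=tuning,
                     message="" if converged else "iteration cap reached")


def fit_single(data, tuning: TuningConfig, opts: SolverOptions | None = None,
               warm_start: tuple | None = None) -> FitResult:
    """Fit the penalized multi-group 2PL at one (lam, tau, rho).

    Without an explicit ``warm_start`` the solver first runs the pure-LP
    (tau = inf) problem from a neutral start and continues from its
    solution.  ``warm_start`` is a (ModelParams, PairState) tuple.
    """
    if data.n_groups < 2:
        raise ValueError("need at least 2 groups to fit pairwise DIF")
    opts = opts or SolverOptions()
    if warm_start is None:
        warm_start = initialize(data, tuning, opts)
    params, pairs = warm_start
    return _fit_from(params, pairs, data, tuning, opts)
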