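"""Independent reference implementations used only by the tests.

Everything here is written from first principles (direct numpy/scipy, no
calls into the package's likelihood or solver code) so that it can serve
as an oracle: a plain marginal-likelihood EM for the multi-group 2PL
(free item parameters per group, no penalty, no ADMM), a
shared-item-parameter constrained EM, a brute-force dense-grid marginal
likelihood, a 1-D grid minimizer for the soft-threshold update and a
Floyd-Warshall transitive closure.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

VAR_FLOOR = 1e-4


def _gh(mu, sigma2, K):
    x, w = np.polynomial.hermite_e.hermegauss(K)
    return mu + np.sqrt(sigma2) * x, w / w.sum()


def _node_loglik(y, mask, a_s, b_s, nodes):
    """(n, K) log-likelihood of each row at each node; a_s, b_s are (J,)."""
    z = nodes[:, None] * a_s[None, :] - b_s[None, :]  # (K, J)
    with np.errstate(over="ignore"):
        logp = -np.log1p(np.exp(-z))
        log1mp = -np.log1p(np.exp(z))
    y0 = np.where(mask, 1.0 - y, 0.0)
    y1 = np.where(mask, y, 0.0)
    return y1 @ logp.T + y0 @ log1mp.T


def dense_grid_loglik(y, mask, groups, a, b, mu, sigma2,
                      lo=-8.0, hi=8.0, n_points=20001):
    """Trapezoid-rule marginal log-likelihood on a dense theta grid."""
    theta = np.linspace(lo, hi, n_points)
    dt = theta[1] - theta[0]
    total = 0.0
    for s in range(len(mu)):
        rows = np.flatnonzero(groups == s)
        if rows.size == 0:
            continue
        dens = np.exp(-0.5 * (theta - mu[s]) ** 2 / sigma2[s]) / np.sqrt(
            2 * np.pi * sigma2[s])
        ll = _node_loglik(y[rows], mask[rows], a[:, s], b[:, s], theta)
        trap = np.full(n_points, dt)
        trap[[0, -1]] = dt / 2
        total += logsumexp(ll + np.log(dens * trap), axis=1).sum()
    return float(total)


def plain_em_2pl(y, mask, groups, S, K=21, tol=1e-4, max_iter=2000,
                 lbfgs_iters=20):
    """Unpenalized multi-group 2PL MML fit, free parameters per group.

    One EM cycle = E-step over all groups at the current parameters, then
    the closed-form impact update, then one L-BFGS pass per item; stops
    when the largest absolute parameter change falls below ``tol``.  The
    free-per-group model leaves the non-reference impact parameters
    unidentified (only a*sigma and a*mu - b enter the likelihood), so the
    converged point depends on the update order; this oracle uses the
    same deterministic order the checked algorithm defines.  Returns
    (a, b, mu, sigma2, loglik) with group 1 pinned at N(0, 1).
    """
    n, J = y.shape
    y1 = np.where(mask, y, 0.0)
    y0 = np.where(mask, 1.0 - y, 0.0)
    p = y1.sum(axis=0) / mask.sum(axis=0)
    p = np.clip(p, 0.01, 0.99)
    a = np.ones((J, S))
    b = np.tile(np.log((1 - p) / p)[:, None], (1, S))
    mu = np.zeros(S)
    sigma2 = np.ones(S)
    for _ in range(max_iter):
        old = (a.copy(), b.copy(), mu.copy(), sigma2.copy())
        # E-step at current parameters, all groups
        post_s, nodes_s, rows_s = [], [], []
        for s in range(S):
            rows = np.flatnonzero(groups == s)
            nodes, w = _gh(mu[s], sigma2[s], K)
            joint = _node_loglik(y[rows], mask[rows], a[:, s], b[:, s],
                                 nodes) + np.log(w)
            post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
            post_s.append(post)
            nodes_s.append(nodes)
            rows_s.append(rows)
        # closed-form impact update (group 1 fixed)
        for s in range(1, S):
            pm = post_s[s] @ nodes_s[s]
            mu[s] = pm.mean()
            sigma2[s] = max((post_s[s] @ (nodes_s[s] - mu[s]) ** 2).mean(),
                            VAR_FLOOR)
        # per-item L-BFGS on the expected Bernoulli loss
        for s in range(S):
            r1 = post_s[s].T @ y1[rows_s[s]]  # (K, J)
            r0 = post_s[s].T @ y0[rows_s[s]]
            nodes = nodes_s[s]
            for j in range(J):
                def nll(x, r1j=r1[:, j], r0j=r0[:, j]):
                    z = x[0] * nodes - x[1]
                    val = -(r1j * (-np.log1p(np.exp(-z)))
                            + r0j * (-np.log1p(np.exp(z)))).sum()
                    resid = r1j - (r1j + r0j) * expit(z)
                    return val, np.array([-(resid * nodes).sum(), resid.sum()])
                res = minimize(nll, np.array([a[j, s], b[j, s]]), jac=True,
                               method="L-BFGS-B",
                               options={"maxiter": lbfgs_iters})
                a[j, s], b[j, s] = res.x
        moved = max(np.abs(a - old[0]).max(), np.abs(b - old[1]).max(),
                    np.abs(mu - old[2]).max(), np.abs(sigma2 - old[3]).max())
        if moved < tol:
            break
    ll = 0.0
    for s in range(S):
        rows = np.flatnonzero(groups == s)
        nodes, w = _gh(mu[s], sigma2[s], K)
        joint = _node_loglik(y[rows], mask[rows], a[:, s], b[:, s],
                             nodes) + np.log(w)
        ll += logsumexp(joint, axis=1).sum()
    return a, b, mu, sigma2, float(ll)


def constrained_em_2pl(y, mask, groups, S, K=21, tol=1e-6, max_iter=2000):
    """Shared-item-parameter 2PL with group-specific impact.

    One (a_j, b_j) per item across all groups; group 1 pinned at N(0, 1).
    Returns (a, b, mu, sigma2, loglik) with a, b of shape (J,).
    """
    n, J = y.shape
    y1 = np.where(mask, y, 0.0)
    y0 = np.where(mask, 1.0 - y, 0.0)
    p = np.clip(y1.sum(axis=0) / mask.sum(axis=0), 0.01, 0.99)
    a = np.ones(J)
    b = np.log((1 - p) / p)
    mu = np.zeros(S)
    sigma2 = np.ones(S)
    prev_ll = -np.inf
    for _ in range(max_iter):
        nodes_s, w_s, post_s, rows_s = [], [], [], []
        ll_total = 0.0
        new_mu, new_sigma2 = mu.copy(), sigma2.copy()
        for s in range(S):
            rows = np.flatnonzero(groups == s)
            nodes, w = _gh(mu[s], sigma2[s], K)
            joint = _node_loglik(y[rows], mask[rows], a, b, nodes) + np.log(w)
            norm = logsumexp(joint, axis=1, keepdims=True)
            ll_total += norm.sum()
            post = np.exp(joint - norm)
            if s > 0:
                pm = post @ nodes
                new_mu[s] = pm.mean()
                new_sigma2[s] = max((post @ (nodes - new_mu[s]) ** 2).mean(),
                                    VAR_FLOOR)
            nodes_s.append(nodes)
            post_s.append(post)
            rows_s.append(rows)
        r1 = np.stack([post_s[s].T @ y1[rows_s[s]] for s in range(S)])  # (S,K,J)
        r0 = np.stack([post_s[s].T @ y0[rows_s[s]] for s in range(S)])
        nodes_arr = np.stack(nodes_s)  # (S, K)
        for j in range(J):
            def nll(x, r1j=r1[:, :, j], r0j=r0[:, :, j]):
                z = x[0] * nodes_arr - x[1]
                val = -(r1j * (-np.log1p(np.exp(-z)))
                        + r0j * (-np.log1p(np.exp(z)))).sum()
                resid = r1j - (r1j + r0j) * expit(z)
                return val, np.array([-(resid * nodes_arr).sum(), resid.sum()])
            res = minimize(nll, np.array([a[j], b[j]]), jac=True,
                           method="L-BFGS-B")
            a[j], b[j] = res.x
        mu, sigma2 = new_mu, new_sigma2
        if abs(ll_total - prev_ll) < tol:
            break
        prev_ll = ll_total
    ll = 0.0
    for s in range(S):
        rows = np.flatnonzero(groups == s)
        nodes, w = _gh(mu[s], sigma2[s], K)
        ll += logsumexp(_node_loglik(y[rows], mask[rows], a, b, nodes)
                        + np.log(w), axis=1).sum()
    return a, b, mu, sigma2, float(ll)


def grid_argmin_soft(z, lam, rho, w, lo=-2.0, hi=2.0, step=1e-4):
    """Brute-force argmin of (rho/2)(z - d)^2 + w*lam*|d| over a 1-D grid."""
    d = np.arange(lo, hi + step / 2, step)
    obj = 0.5 * rho * (z - d) ** 2 + w * lam * np.abs(d)
    return float(d[np.argmin(obj)])


def transitive_closure_reps(zero_pairs, S):
    """Connected-component representative per group via Floyd-Warshall.

    Returns an array mapping each 1-based group to a canonical component
    id (the smallest member), comparable up to relabeling.
    """
    reach = np.eye(S, dtype=bool)
    for m, n in zero_pairs:
        reach[m - 1, n - 1] = reach[n - 1, m - 1] = True
    for k in range(S):
        reach |= reach[:, k][:, None] & reach[k, :][None, :]
    return np.array([int(np.flatnonzero(reach[i])[0]) + 1 for i in range(S)])
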