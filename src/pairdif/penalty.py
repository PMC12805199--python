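"""Group-pairwise truncated-L1 penalty algebra and the ADMM update rules.

For every item j and every ordered pair of groups m < n, the differences
``a[j,m] - a[j,n]`` and ``b[j,m] - b[j,n]`` are penalized by the truncated
L1 penalty (TLP) ``lam * min(|d|, tau)``.  Near zero the TLP behaves like
the lasso and shrinks small differences to exactly zero; beyond the
truncation point ``tau`` it is flat, so large (real) DIF effects are not
biased toward zero.  As ``tau`` grows the TLP degenerates to the plain L1
penalty (LP).

The nonconvex TLP is handled by difference-of-convex (DC) majorization:
at each outer iteration the penalty on a pair is replaced by a weighted L1
term with binary weight ``w = 1{|delta| <= tau}``.  The resulting convex
surrogate is solved by ADMM with scaled duals, whose difference-parameter
update is a soft-thresholding step.  Differences are always oriented
``param(m) - param(n)`` for ``m < n``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TuningConfig",
    "PairState",
    "pair_index",
    "diff_matrix",
    "tlp_value",
    "penalty_total",
    "dc_weights",
    "soft_threshold",
    "delta_update",
    "dual_update",
]


@dataclass(frozen=True)
class TuningConfig:
    """Tuning parameters: penalty strength ``lam`` (on the total
    log-likelihood scale), truncation threshold ``tau`` (``inf`` = LP)
    and ADMM penalty parameter ``rho``."""

    lam: float
    tau: float
    rho: float

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0 (inf allowed)")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")


def pair_index(S: int) -> list:
    """Lexicographically ordered 1-based group pairs (m, n), m < n."""
    if S < 2:
        raise ValueError("need at least 2 groups")
    return [(m, n) for m in range(1, S + 1) for n in range(m + 1, S + 1)]


def diff_matrix(S: int) -> np.ndarray:
    """P x S matrix D with D @ v = (v_m - v_n) over all pairs m < n."""
    pairs = pair_index(S)
    D = np.zeros((len(pairs), S))
    for p, (m, n) in enumerate(pairs):
        D[p, m - 1] = 1.0
        D[p, n - 1] = -1.0
    return D


@dataclass
class PairState:
    """Per (item, parameter kind, pair) ADMM state.

    Arrays have shape (J, P) with P = S(S-1)/2, ordered as
    :func:`pair_index`.  ``delta_*`` are the difference parameters,
    ``u_*`` the scaled duals and ``w_*`` the binary DC weights.
    """

    pairs: list
    delta_a: np.ndarray
    delta_b: np.ndarray
    u_a: np.ndarray
    u_b: np.ndarray
    w_a: np.ndarray
    w_b: np.ndarray

    @classmethod
    def zeros(cls, J: int, S: int) -> "PairState":
        pairs = pair_index(S)
        P = len(pairs)
        z = lambda: np.zeros((J, P))
        return cls(pairs, z(), z(), z(), z(), np.ones((J, P)), np.ones((J, P)))

    def copy(self) -> "PairState":
        return PairState(list(self.pairs), *(x.copy() for x in
                         (self.delta_a, self.delta_b, self.u_a, self.u_b,
                          self.w_a, self.w_b)))


def tlp_value(d, lam: float, tau: float):
    """Truncated L1 penalty ``lam * min(|d|, tau)`` (elementwise)."""
    return lam * np.minimum(np.abs(d), tau)


def penalty_total(params, lam: float, tau: float) -> float:
    """Total group-pairwise TLP over all items, pairs and both kinds.

    A single common (lam, tau) applies to the slope and intercept kinds.
    """
    S = params.a.shape[1]
    D = diff_matrix(S)
    da = params.a @ D.T
    db = params.b @ D.T
    return float(tlp_value(da, lam, tau).sum() + tlp_value(db, lam, tau).sum())


def dc_weights(pairs: PairState, tau: float) -> PairState:
    """Refresh the DC majorization weights from the current deltas.

    ``w = 1`` iff ``|delta| <= tau`` (boundary penalized, so the tau = inf
    LP limit is exact); returns a new PairState, deltas and duals untouched.
    """
    new = pairs.copy()
    new.w_a = (np.abs(pairs.delta_a) <= tau).astype(float)
    new.w_b = (np.abs(pairs.delta_b) <= tau).astype(float)
    return new


def soft_threshold(z, t):
    """``sign(z) * max(|z| - t, 0)`` (elementwise)."""
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def delta_update(diff, dual_u, w, lam: float, rho: float):
    """Closed-form difference-parameter update.

    Minimizes ``(rho/2) (diff + u - delta)^2 + w lam |delta|``: a
    soft-threshold at ``w lam / rho``.  Pairs with ``w = 0`` (already
    beyond the truncation point) pass through unshrunk.
    """
    return soft_threshold(np.asarray(diff) + dual_u, np.asarray(w) * (lam / rho))


def dual_update(dual_u, diff, delta):
    """Scaled-dual ascent: ``u + (diff - delta)``."""
    return (dual_u + diff) - delta
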