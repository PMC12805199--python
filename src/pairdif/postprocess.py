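"""Post-processing of a converged fit: cluster collapsing, DIF flags, BIC.

When the solver converges, a pair of groups shows no DIF on an item if and
only if both of the item's difference parameters (slope and intercept
kinds) are zero.  Soft-thresholding yields exact zeros, but the solver
never checks transitivity: delta(1,2) = delta(2,3) = 0 can coexist with a
tiny nonzero delta(1,3).  Groups connected by zero differences are
therefore collapsed with a union-find structure (with path compression)
and every within-cluster delta is reset to exactly zero before flagging.

Model selection fits a (lam, tau) grid and keeps the candidate with the
lowest BIC, where the parameter count is the number of distinct slope and
intercept parameters after collapsing plus the 2(S-1) free impact terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .penalty import PairState, TuningConfig
from .solver import (FitResult, SolverOptions, _neutral_start, default_rho,
                     fit_single)
from .twopl import ModelParams, build_quadrature, log_marginal_likelihood

__all__ = [
    "ZERO_TOL",
    "UnionFind",
    "DifReport",
    "collapse_clusters",
    "build_clusters",
    "enforce_transitivity",
    "dif_flag_matrix",
    "distinct_param_counts",
    "bic_score",
    "merged_params",
    "postprocess_fit",
    "select_model",
]

#: |delta| below this is treated as an exact zero when building clusters
ZERO_TOL = 1e-6


class UnionFind:
    """Disjoint-set forest over 1-based elements with path compression.

    ``union(m, n)`` attaches the root of m's tree under the root of n's,
    so the representative of a merged cluster is the root reached through
    n.  ``find`` re-points every node on the walked path directly at the
    root.
    """

    def __init__(self, n: int):
        self.parent = list(range(n + 1))  # index 0 unused

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, m: int, n: int) -> None:
        rm, rn = self.find(m), self.find(n)
        if rm != rn:
            self.parent[rm] = rn

    def representatives(self) -> np.ndarray:
        """1-based representative of each element 1..n."""
        return np.array([self.find(x) for x in range(1, len(self.parent))])


def collapse_clusters(zero_pairs, S: int) -> UnionFind:
    """Merge groups connected by zero difference parameters.

    ``zero_pairs`` is an iterable of 1-based pairs (m, n); the transitive
    closure is implied by the union-find structure.
    """
    uf = UnionFind(S)
    for m, n in zero_pairs:
        if not (1 <= m < n <= S):
            raise ValueError(f"invalid pair ({m}, {n}) for S={S}")
        uf.union(m, n)
    return uf


def build_clusters(pairs: PairState, S: int, zero_tol: float = ZERO_TOL):
    """Per-item, per-kind representatives (J, S) from near-zero deltas."""
    J = pairs.delta_a.shape[0]
    reps_a = np.empty((J, S), dtype=int)
    reps_b = np.empty((J, S), dtype=int)
    for j in range(J):
        for delta, reps in ((pairs.delta_a[j], reps_a), (pairs.delta_b[j], reps_b)):
            zp = [pairs.pairs[p] for p in np.flatnonzero(np.abs(delta) < zero_tol)]
            reps[j] = collapse_clusters(zp, S).representatives()
    return reps_a, reps_b


def enforce_transitivity(pairs: PairState, reps_a: np.ndarray,
                         reps_b: np.ndarray) -> PairState:
    """Reset every within-cluster delta to exactly zero.

    Guarantees that "zero delta" is an equivalence relation on groups for
    every (item, kind); all other deltas are untouched.  Idempotent.
    """
    new = pairs.copy()
    idx_m = np.array([m - 1 for m, _ in pairs.pairs])
    idx_n = np.array([n - 1 for _, n in pairs.pairs])
    same_a = reps_a[:, idx_m] == reps_a[:, idx_n]
    same_b = reps_b[:, idx_m] == reps_b[:, idx_n]
    new.delta_a[same_a] = 0.0
    new.delta_b[same_b] = 0.0
    return new


@dataclass
class DifReport:
    """Pairwise DIF flags, group clusters and distinct-parameter counts.

    ``flags_*`` have shape (J, P) over the pairs of ``pairs``; ``reps_*``
    give each group's 1-based cluster representative per item.
    """

    pairs: list
    flags_a: np.ndarray
    flags_b: np.ndarray
    flags_any: np.ndarray
    reps_a: np.ndarray
    reps_b: np.ndarray
    p_a: int
    p_b: int

    def flag(self, item: int, g1: int, g2: int, kind: str = "any") -> bool:
        """Flag for 1-based item and (unordered) 1-based group pair."""
        m, n = min(g1, g2), max(g1, g2)
        p = self.pairs.index((m, n))
        arr = {"a": self.flags_a, "b": self.flags_b, "any": self.flags_any}[kind]
        return bool(arr[item - 1, p])


def dif_flag_matrix(pairs: PairState) -> tuple:
    """Per-pair flags: DIF present iff the (transitivity-repaired) delta
    is nonzero; the any-kind flag is the OR over kinds."""
    fa = pairs.delta_a != 0.0
    fb = pairs.delta_b != 0.0
    return fa, fb, fa | fb


def distinct_param_counts(reps_a: np.ndarray, reps_b: np.ndarray) -> tuple:
    """Numbers of distinct slope / intercept parameters across items."""
    p_a = sum(len(np.unique(row)) for row in reps_a)
    p_b = sum(len(np.unique(row)) for row in reps_b)
    return int(p_a), int(p_b)


def bic_score(loglik: float, p_a: int, p_b: int, N: int, S: int) -> float:
    """BIC = -2 loglik + log(N) (p_a + p_b + 2(S-1)).

    The impact terms are constant across candidate models but are included
    so reported values are self-consistent.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return -2.0 * loglik + math.log(N) * (p_a + p_b + 2 * (S - 1))


def merged_params(params: ModelParams, reps_a: np.ndarray, reps_b: np.ndarray,
                  group_sizes: np.ndarray) -> ModelParams:
    """Replace each cluster's parameters by the group-size-weighted mean.

    The ADMM updates drive within-cluster differences to zero but not to
    exact equality, so the counted model and the scored likelihood are
    reconciled by averaging within clusters.
    """
    out = params.copy()
    w = np.asarray(group_sizes, dtype=float)
    for mat, reps in ((out.a, reps_a), (out.b, reps_b)):
        for j in range(mat.shape[0]):
            for r in np.unique(reps[j]):
                members = reps[j] == r
                mat[j, members] = np.average(mat[j, members], weights=w[members])
    return out


def postprocess_fit(fit: FitResult, data, K: int = 21):
    """Clusters, transitivity repair, flags, merged parameters and BIC.

    Returns ``(report, merged, bic, merged_loglik)`` where ``merged`` holds
    the cluster-averaged parameters at which the BIC's likelihood is
    evaluated.
    """
    S = data.n_groups
    reps_a, reps_b = build_clusters(fit.pairs, S)
    fit.pairs = enforce_transitivity(fit.pairs, reps_a, reps_b)
    fa, fb, fany = dif_flag_matrix(fit.pairs)
    p_a, p_b = distinct_param_counts(reps_a, reps_b)
    report = DifReport(list(fit.pairs.pairs), fa, fb, fany,
                       reps_a, reps_b, p_a, p_b)
    merged = merged_params(fit.params, reps_a, reps_b, data.group_sizes)
    grid = build_quadrature(merged.mu, merged.sigma2, K)
    ll = log_marginal_likelihood(data, merged, grid)
    bic = bic_score(ll, p_a, p_b, data.n_respondents, S)
    return report, merged, bic, ll


def select_model(data, lam_grid, tau_grid, opts: SolverOptions | None = None,
                 rho: float | None = None):
    """Grid search over (lam, tau) with BIC selection.

    ``lam_grid`` is on the per-respondent scale (internally multiplied by
    N); ``tau_grid`` entries may include ``inf`` for the pure LP.  All
    candidates are warm-started from a single LP initialization run at the
    median lam of the grid.  Ties in BIC break toward larger lam, then
    larger tau.  Returns ``(best, table)`` where ``best`` is a dict with
    the winning fit, report, merged parameters and score, and ``table``
    collects one row per candidate.
    """
    lam_grid = sorted(set(float(x) for x in lam_grid))
    tau_grid = sorted(set(float(x) for x in tau_grid))
    if not lam_grid or not tau_grid:
        raise ValueError("tuning grids must be non-empty")
    opts = opts or SolverOptions()
    N = data.n_respondents
    rho = default_rho(N) if rho is None else float(rho)
    lam_mid = lam_grid[len(lam_grid) // 2] * N
    lp = fit_single(data, TuningConfig(lam_mid, math.inf, rho), opts,
                    warm_start=_neutral_start(data))
    warm = (lp.params, lp.pairs)
    rows = []
    candidates = []
    errors = []
    for lam_user in lam_grid:
        for tau in tau_grid:
            tuning = TuningConfig(lam_user * N, tau, rho)
            try:
                fit = fit_single(data, tuning, opts, warm_start=warm)
                report, merged, bic, ll = postprocess_fit(fit, data, opts.K)
            except (FloatingPointError, ValueError) as exc:  # pragma: no cover
                errors.append((lam_user, tau, str(exc)))
                rows.append({"lam": lam_user, "tau": tau, "loglik": np.nan,
                             "p_a": -1, "p_b": -1, "bic": np.nan,
                             "converged": False})
                continue
            rows.append({"lam": lam_user, "tau": tau, "loglik": ll,
                         "p_a": report.p_a, "p_b": report.p_b, "bic": bic,
                         "converged": fit.converged})
            candidates.append({"lam": lam_user, "tau": tau, "fit": fit,
                               "report": report, "merged": merged,
                               "bic": bic, "loglik": ll})
    table = pd.DataFrame(rows)
    if not candidates:
        raise RuntimeError(f"all fits failed: {errors}; table:\n{table}")
    best = min(candidates, key=lambda c: (c["bic"], -c["lam"], -c["tau"]))
    return best, table
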