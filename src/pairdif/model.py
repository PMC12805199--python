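"""Model / Results interface for group-pairwise DIF detection.

:class:`GroupPairwise2PL` is built from a response matrix with group
labels; :meth:`~GroupPairwise2PL.fit` estimates the TLP-penalized
multi-group 2PL at one tuning point and :meth:`~GroupPairwise2PL.fit_select`
searches a (lam, tau) grid and keeps the BIC-best candidate.  Both return
a :class:`GroupPairwise2PLResults` carrying the item and impact estimates,
the pairwise DIF flags, the group clusters per item parameter and a
plain-text :meth:`~GroupPairwise2PLResults.summary`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import __version__
from .data import ResponseData, read_responses, write_fit_report
from .penalty import TuningConfig
from .postprocess import postprocess_fit, select_model
from .solver import SolverOptions, default_rho, fit_single

__all__ = ["GroupPairwise2PL", "GroupPairwise2PLResults"]


class GroupPairwise2PL:
    """Multi-group 2PL with a group-pairwise truncated-L1 DIF penalty.

    Parameters
    ----------
    data : ResponseData
        Binary responses (missing allowed) with a group per respondent.

    Examples
    --------
    >>> model = GroupPairwise2PL.from_dataframe(df, group_col="country")
    >>> res = model.fit_select(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, data: ResponseData):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group",
                       id_col: str | None = None) -> "GroupPairwise2PL":
        """Build from a wide DataFrame (one item column per item)."""
        item_cols = [c for c in df.columns if c not in (group_col, id_col)]
        resp = df[item_cols].to_numpy(dtype=float)
        raw = df[group_col].tolist()
        labels: list = []
        idx: dict = {}
        groups = np.empty(len(df), dtype=int)
        for i, g in enumerate(raw):
            key = str(g)
            if key not in idx:
                idx[key] = len(labels)
                labels.append(key)
            groups[i] = idx[key]
        rids = df[id_col].astype(str).tolist() if id_col else []
        return cls(ResponseData(resp, groups, item_ids=[str(c) for c in item_cols],
                                respondent_ids=rids, group_labels=labels))

    @classmethod
    def from_csv(cls, path, group_col: str = "group", missing_token: str = "NA",
                 id_col: str | None = None) -> "GroupPairwise2PL":
        return cls(read_responses(path, group_column=group_col,
                                  missing_token=missing_token, id_column=id_col))

    def _opts(self, **kwargs) -> SolverOptions:
        return SolverOptions(**kwargs)

    def fit(self, lam: float = 0.01, tau: float = 0.2,
            rho: float | None = None, **opts) -> "GroupPairwise2PLResults":
        """Fit at a single tuning point.

        ``lam`` is on the per-respondent scale (multiplied by N
        internally); ``tau`` may be ``inf`` for the plain-lasso limit;
        ``rho`` defaults to N/10.  Extra keywords go to
        :class:`~pairdif.solver.SolverOptions`.
        """
        N = self.data.n_respondents
        rho = default_rho(N) if rho is None else float(rho)
        options = self._opts(**opts)
        tuning = TuningConfig(lam * N, tau, rho)
        fit = fit_single(self.data, tuning, options)
        report, merged, bic, ll = postprocess_fit(fit, self.data, options.K)
        return GroupPairwise2PLResults(self, fit, report, merged, bic, ll,
                                       lam_user=lam, options=options)

    def fit_select(self, lam_grid=None, tau_grid=None,
                   rho: float | None = None, **opts) -> "GroupPairwise2PLResults":
        """Grid search over (lam, tau); keep the BIC-best fit."""
        lam_grid = ([0.0025, 0.005, 0.01, 0.02, 0.04, 0.08]
                    if lam_grid is None else list(lam_grid))
        tau_grid = ([0.05, 0.1, 0.2, 0.3, 0.5]
                    if tau_grid is None else list(tau_grid))
        options = self._opts(**opts)
        best, table = select_model(self.data, lam_grid, tau_grid, options, rho)
        res = GroupPairwise2PLResults(self, best["fit"], best["report"],
                                      best["merged"], best["bic"],
                                      best["loglik"], lam_user=best["lam"],
                                      options=options)
        res.selection_table = table
        return res


class GroupPairwise2PLResults:
    """Estimates, DIF flags and diagnostics from a fitted model."""

    def __init__(self, model, fit, report, merged, bic, loglik,
                 lam_user, options):
        self.model = model
        self.fit = fit
        self.dif = report
        self.params = merged          # cluster-averaged (reported) parameters
        self.raw_params = fit.params  # final solver iterate
        self.bic = bic
        self.loglik = loglik
        self.lam = lam_user
        self.tau = fit.tuning.tau
        self.rho = fit.tuning.rho
        self.options = options
        self.converged = fit.converged
        self.selection_table = None

    # -- tables -------------------------------------------------------------

    def item_table(self) -> pd.DataFrame:
        """One row per (item, group): a, b and cluster representatives."""
        data = self.model.data
        rows = []
        for j, item in enumerate(data.item_ids):
            for s in range(data.n_groups):
                rows.append({
                    "item": item,
                    "group": data.group_labels[s],
                    "a": self.params.a[j, s],
                    "b": self.params.b[j, s],
                    "cluster_a": int(self.dif.reps_a[j, s]),
                    "cluster_b": int(self.dif.reps_b[j, s]),
                })
        return pd.DataFrame(rows)

    def flag_table(self) -> pd.DataFrame:
        """One row per (item, group pair) with per-kind DIF flags."""
        data = self.model.data
        rows = []
        for j, item in enumerate(data.item_ids):
            for p, (m, n) in enumerate(self.dif.pairs):
                rows.append({
                    "item": item, "m": m, "n": n,
                    "dif_a": bool(self.dif.flags_a[j, p]),
                    "dif_b": bool(self.dif.flags_b[j, p]),
                    "dif_any": bool(self.dif.flags_any[j, p]),
                })
        return pd.DataFrame(rows)

    def impact_table(self) -> pd.DataFrame:
        data = self.model.data
        return pd.DataFrame({
            "group": data.group_labels,
            "mu": self.params.mu,
            "sigma2": self.params.sigma2,
        })

    def metadata(self) -> dict:
        return {
            "package": f"pairdif {__version__}",
            "lam": self.lam,
            "lam_total": self.fit.tuning.lam,
            "tau": None if math.isinf(self.tau) else self.tau,
            "rho": self.rho,
            "bic": self.bic,
            "loglik": self.loglik,
            "n_outer": self.fit.n_outer,
            "n_inner": self.fit.n_inner,
            "converged": self.converged,
            "feasibility_gap": self.fit.feasibility_gap,
            "p_a": self.dif.p_a,
            "p_b": self.dif.p_b,
            "n_respondents": self.model.data.n_respondents,
            "n_items": self.model.data.n_items,
            "n_groups": self.model.data.n_groups,
            "seed": self.options.seed,
            "tol": self.options.tol,
            "quad_points": self.options.K,
        }

    def save(self, out_dir) -> list:
        """Write the report files (see :func:`pairdif.data.write_fit_report`)."""
        return write_fit_report(self, out_dir)

    def summary(self) -> str:
        data = self.model.data
        n_dif_items = int(self.dif.flags_any.any(axis=1).sum())
        tau_str = "inf" if math.isinf(self.tau) else f"{self.tau:g}"
        lines = [
            "Group-pairwise TLP DIF detection (2PL)",
            "=" * 54,
            f"Respondents: {data.n_respondents}   Items: {data.n_items}   "
            f"Groups: {data.n_groups}",
            f"lam = {self.lam:g} (per respondent)   tau = {tau_str}   "
            f"rho = {self.rho:g}",
            f"log-likelihood = {self.loglik:.3f}   BIC = {self.bic:.3f}",
            f"distinct parameters: {self.dif.p_a} slopes, {self.dif.p_b} intercepts",
            f"converged: {self.converged} "
            f"(outer {self.fit.n_outer}, inner {self.fit.n_inner}, "
            f"feasibility gap {self.fit.feasibility_gap:.2e})",
            f"items with DIF on any pair: {n_dif_items} / {data.n_items}",
            "",
            "Impact (latent trait by group):",
        ]
        for s in range(data.n_groups):
            lines.append(f"  group {data.group_labels[s]:>6}: "
                         f"mu = {self.params.mu[s]:+.3f}, "
                         f"sigma2 = {self.params.sigma2[s]:.3f}")
        flagged = self.flag_table()
        flagged = flagged[flagged["dif_any"]]
        lines.append("")
        if flagged.empty:
            lines.append("No pairwise DIF detected.")
        else:
            lines.append("Flagged (item, group pair) cells: "
                         f"{len(flagged)}")
            per_item = flagged.groupby("item").size()
            for item, cnt in per_item.items():
                lines.append(f"  {item}: {cnt} pair(s)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<GroupPairwise2PLResults lam={self.lam:g} tau={self.tau:g} "
                f"bic={self.bic:.2f} converged={self.converged}>")
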