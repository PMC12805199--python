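"""Synthetic multi-group 2PL data with impact and configurable DIF.

The generator mirrors the structure of a multi-group DIF simulation
study: S groups (balanced or unbalanced sizes), J items whose base
parameters are shared across groups, a leading block of DIF items whose
parameters receive per-group offsets, and impact simulated as
group-specific latent means with a common variance.  Detection quality is
scored by pairwise true/false positive rates over all S(S-1)/2 group
pairs and both parameter kinds.

Defaults: base slopes LogNormal(0, 0.25), base intercepts N(0, 1), DIF
offsets +-0.5 on slopes and +-1.0 on intercepts (alternating sign across
groups 2..S, group 1 unshifted), impact means evenly spaced in
[-0.5, 0.5] for groups 2..S with group 1 at 0, common variance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import ResponseData
from .penalty import pair_index
from .twopl import ModelParams, irf

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "truth_flags",
    "tpr_fpr",
    "unbalanced_sizes",
    "load_config",
]


def _default_impact_means(S: int) -> np.ndarray:
    means = np.zeros(S)
    if S > 1:
        means[1:] = np.linspace(-0.5, 0.5, S - 1)
    return means


def unbalanced_sizes(N: int, S: int, decay: float = 0.5) -> list:
    """Geometric-decay group shares: group s+1 is ``decay`` times group s.

    A documented fallback for unbalanced designs; shares are normalized to
    sum to N with every group kept at size >= 1.
    """
    shares = decay ** np.arange(S)
    sizes = np.maximum(1, np.round(N * shares / shares.sum()).astype(int))
    sizes[0] += N - sizes.sum()
    return sizes.tolist()


@dataclass
class SimulationConfig:
    """Generating configuration for one synthetic dataset.

    ``dif_a`` / ``dif_b`` are either scalar magnitudes (expanded to the
    alternating per-group scheme 0, +d, -d, +d, ... over the leading
    ``n_dif_items`` items) or full (n_dif_items, S) offset matrices.
    """

    S: int = 4
    group_sizes: list = field(default_factory=lambda: [500, 500, 500, 500])
    J: int = 20
    n_dif_items: int = 4
    dif_a: object = 0.5
    dif_b: object = 1.0
    base_a_dist: tuple = ("lognormal", {"mean": 0.0, "sigma": 0.25})
    base_b_dist: tuple = ("normal", {"loc": 0.0, "scale": 1.0})
    impact_means: list | None = None
    impact_var: float = 1.0
    missing_rate: float = 0.0
    items_per_respondent: int | None = None
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != self.S:
            raise ValueError("group_sizes must have S entries")
        if min(self.group_sizes) < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.n_dif_items <= self.J:
            raise ValueError("n_dif_items must be in [0, J]")
        if self.impact_means is None:
            self.impact_means = _default_impact_means(self.S).tolist()
        if len(self.impact_means) != self.S or self.impact_means[0] != 0.0:
            raise ValueError("impact_means must have S entries with the first 0")
        if not self.impact_var > 0:
            raise ValueError("impact_var must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def offsets(self, kind: str) -> np.ndarray:
        """(n_dif_items, S) offset matrix for parameter kind 'a' or 'b'."""
        raw = self.dif_a if kind == "a" else self.dif_b
        raw = np.asarray(raw, dtype=float)
        if raw.ndim == 0:
            row = np.zeros(self.S)
            for s in range(1, self.S):
                row[s] = float(raw) * (1 if s % 2 == 1 else -1)
            return np.tile(row, (self.n_dif_items, 1))
        if raw.shape != (self.n_dif_items, self.S):
            raise ValueError("offset matrix must have shape (n_dif_items, S)")
        return raw


@dataclass
class SimulatedDataset:
    """Responses plus generating truth: parameters and pairwise DIF flags."""

    data: ResponseData
    true_params: ModelParams
    true_flags_a: np.ndarray
    true_flags_b: np.ndarray
    config: SimulationConfig


_DISTS = {
    "lognormal": lambda rng, p, n: rng.lognormal(p.get("mean", 0.0),
                                                 p.get("sigma", 1.0), n),
    "normal": lambda rng, p, n: rng.normal(p.get("loc", 0.0),
                                           p.get("scale", 1.0), n),
    "uniform": lambda rng, p, n: rng.uniform(p.get("low", 0.0),
                                             p.get("high", 1.0), n),
}


def _raw_item_params(config: SimulationConfig, rng) -> tuple:
    name_a, pa = config.base_a_dist
    name_b, pb = config.base_b_dist
    for name in (name_a, name_b):
        if name not in _DISTS:
            raise ValueError(f"unknown distribution {name!r}")
    base_a = _DISTS[name_a](rng, pa, config.J)
    base_b = _DISTS[name_b](rng, pb, config.J)
    a = np.tile(base_a[:, None], (1, config.S))
    b = np.tile(base_b[:, None], (1, config.S))
    k = config.n_dif_items
    if k:
        a[:k] += config.offsets("a")
        b[:k] += config.offsets("b")
    return a, b


def truth_flags(config: SimulationConfig, true_params: ModelParams) -> tuple:
    """Pairwise ground-truth DIF flags from exact parameter inequality."""
    pairs = pair_index(config.S)
    fa = np.zeros((config.J, len(pairs)), dtype=bool)
    fb = np.zeros_like(fa)
    for p, (m, n) in enumerate(pairs):
        fa[:, p] = true_params.a[:, m - 1] != true_params.a[:, n - 1]
        fb[:, p] = true_params.b[:, m - 1] != true_params.b[:, n - 1]
    return fa, fb


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    a_raw, b_raw = _raw_item_params(config, rng)
    groups = np.repeat(np.arange(config.S), config.group_sizes)
    N = groups.size
    theta = rng.normal(np.asarray(config.impact_means)[groups],
                       np.sqrt(config.impact_var))
    prob = irf(theta[:, None], a_raw[:, groups].T, b_raw[:, groups].T)
    # ground truth on the identified metric (group-1 trait SD = 1): a common
    # generating variance is absorbed into the slopes and the impact means
    sd = float(np.sqrt(config.impact_var))
    params = ModelParams(a_raw * sd, b_raw,
                         np.asarray(config.impact_means) / sd,
                         np.ones(config.S))
    resp = (rng.random((N, config.J)) < prob).astype(float)
    if config.items_per_respondent is not None:
        keep = np.zeros((N, config.J), dtype=bool)
        for i in range(N):
            keep[i, rng.choice(config.J, config.items_per_respondent,
                               replace=False)] = True
        resp[~keep] = np.nan
    elif config.missing_rate > 0:
        resp[rng.random((N, config.J)) < config.missing_rate] = np.nan
    # repair rows/columns left fully missing so the data invariants hold
    mask = ~np.isnan(resp)
    for i in np.flatnonzero(mask.sum(axis=1) == 0):
        j = rng.integers(config.J)
        resp[i, j] = float(rng.random() < prob[i, j])
    mask = ~np.isnan(resp)
    for j in np.flatnonzero(mask.sum(axis=0) == 0):
        i = rng.integers(N)
        resp[i, j] = float(rng.random() < prob[i, j])
    data = ResponseData(resp, groups)
    fa, fb = truth_flags(config, params)
    return SimulatedDataset(data, params, fa, fb, config)


def tpr_fpr(flags_a, flags_b, truth_a, truth_b) -> dict:
    """Pairwise detection rates per parameter kind.

    TPR = flagged-and-true / true, FPR = flagged-and-false / false, each
    computed over all (item, pair) cells; an undefined ratio (empty
    denominator) is reported as ``nan``.
    """
    out = {}
    for kind, flags, truth in (("a", flags_a, truth_a), ("b", flags_b, truth_b)):
        flags = np.asarray(flags, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if flags.shape != truth.shape:
            raise ValueError(f"shape mismatch for kind {kind!r}: "
                             f"{flags.shape} vs {truth.shape}")
        pos = truth.sum()
        neg = (~truth).sum()
        out[f"tpr_{kind}"] = float((flags & truth).sum() / pos) if pos else float("nan")
        out[f"fpr_{kind}"] = float((flags & ~truth).sum() / neg) if neg else float("nan")
    return out


def load_config(path) -> SimulationConfig:
    """Read a YAML scenario file into a :class:`SimulationConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("base_a_dist", "base_b_dist"):
        if key in raw and isinstance(raw[key], (list, tuple)):
            raw[key] = (raw[key][0], dict(raw[key][1]))
    return SimulationConfig(**raw)
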