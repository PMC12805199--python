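"""Response-matrix containers and text-format I/O.

The canonical input is a wide CSV: one row per respondent, one column per
item (entries 0, 1 or a missing token) and one group column.  Sparse data
from adaptive tests is naturally long (respondent, item, response), so a
long-format reader is provided as well.  Groups may be labelled by arbitrary
strings; they are mapped to contiguous indices by order of first appearance
and the label map is kept for reporting.  All user-facing output uses
1-based group and item-pair indexing; internal arrays are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResponseData",
    "read_responses",
    "read_responses_long",
    "write_fit_report",
]


@dataclass
class ResponseData:
    """An N x J binary response matrix with missingness and group labels.

    Parameters
    ----------
    responses : ndarray of shape (N, J)
        Float matrix with entries 0.0, 1.0 or ``nan`` (missing).
    groups : ndarray of shape (N,)
        Contiguous 0-based group index per respondent.
    item_ids, respondent_ids : list of str
        Column / row labels.
    group_labels : list of str
        ``group_labels[s]`` is the original label of internal group ``s``.
    """

    responses: np.ndarray
    groups: np.ndarray
    item_ids: list = field(default_factory=list)
    respondent_ids: list = field(default_factory=list)
    group_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-dimensional")
        n, j = self.responses.shape
        if self.groups.shape != (n,):
            raise ValueError("groups must have one entry per respondent")
        if not self.item_ids:
            self.item_ids = [f"item{k + 1}" for k in range(j)]
        if not self.respondent_ids:
            self.respondent_ids = [str(i + 1) for i in range(n)]
        if not self.group_labels:
            self.group_labels = [str(s + 1) for s in range(self.groups.max() + 1)]
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.groups, minlength=self.n_groups)

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix: True where a response is observed."""
        return ~np.isnan(self.responses)

    def validate(self):
        bad = self.mask & (self.responses != 0.0) & (self.responses != 1.0)
        if bad.any():
            rows, cols = np.where(bad)
            raise ValueError(
                f"non-binary observed value at row {rows[0] + 1} "
                f"(respondent {self.respondent_ids[rows[0]]}), "
                f"column {self.item_ids[cols[0]]}"
            )
        if self.groups.min() < 0 or self.groups.max() >= len(self.group_labels):
            raise ValueError("group indices out of range")
        sizes = self.group_sizes
        if (sizes < 1).any():
            empty = int(np.where(sizes < 1)[0][0])
            raise ValueError(f"group {self.group_labels[empty]!r} is empty")
        per_resp = self.mask.sum(axis=1)
        if (per_resp == 0).any():
            i = int(np.where(per_resp == 0)[0][0])
            raise ValueError(f"respondent {self.respondent_ids[i]!r} has no observed responses")
        per_item = self.mask.sum(axis=0)
        if (per_item == 0).any():
            j = int(np.where(per_item == 0)[0][0])
            raise ValueError(f"item {self.item_ids[j]!r} has no observed responses")

    # internal per-group cache used by the likelihood routines
    def _cache(self):
        if getattr(self, "_cache_", None) is None:
            m = self.mask
            y = np.nan_to_num(self.responses, nan=0.0)
            rows = [np.flatnonzero(self.groups == s) for s in range(self.n_groups)]
            self._cache_ = {
                "rows": rows,
                "y1": y * m,  # observed correct indicator
                "y0": (1.0 - y) * m,  # observed incorrect indicator
            }
        return self._cache_


def _relabel_groups(raw) -> tuple[np.ndarray, list]:
    labels: list = []
    index: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, g in enumerate(raw):
        key = str(g)
        if key not in index:
            index[key] = len(labels)
            labels.append(key)
        out[i] = index[key]
    return out, labels


def read_responses(path, group_column: str = "group", missing_token: str = "NA",
                   id_column: str | None = None) -> ResponseData:
    """Read a wide response CSV (one row per respondent, one column per item)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path}")
    groups, labels = _relabel_groups(df[group_column].tolist())
    item_cols = [c for c in df.columns if c not in (group_column, id_column)]
    respondent_ids = (
        df[id_column].tolist() if id_column else [str(i + 1) for i in range(len(df))]
    )
    resp = np.full((len(df), len(item_cols)), np.nan)
    for jj, col in enumerate(item_cols):
        vals = df[col].tolist()
        for ii, v in enumerate(vals):
            v = v.strip()
            if v == missing_token or v == "":
                continue
            try:
                x = float(v)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {v!r} at row {ii + 1}, column {col!r}"
                ) from None
            if x not in (0.0, 1.0):
                raise ValueError(
                    f"non-binary observed value {v!r} at row {ii + 1}, column {col!r}"
                )
            resp[ii, jj] = x
    return ResponseData(resp, groups, item_ids=item_cols,
                        respondent_ids=respondent_ids, group_labels=labels)


def read_responses_long(path, respondent_column: str = "respondent",
                        item_column: str = "item", response_column: str = "response",
                        group_column: str = "group") -> ResponseData:
    """Read a long response CSV (one row per observed respondent-item pair).

    Missing responses are simply absent rows, the natural encoding for sparse
    adaptive-test data.  The group label must be constant within respondent.
    """
    df = pd.read_csv(path, dtype={respondent_column: str, item_column: str})
    for col in (respondent_column, item_column, response_column, group_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    resp_ids = list(dict.fromkeys(df[respondent_column]))
    item_ids = list(dict.fromkeys(df[item_column]))
    ri = {r: i for i, r in enumerate(resp_ids)}
    ci = {c: j for j, c in enumerate(item_ids)}
    resp = np.full((len(resp_ids), len(item_ids)), np.nan)
    group_raw = [None] * len(resp_ids)
    for r, c, v, g in zip(df[respondent_column], df[item_column],
                          df[response_column], df[group_column]):
        x = float(v)
        if x not in (0.0, 1.0):
            raise ValueError(f"non-binary response {v!r} for respondent {r!r}, item {c!r}")
        i = ri[r]
        if group_raw[i] is not None and str(group_raw[i]) != str(g):
            raise ValueError(f"respondent {r!r} appears with two group labels")
        group_raw[i] = g
        resp[i, ci[c]] = x
    groups, labels = _relabel_groups(group_raw)
    return ResponseData(resp, groups, item_ids=item_ids,
                        respondent_ids=resp_ids, group_labels=labels)


def write_fit_report(results, out_dir) -> list:
    """Write a fitted model's report files to ``out_dir``.

    Emits ``item_parameters.csv`` (item, group, a, b, cluster_a, cluster_b),
    ``dif_flags.csv`` (item, m, n, dif_a, dif_b, dif_any), ``impact.csv``
    (group, mu, sigma2) and ``metadata.json``.  ``results`` is any object
    with ``item_table`` / ``flag_table`` / ``impact_table`` / ``metadata``
    methods (see :class:`pairdif.model.GroupPairwise2PLResults`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("item_parameters.csv", results.item_table()),
        ("dif_flags.csv", results.flag_table()),
        ("impact.csv", results.impact_table()),
    ):
        p = out / name
        frame.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    meta = out / "metadata.json"
    with open(meta, "w") as fh:
        json.dump(results.metadata(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(meta)
    return written
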