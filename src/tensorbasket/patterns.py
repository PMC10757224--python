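"""Turning scores and loadings into purchase-pattern summaries.

Covers the downstream analyses of the fitted decomposition: flagging
atypical weeks/groups from large loadings, stratifying customers into
high/typical/low score groups and deciles, standardized group profiles,
weekly expenditure-share trajectories per decile, and hierarchical
clustering of loadings for heat-map ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .model import ScoreArray, TensorPCAResults
from .tensor import PurchaseTensor

__all__ = [
    "StratificationLabels",
    "GroupProfile",
    "stratify",
    "deciles",
    "group_profile",
    "trajectory_by_decile",
    "flag_atypical",
    "cluster_loadings",
]


@dataclass
class StratificationLabels:
    """High/typical/low labels for one component pair."""

    pair: tuple[int, int]
    q: float
    customer_ids: list[str]
    labels: np.ndarray  # array of "high" | "typical" | "low"

    def ids(self, label: str) -> list[str]:
        return [c for c, l in zip(self.customer_ids, self.labels) if l == label]

    def counts(self) -> dict[str, int]:
        return {k: int((self.labels == k).sum()) for k in ("high", "typical", "low")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "customer_id": self.customer_ids,
                "j1": self.pair[0],
                "j2": self.pair[1],
                "label": self.labels,
            }
        )


@dataclass
class GroupProfile:
    """Within-group mean of per-cell standardized expenditures (p×t)."""

    z_profile: pd.DataFrame
    group_size: int


def _ranks(scores: np.ndarray) -> np.ndarray:
    """Ascending rank positions with ties broken by stable customer order."""
    order = np.argsort(scores, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return ranks


def stratify(
    scores: ScoreArray, pair: tuple[int, int], q: float = 0.10
) -> StratificationLabels:
    """Label the top and bottom q-fraction of customers by one pair score.

    The ⌊qn⌋ customers with the highest (j1, j2) scores form "high", the
    ⌊qn⌋ lowest "low", and the remaining ~(1−2q) fraction "typical".
    Ties resolve by stable customer order: earlier customers take the
    lower rank.
    """
    if not (0 <= q < 0.5):
        raise ValueError("q must satisfy 0 <= q < 0.5")
    s = scores.pair(*pair)
    n = s.size
    k = floor(q * n)
    ranks = _ranks(s)
    labels = np.full(n, "typical", dtype=object)
    if k > 0:
        labels[ranks < k] = "low"
        labels[ranks >= n - k] = "high"
    return StratificationLabels(tuple(pair), q, list(scores.customer_ids), labels)


def deciles(scores: ScoreArray, pair: tuple[int, int]) -> pd.Series:
    """Rank-based decile labels 1..10 for one component pair.

    Decile 10 holds the highest scores; sizes differ by at most one, with
    the larger deciles assigned to the lowest ranks.  Ties are stable in
    customer order.
    """
    s = scores.pair(*pair)
    n = s.size
    if n < 10:
        raise ValueError("deciles need at least 10 customers")
    base, rem = divmod(n, 10)
    sizes = np.array([base + 1] * rem + [base] * (10 - rem))
    bounds = np.cumsum(sizes)
    ranks = _ranks(s)
    labels = np.searchsorted(bounds, ranks, side="right") + 1
    return pd.Series(labels, index=scores.customer_ids, name="decile")


def group_profile(tensor: PurchaseTensor, member_ids: Sequence[str]) -> GroupProfile:
    """Standardized expenditure profile of a customer group.

    Each (group, week) cell is z-scored across ALL customers (population
    standard deviation; constant cells map to 0), then averaged over the
    member set — so the all-customer profile is exactly zero and a value
    of, say, −0.4 reads "0.4 SDs below the cohort average".
    """
    members = list(member_ids)
    if not members:
        raise ValueError("member set is empty")
    index = {c: i for i, c in enumerate(tensor.customer_ids)}
    unknown = [c for c in members if c not in index]
    if unknown:
        raise ValueError(f"unknown customer id(s) {unknown[:10]}")
    rows = [index[c] for c in members]
    mean = tensor.values.mean(axis=0)
    sd = tensor.values.std(axis=0)  # population sd over customers
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (tensor.values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    profile = pd.DataFrame(
        z[rows].mean(axis=0), index=tensor.group_labels, columns=tensor.week_labels
    )
    return GroupProfile(profile, len(members))


def trajectory_by_decile(
    tensor: PurchaseTensor,
    decile_labels: pd.Series,
    product_subset: Sequence[str],
) -> pd.DataFrame:
    """Mean weekly percentage spent on a product subset, per decile.

    For each customer and week the percentage is 100 × (spend on the
    subset) / (total spend that week); weeks where a customer spent
    nothing at all express no composition and are excluded from that
    customer's contribution.  Rows are deciles 1..10, columns weeks.
    """
    subset = [str(g) for g in product_subset]
    if not subset:
        raise ValueError("product subset is empty")
    unknown = [g for g in subset if g not in tensor.group_labels]
    if unknown:
        raise ValueError(f"unknown product group(s) {unknown[:10]}")
    gi = [tensor.group_labels.index(g) for g in subset]
    totals = tensor.values.sum(axis=1)               # n×t
    subset_spend = tensor.values[:, gi, :].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * subset_spend / np.where(totals > 0, totals, 1.0), np.nan)
    labels = decile_labels.reindex(tensor.customer_ids)
    out = np.full((10, tensor.n_weeks), np.nan)
    for d in range(1, 11):
        rows = np.flatnonzero(labels.to_numpy() == d)
        if rows.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN weeks
                out[d - 1] = np.nanmean(pct[rows], axis=0)
    return pd.DataFrame(out, index=pd.RangeIndex(1, 11, name="decile"),
                        columns=tensor.week_labels)


def flag_atypical(
    results: TensorPCAResults,
    threshold: float = 0.3,
    n_components: int | tuple[int, int] | None = None,
) -> tuple[list[int], list[str]]:
    """Weeks and product groups with a large loading on any leading component.

    A label is flagged when the absolute loading exceeds ``threshold`` in
    at least one of the first ``n_components`` columns of that mode's
    loading matrix.  Intended to run on a model fitted to the unpeeled
    tensor; the flagged slices are then peeled before a refit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if n_components is None:
        kp, kt = results.n_product_components, results.n_week_components
    elif isinstance(n_components, int):
        kp = min(n_components, results.n_product_components)
        kt = min(n_components, results.n_week_components)
    else:
        kp, kt = n_components
        if kp > results.n_product_components or kt > results.n_week_components:
            raise ValueError("n_components exceeds fitted ranks")
    big_g = np.any(np.abs(results.U1[:, :kp]) > threshold, axis=1)
    big_w = np.any(np.abs(results.U2[:, :kt]) > threshold, axis=1)
    weeks = [int(w) for w, b in zip(results.model.tensor.week_labels, big_w) if b]
    groups = [g for g, b in zip(results.model.tensor.group_labels, big_g) if b]
    return weeks, groups


def correlation_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Pearson(x, y) between rows; constant rows sit at the
    maximal distance 1 from everything."""
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Xc @ Xc.T / np.where(denom > 0, denom, 1.0), 0.0)
    D = 1.0 - corr
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cluster_loadings(loading_matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering with correlation distance.

    Returns ``(leaf_order, linkage_matrix)``; the leaf order arranges
    similar loading rows adjacently for heat-map display.
    """
    if isinstance(loading_matrix, pd.DataFrame):
        loading_matrix = loading_matrix.to_numpy()
    X = np.asarray(loading_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    D = correlation_distance_matrix(X)
    Z = linkage(squareform(D, checks=False), method="average")
    order = leaves_list(Z)
    return order, Z
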