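"""Cohort filters and normalisation for purchase tensors.

Implements the exclusion criteria used to restrict a loyalty-card cohort
to regular customers (too many empty weeks, or an annual total below a
spending floor), the rescaling of every customer's annual expenditure to a
common €1000 budget, the peeling of atypical weeks/groups before a refit,
and the descriptive weekly-share and z-score summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tensor import PurchaseTensor

__all__ = [
    "ExclusionReport",
    "EmptyCohortError",
    "apply_group_mapping",
    "apply_exclusions",
    "rescale_annual",
    "peel",
    "weekly_share",
    "row_zscore",
]

#: Absolute tolerance for currency comparisons at the exclusion boundary.
CURRENCY_TOL = 1e-9


class EmptyCohortError(ValueError):
    """Every customer was removed by the exclusion filters."""


@dataclass
class ExclusionReport:
    """Tally of the cohort exclusion filters.

    Customers may violate both criteria; they are listed under each but
    counted once in the final arithmetic:
    ``n_final = n_initial - |zero_weeks ∪ low_total|``.
    """

    n_initial: int
    n_final: int
    max_zero_weeks: int
    min_total: float
    excluded_zero_weeks: list[str] = field(default_factory=list)
    excluded_low_total: list[str] = field(default_factory=list)

    @property
    def n_excluded_zero_weeks(self) -> int:
        return len(self.excluded_zero_weeks)

    @property
    def n_excluded_low_total(self) -> int:
        return len(self.excluded_low_total)

    @property
    def n_excluded_overlap(self) -> int:
        return len(set(self.excluded_zero_weeks) & set(self.excluded_low_total))

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.excluded_zero_weeks) | set(self.excluded_low_total)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_final": self.n_final,
            "n_excluded_zero_weeks": self.n_excluded_zero_weeks,
            "n_excluded_low_total": self.n_excluded_low_total,
            "n_excluded_overlap": self.n_excluded_overlap,
            "max_zero_weeks": self.max_zero_weeks,
            "min_total": self.min_total,
            "excluded_zero_weeks": sorted(self.excluded_zero_weeks),
            "excluded_low_total": sorted(self.excluded_low_total),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def apply_group_mapping(records: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Regroup transaction records through a user-supplied two-column table.

    ``mapping`` must have columns ``from`` and ``to``; every group label in
    ``records`` must be mapped.  Applied before tensor assembly.
    """
    for col in ("from", "to"):
        if col not in mapping.columns:
            raise ValueError("mapping table needs columns 'from' and 'to'")
    lut = dict(zip(mapping["from"].astype(str), mapping["to"].astype(str)))
    unknown = set(records["group"].astype(str)) - set(lut)
    if unknown:
        raise ValueError(f"unmapped group label(s): {sorted(unknown)[:10]}")
    out = records.copy()
    out["group"] = out["group"].astype(str).map(lut)
    return out


def apply_exclusions(
    tensor: PurchaseTensor,
    max_zero_weeks: int = 8,
    min_total: float = 500.0,
    remove_ids: Sequence[str] | None = None,
) -> tuple[PurchaseTensor, ExclusionReport]:
    """Remove irregular customers from the cohort.

    A customer is excluded when they have strictly more than
    ``max_zero_weeks`` weeks with no purchases at all, or an annual total
    strictly below ``min_total`` (boundary totals compared with a 1e-9
    absolute tolerance, so exactly €500 is retained).  ``remove_ids``
    (e.g. known staff cards) are dropped before the numeric criteria.
    """
    if remove_ids:
        keep = [c for c in tensor.customer_ids if c not in set(remove_ids)]
        tensor = tensor.select_customers(keep)
    n_initial = tensor.n_customers
    weekly_totals = tensor.values.sum(axis=1)          # n × t
    zero_weeks = (weekly_totals == 0.0).sum(axis=1)
    totals = tensor.customer_totals()
    ids = np.asarray(tensor.customer_ids, dtype=object)
    crit_zero = zero_weeks > max_zero_weeks
    crit_low = totals < min_total - CURRENCY_TOL
    keep_mask = ~(crit_zero | crit_low)
    if not keep_mask.any():
        raise EmptyCohortError(
            "all customers excluded; relax max_zero_weeks/min_total or check units"
        )
    kept = PurchaseTensor(
        tensor.values[keep_mask],
        list(ids[keep_mask]),
        list(tensor.group_labels),
        tensor.week_labels.copy(),
    )
    report = ExclusionReport(
        n_initial=n_initial,
        n_final=int(keep_mask.sum()),
        max_zero_weeks=max_zero_weeks,
        min_total=min_total,
        excluded_zero_weeks=list(ids[crit_zero]),
        excluded_low_total=list(ids[crit_low]),
    )
    return kept, report


def rescale_annual(tensor: PurchaseTensor, target: float = 1000.0) -> PurchaseTensor:
    """Rescale each customer so their annual total equals ``target`` euros.

    Gives every card holder equal weight and makes cells interpretable as
    euros out of €1000; within-customer proportions are unchanged.
    """
    totals = tensor.customer_totals()
    if np.any(totals <= 0):
        raise ValueError(
            "zero-total customer present; run apply_exclusions before rescaling"
        )
    values = tensor.values * (target / totals)[:, None, None]
    return PurchaseTensor(
        values, list(tensor.customer_ids), list(tensor.group_labels), tensor.week_labels.copy()
    )


def peel(
    tensor: PurchaseTensor,
    drop_weeks: Sequence[int] = (),
    drop_groups: Sequence[str] = (),
) -> PurchaseTensor:
    """Remove atypical week and product-group slices before refitting.

    No re-scaling is performed: the peeled tensor keeps the already-scaled
    expenditures, so customer totals drop below the €1000 budget by the
    amount spent on the removed slices.
    """
    drop_weeks = [int(w) for w in drop_weeks]
    drop_groups = [str(g) for g in drop_groups]
    week_set = set(tensor.week_labels.tolist())
    unknown_w = [w for w in drop_weeks if w not in week_set]
    if unknown_w:
        raise ValueError(f"unknown week label(s) {unknown_w}")
    unknown_g = [g for g in drop_groups if g not in tensor.group_labels]
    if unknown_g:
        raise ValueError(f"unknown group label(s) {unknown_g}")
    keep_w = [i for i, w in enumerate(tensor.week_labels) if w not in set(drop_weeks)]
    keep_g = [i for i, g in enumerate(tensor.group_labels) if g not in set(drop_groups)]
    if not keep_w or not keep_g:
        raise ValueError("peeling would remove every week or every group")
    return PurchaseTensor(
        tensor.values[:, keep_g][:, :, keep_w],
        list(tensor.customer_ids),
        [tensor.group_labels[i] for i in keep_g],
        tensor.week_labels[keep_w],
    )


def weekly_share(tensor: PurchaseTensor) -> pd.Series:
    """Percentage of all purchases falling in each week.

    Under a perfectly even distribution every week carries 100/t percent —
    1.9% for a 52-week year; holiday weeks stand out above this line.
    """
    grand = tensor.values.sum()
    if grand <= 0:
        raise ValueError("tensor has zero grand total")
    shares = 100.0 * tensor.values.sum(axis=(0, 1)) / grand
    return pd.Series(shares, index=tensor.week_labels, name="weekly_share_pct")


def row_zscore(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Row-wise z scores with population standard deviation.

    Constant rows map to all-zeros rather than NaN so that flat product
    groups render as neutral in heat maps.
    """
    values = np.asarray(matrix, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd (denominator t)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z
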