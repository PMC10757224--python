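"""Labelled purchase tensors and long-format transaction I/O.

The central container is :class:`PurchaseTensor`, a dense labelled 3-way
array ``X ∈ R^(n×p×t)`` of nonnegative weekly expenditures indexed by
customer, product group and week.  Absent transactions are zeros by
construction, so the tensor has no missing values.

Transactions travel as long-format delimited text with the header
``customer_id,week,group,amount`` — one row per nonzero cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PurchaseRecord",
    "PurchaseTensor",
    "TransactionFormatError",
    "TransactionValidationError",
    "read_transactions",
    "assemble_tensor",
    "write_transactions",
    "write_tensor_dir",
    "read_tensor_dir",
]

REQUIRED_COLUMNS = ("customer_id", "week", "group", "amount")


class TransactionFormatError(ValueError):
    """The transaction file lacks required structure (columns, header)."""


class TransactionValidationError(ValueError):
    """Rows parsed but violate the record contract (range, sign, labels)."""


class PurchaseRecord(NamedTuple):
    """One elementary observation: a customer's spend on a group in a week."""

    customer_id: str
    week: int
    group: str
    amount: float


@dataclass
class PurchaseTensor:
    """Dense labelled expenditure tensor (customers × product groups × weeks).

    Parameters
    ----------
    values : ndarray, shape (n, p, t)
        Nonnegative expenditures; cell ``[i, g, w]`` is customer ``i``'s
        spend on group ``g`` in week ``w``.
    customer_ids : list of str
        Unique customer identifiers, one per tensor row.
    group_labels : list of str
        Unique product-group labels.
    week_labels : ndarray of int
        Strictly increasing week indices (1-based).
    """

    values: np.ndarray
    customer_ids: list[str]
    group_labels: list[str]
    week_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-way array (n, p, t)")
        n, p, t = self.values.shape
        self.customer_ids = [str(c) for c in self.customer_ids]
        self.group_labels = [str(g) for g in self.group_labels]
        if self.week_labels is None:
            self.week_labels = np.arange(1, t + 1)
        self.week_labels = np.asarray(self.week_labels, dtype=int)
        if len(self.customer_ids) != n:
            raise ValueError(f"{len(self.customer_ids)} customer ids for {n} rows")
        if len(self.group_labels) != p:
            raise ValueError(f"{len(self.group_labels)} group labels for {p} groups")
        if self.week_labels.shape != (t,):
            raise ValueError(f"{self.week_labels.size} week labels for {t} weeks")
        if len(set(self.customer_ids)) != n:
            raise ValueError("customer ids must be unique")
        if len(set(self.group_labels)) != p:
            raise ValueError("group labels must be unique")
        if np.any(np.diff(self.week_labels) <= 0):
            raise ValueError("week labels must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor values must be finite")

    # -- basic geometry -------------------------------------------------
    @property
    def n_customers(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    @property
    def n_weeks(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def slice(self, customer_id: str) -> np.ndarray:
        """The p×t expenditure matrix of one customer."""
        return self.values[self.customer_ids.index(customer_id)]

    def customer_totals(self) -> np.ndarray:
        """Annual total per customer (sum over groups and weeks)."""
        return self.values.sum(axis=(1, 2))

    def select_customers(self, ids: Sequence[str]) -> "PurchaseTensor":
        index = {c: i for i, c in enumerate(self.customer_ids)}
        rows = [index[c] for c in ids]
        return PurchaseTensor(
            self.values[rows], list(ids), list(self.group_labels), self.week_labels.copy()
        )

    def to_long_frame(self, drop_zeros: bool = True) -> pd.DataFrame:
        """Long-format DataFrame with one row per (nonzero) cell."""
        n, p, t = self.shape
        ci, gi, wi = np.unravel_index(np.arange(n * p * t), (n, p, t))
        frame = pd.DataFrame(
            {
                "customer_id": np.asarray(self.customer_ids, dtype=object)[ci],
                "week": self.week_labels[wi],
                "group": np.asarray(self.group_labels, dtype=object)[gi],
                "amount": self.values.ravel(),
            }
        )
        if drop_zeros:
            frame = frame[frame["amount"] != 0.0].reset_index(drop=True)
        return frame

    def __eq__(self, other: object) -> bool:  # label-aware equality
        if not isinstance(other, PurchaseTensor):
            return NotImplemented
        return (
            self.customer_ids == other.customer_ids
            and self.group_labels == other.group_labels
            and np.array_equal(self.week_labels, other.week_labels)
            and np.array_equal(self.values, other.values)
        )


def read_transactions(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format transaction file.

    Returns a DataFrame with columns ``customer_id`` (str), ``week`` (int),
    ``group`` (str) and ``amount`` (float).  Malformed rows raise
    :class:`TransactionValidationError` naming the offending line numbers
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise TransactionFormatError(
            f"{path}: missing required column(s) {missing}; header must contain "
            f"{list(REQUIRED_COLUMNS)}"
        )
    if raw.empty:
        return pd.DataFrame(
            {"customer_id": pd.Series(dtype=object), "week": pd.Series(dtype=int),
             "group": pd.Series(dtype=object), "amount": pd.Series(dtype=float)}
        )
    week = pd.to_numeric(raw["week"], errors="coerce")
    amount = pd.to_numeric(raw["amount"], errors="coerce")
    bad = week.isna() | amount.isna() | (week != week.round())
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # +2: header line plus 1-basing
        raise TransactionValidationError(
            f"{path}: malformed week/amount on line(s) {lines[:20]}"
        )
    negative = amount < 0
    if negative.any():
        lines = (raw.index[negative] + 2).tolist()
        raise TransactionValidationError(
            f"{path}: negative amount on line(s) {lines[:20]}"
        )
    return pd.DataFrame(
        {
            "customer_id": raw["customer_id"].astype(object),
            "week": week.astype(int),
            # astype parses with correctly-rounded floats, so shortest-repr
            # output round-trips bit for bit
            "amount": raw["amount"].astype(float),
            "group": raw["group"].astype(object),
        }
    )[["customer_id", "week", "group", "amount"]]


def iter_records(frame: pd.DataFrame) -> Iterable[PurchaseRecord]:
    """Yield :class:`PurchaseRecord` tuples from a validated frame."""
    for row in frame.itertuples(index=False):
        yield PurchaseRecord(str(row.customer_id), int(row.week), str(row.group), float(row.amount))


def assemble_tensor(
    records: pd.DataFrame | Iterable[PurchaseRecord],
    week_range: tuple[int, int],
    group_list: Sequence[str] | None = None,
    customer_list: Sequence[str] | None = None,
) -> PurchaseTensor:
    """Assemble records into a dense :class:`PurchaseTensor`.

    Duplicate (customer, week, group) rows are summed; cells with no record
    are zero.  Customers are ordered by first appearance unless
    ``customer_list`` is given; groups by ``group_list`` or lexicographically.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=list(REQUIRED_COLUMNS))
    first, last = int(week_range[0]), int(week_range[1])
    if last < first:
        raise ValueError("week_range must be (first, last) with first <= last")
    t = last - first + 1
    if not records.empty:
        weeks = records["week"].to_numpy()
        out = (weeks < first) | (weeks > last)
        if out.any():
            raise TransactionValidationError(
                f"weeks outside declared range {first}..{last}: "
                f"{sorted(set(weeks[out]))[:10]}"
            )
    if customer_list is not None:
        customers = [str(c) for c in customer_list]
        unknown = set(records["customer_id"].astype(str)) - set(customers)
        if unknown:
            raise TransactionValidationError(f"unknown customer ids {sorted(unknown)[:10]}")
    else:
        customers = list(pd.unique(records["customer_id"].astype(str)))
    if group_list is not None:
        groups = [str(g) for g in group_list]
        unknown = set(records["group"].astype(str)) - set(groups)
        if unknown:
            raise TransactionValidationError(
                f"group label(s) not in the declared group list: {sorted(unknown)[:10]}"
            )
    else:
        groups = sorted(set(records["group"].astype(str)))
    values = np.zeros((len(customers), max(len(groups), 0), t))
    if not records.empty and groups:
        c_codes = pd.Categorical(records["customer_id"].astype(str), categories=customers).codes
        g_codes = pd.Categorical(records["group"].astype(str), categories=groups).codes
        w_codes = records["week"].to_numpy() - first
        np.add.at(values, (c_codes, g_codes, w_codes), records["amount"].to_numpy())
    return PurchaseTensor(values, customers, groups, np.arange(first, last + 1))


def write_transactions(tensor: PurchaseTensor, path: str | Path) -> None:
    """Write the tensor as long-format delimited text, one row per nonzero cell.

    Floats are written with round-trip precision so write → read → assemble
    is the identity.
    """
    frame = tensor.to_long_frame(drop_zeros=True)
    frame["amount"] = [repr(float(a)) for a in frame["amount"]]
    frame.to_csv(path, index=False)


def write_tensor_dir(tensor: PurchaseTensor, directory: str | Path) -> None:
    """Write one p×t delimited matrix per customer plus a labels file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = {
        "customer_ids": tensor.customer_ids,
        "group_labels": tensor.group_labels,
        "week_labels": tensor.week_labels.tolist(),
    }
    (directory / "labels.json").write_text(json.dumps(labels, indent=1))
    for i, cid in enumerate(tensor.customer_ids):
        frame = pd.DataFrame(
            tensor.values[i], index=tensor.group_labels, columns=tensor.week_labels
        )
        frame.to_csv(directory / f"customer_{i:05d}.csv")


def read_tensor_dir(directory: str | Path) -> PurchaseTensor:
    directory = Path(directory)
    labels = json.loads((directory / "labels.json").read_text())
    slices = [
        pd.read_csv(directory / f"customer_{i:05d}.csv", index_col=0).to_numpy()
        for i in range(len(labels["customer_ids"]))
    ]
    return PurchaseTensor(
        np.stack(slices),
        labels["customer_ids"],
        labels["group_labels"],
        np.asarray(labels["week_labels"]),
    )
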