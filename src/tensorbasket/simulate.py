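"""Synthetic loyalty-card purchase tensors with known separable structure.

The generator draws customer slices from the bilinear latent model

    Y_i = M + A Z_i Bᵀ + E_i,

where ``A`` (p×p₀) and ``B`` (t×t₀) have orthonormal columns built from
interpretable templates (flat average, block contrasts, an annual
sinusoid), ``Z_i`` has independent zero-mean entries with user-chosen
standard deviations, ``M`` is a nonnegative population mean matrix and
``E_i`` is iid Gaussian noise.

Two modes are supported.  ``gaussian`` returns the model exactly (values
may be negative) so that recovery oracles hold to machine precision.
``expenditure`` adds the features of real loyalty-card data that break
exact separability: clamping at zero, per-group zero inflation (customers
who never buy tobacco/alcohol-like groups), a multiplicative holiday boost
on selected weeks of ``M`` and summer–winter seasonality in ``M``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tensor import PurchaseTensor, write_transactions

__all__ = [
    "DEFAULT_GROUP_LABELS",
    "SyntheticConfig",
    "SyntheticTruth",
    "InjectionSpec",
    "make_factor_bases",
    "simulate_tensor",
    "write_transactions_with_injection",
]

#: Canonical product groups used by the default generator.  The names mark
#: the blocks the factor templates contrast: ready-to-eat vs fresh produce,
#: a red-meat spike, and zero-inflated tobacco/alcohol-like groups.
DEFAULT_GROUP_LABELS = (
    "fresh vegetables",
    "fresh fruit",
    "ready-to-eat meals",
    "ready-to-eat snacks",
    "red meat",
    "poultry",
    "fish",
    "dairy",
    "bread",
    "beer",
    "cigarettes",
    "wine and cider",
)

_DEFAULT_ZERO_INFLATION = {"beer": 0.55, "cigarettes": 0.70, "wine and cider": 0.60}

#: Latent standard deviations for the default (3, 3) rank configuration,
#: assigned to (product-component, time-component) pairs in row-major
#: order; strongly decreasing so customer-level structure dominates cell
#: noise, as in real purchase data.
_DEFAULT_LATENT_SDS = (45.0, 30.0, 22.0, 16.0, 12.0, 9.0, 7.0, 5.0, 4.0)


def _default_zero_inflation(labels: Sequence[str]) -> tuple[float, ...]:
    return tuple(_DEFAULT_ZERO_INFLATION.get(g, 0.0) for g in labels)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a 52-week loyalty-card year."""

    n_customers: int = 500
    n_groups: int = 12
    n_weeks: int = 52
    true_ranks: tuple[int, int] = (3, 3)
    latent_sds: tuple[float, ...] = _DEFAULT_LATENT_SDS
    noise_sd: float = 1.0
    mean_matrix_scale: float = 2.0
    holiday_weeks: tuple[int, ...] = (12, 25, 51)
    holiday_boost: float = 0.25
    seasonal_amplitude: float = 0.15
    zero_inflation_prob: tuple[float, ...] | None = None
    mode: str = "expenditure"
    seed: int = 0
    group_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.group_labels is None and self.n_groups == len(DEFAULT_GROUP_LABELS):
            self.group_labels = DEFAULT_GROUP_LABELS
        if self.group_labels is not None:
            self.group_labels = tuple(self.group_labels)
            if len(self.group_labels) != self.n_groups:
                raise ValueError("group_labels length must equal n_groups")
        if self.zero_inflation_prob is None:
            labels = self.group_labels or tuple(f"group_{g:02d}" for g in range(self.n_groups))
            self.zero_inflation_prob = _default_zero_inflation(labels)
        self.zero_inflation_prob = tuple(float(z) for z in self.zero_inflation_prob)
        self.validate()

    def validate(self) -> None:
        p0, t0 = self.true_ranks
        if min(self.n_customers, self.n_groups, self.n_weeks) < 1:
            raise ValueError("dimensions must be positive")
        if not (1 <= p0 <= self.n_groups and 1 <= t0 <= self.n_weeks):
            raise ValueError(f"true_ranks {self.true_ranks} exceed dimensions")
        sds = np.asarray(self.latent_sds, dtype=float)
        if sds.size != p0 * t0:
            raise ValueError(f"latent_sds must have length p0*t0 = {p0 * t0}")
        if np.any(sds <= 0) or np.any(np.diff(sds) >= 0):
            raise ValueError("latent_sds must be strictly decreasing positives")
        if self.noise_sd < 0 or self.mean_matrix_scale < 0 or self.holiday_boost < 0:
            raise ValueError("noise_sd, mean_matrix_scale, holiday_boost must be >= 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if any(w < 1 or w > self.n_weeks for w in self.holiday_weeks):
            raise ValueError("holiday_weeks must lie in 1..n_weeks")
        if len(self.zero_inflation_prob) != self.n_groups:
            raise ValueError("zero_inflation_prob must have one entry per group")
        if any(z < 0 or z > 1 for z in self.zero_inflation_prob):
            raise ValueError("zero_inflation_prob entries must be in [0, 1]")
        if self.mode not in ("gaussian", "expenditure"):
            raise ValueError("mode must be 'gaussian' or 'expenditure'")


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a simulated tensor."""

    A: np.ndarray          # p×p0, orthonormal columns (product basis)
    B: np.ndarray          # t×t0, orthonormal columns (time basis)
    latent_sds: np.ndarray
    mean_matrix: np.ndarray  # p×t, the M actually used (nonnegative)
    Z: np.ndarray          # n×p0×t0 latent scores
    archetypes: np.ndarray  # per-customer index of the most amplified component

    def component_pair(self, flat_index: int) -> tuple[int, int]:
        """Map a row-major latent index to a 1-based (j1, j2) pair."""
        t0 = self.B.shape[1]
        return flat_index // t0 + 1, flat_index % t0 + 1


def _gram_schmidt_fill(templates: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormalize template columns in order, filling up to k columns
    with random directions; near-degenerate templates are replaced by
    random draws so the basis always has full column rank."""
    d = templates.shape[0]
    if k > d:
        raise ValueError(f"requested rank {k} exceeds dimension {d}")
    basis: list[np.ndarray] = []
    col = 0
    while len(basis) < k:
        if col < templates.shape[1]:
            v = templates[:, col].astype(float).copy()
            col += 1
        else:
            v = rng.standard_normal(d)
        for u in basis:
            v -= (u @ v) * u
        norm = np.linalg.norm(v)
        if norm < 1e-10 * max(1.0, d):
            continue  # template linearly dependent on earlier ones
        basis.append(v / norm)
    return np.column_stack(basis)


def make_factor_bases(
    p: int,
    t: int,
    p0: int,
    t0: int,
    seed: int = 0,
    *,
    fresh_block: Sequence[int] | None = None,
    ready_block: Sequence[int] | None = None,
    spike_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct orthonormal product and time bases from named templates.

    Time templates, in order: flat weekly average; first-half vs second-half
    contrast (spring vs autumn); one-cycle sinusoid ``cos(2π(w−1)/t)``
    (winter-peaked, i.e. summer vs winter); then random orthogonal fill.
    Product templates: flat positive average; ready-to-eat vs fresh block
    contrast; a single-group (red-meat-like) spike; then random fill.
    """
    if p0 > p or t0 > t:
        raise ValueError(f"ranks ({p0}, {t0}) exceed dimensions ({p}, {t})")
    if p0 < 1 or t0 < 1:
        raise ValueError("ranks must be at least 1")
    rng = np.random.default_rng(seed)
    if fresh_block is None:
        fresh_block = [0, 1] if p >= 4 else [0]
    if ready_block is None:
        ready_block = [2, 3] if p >= 4 else [min(1, p - 1)]
    if spike_index is None:
        spike_index = 4 if p >= 5 else p - 1

    prod = np.zeros((p, 3))
    prod[:, 0] = 1.0
    prod[list(ready_block), 1] = 1.0
    prod[list(fresh_block), 1] = -1.0
    prod[spike_index, 2] = 1.0

    weeks = np.arange(t)
    time = np.zeros((t, 3))
    time[:, 0] = 1.0
    time[: t // 2, 1] = 1.0
    time[t // 2:, 1] = -1.0
    time[:, 2] = np.cos(2 * np.pi * weeks / t)

    A = _gram_schmidt_fill(prod, p0, rng)
    B = _gram_schmidt_fill(time, t0, rng)
    return A, B


def _mean_matrix(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative population mean with per-group levels and seasonality."""
    p, t = config.n_groups, config.n_weeks
    levels = rng.uniform(0.4, 1.6, size=p)
    levels *= p / levels.sum()  # mean level 1 so the scale is interpretable
    season_sign = rng.uniform(-1.0, 1.0, size=p)
    weekly = 1.0 + config.seasonal_amplitude * np.outer(
        season_sign, np.cos(2 * np.pi * np.arange(t) / t)
    )
    M = config.mean_matrix_scale * levels[:, None] * weekly
    return np.clip(M, 0.0, None)


def simulate_tensor(config: SyntheticConfig) -> tuple[PurchaseTensor, SyntheticTruth]:
    """Draw a purchase tensor from the separable latent model.

    Returns the tensor together with a :class:`SyntheticTruth` recording
    the exact bases, latent scores and mean matrix used, so downstream
    estimators can be validated against ground truth.
    """
    config.validate()
    n, p, t = config.n_customers, config.n_groups, config.n_weeks
    p0, t0 = config.true_ranks
    root = np.random.SeedSequence(config.seed)
    s_bases, s_mean, s_latent, s_noise, s_mask = root.spawn(5)
    A, B = make_factor_bases(p, t, p0, t0, seed=s_bases)
    M = _mean_matrix(config, np.random.default_rng(s_mean))
    if config.mode == "expenditure" and config.holiday_weeks:
        M = M.copy()
        M[:, np.asarray(config.holiday_weeks) - 1] *= 1.0 + config.holiday_boost

    sds = np.asarray(config.latent_sds, dtype=float).reshape(p0, t0)  # row-major
    Z = np.random.default_rng(s_latent).standard_normal((n, p0, t0)) * sds
    X = M[None] + np.einsum("pj,ijk,tk->ipt", A, Z, B)
    if config.noise_sd > 0:
        X = X + np.random.default_rng(s_noise).normal(0.0, config.noise_sd, size=(n, p, t))

    if config.mode == "expenditure":
        X = np.clip(X, 0.0, None)
        zi = np.asarray(config.zero_inflation_prob)
        if np.any(zi > 0):
            mask = np.random.default_rng(s_mask).random((n, p)) < zi[None, :]
            X[mask] = 0.0

    # archetype: the latent component each customer expresses most strongly,
    # relative to its typical scale (row-major flat index)
    archetypes = np.argmax(np.abs(Z / sds).reshape(n, -1), axis=1)

    labels = list(config.group_labels) if config.group_labels else [
        f"group_{g:02d}" for g in range(p)
    ]
    width = max(4, len(str(n)))
    tensor = PurchaseTensor(
        X,
        [f"C{i + 1:0{width}d}" for i in range(n)],
        labels,
        np.arange(1, t + 1),
    )
    truth = SyntheticTruth(A, B, sds.ravel(), M, Z, archetypes)
    return tensor, truth


@dataclass
class InjectionSpec:
    """Synthetic customers that violate the cohort exclusion filters.

    ``n_absentee`` customers purchase in too few weeks (more than 8
    all-zero weeks); ``n_low_total`` purchase every week but spend less
    than €500 over the year.
    """

    n_absentee: int = 0
    n_low_total: int = 0
    absentee_zero_weeks: int = 10
    low_total_amount: float = 400.0


def write_transactions_with_injection(
    tensor: PurchaseTensor,
    path: str | Path,
    inject: InjectionSpec | None = None,
    manifest_path: str | Path | None = None,
) -> dict[str, list[str]]:
    """Write transactions, optionally appending excludable customers.

    Returns (and optionally writes) a manifest mapping criterion name to
    the injected customer ids, for exact-filter tests.
    """
    path = Path(path)
    frames = [tensor.to_long_frame(drop_zeros=True)]
    manifest: dict[str, list[str]] = {"absentee": [], "low_total": []}
    if inject is not None and (inject.n_absentee or inject.n_low_total):
        t = tensor.n_weeks
        group = tensor.group_labels[0]
        if inject.n_absentee:
            if inject.absentee_zero_weeks <= 8:
                raise ValueError("absentee customers need more than 8 zero weeks")
            active = tensor.week_labels[: t - inject.absentee_zero_weeks]
            if active.size == 0:
                raise ValueError("absentee_zero_weeks leaves no active weeks")
            amount = 600.0 / active.size  # keep them above the €500 filter
            for k in range(inject.n_absentee):
                cid = f"INJ_ABS_{k:04d}"
                manifest["absentee"].append(cid)
                frames.append(
                    pd.DataFrame(
                        {"customer_id": cid, "week": active, "group": group, "amount": amount}
                    )
                )
        if inject.n_low_total:
            if not inject.low_total_amount < 500.0:
                raise ValueError("low_total_amount must be below 500")
            amount = inject.low_total_amount / t  # active every week, low total
            for k in range(inject.n_low_total):
                cid = f"INJ_LOW_{k:04d}"
                manifest["low_total"].append(cid)
                frames.append(
                    pd.DataFrame(
                        {
                            "customer_id": cid,
                            "week": tensor.week_labels,
                            "group": group,
                            "amount": amount,
                        }
                    )
                )
    combined = pd.concat(frames, ignore_index=True)
    combined["amount"] = [repr(float(a)) for a in combined["amount"]]
    combined.to_csv(path, index=False)
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    return manifest
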