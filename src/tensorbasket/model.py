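"""Tensorial principal component analysis of purchase tensors.

The decomposition keeps the product-group and week dimensions separate.
After centering the customer slices Y_i (p×t) at the sample mean matrix
M, two modal covariance matrices are formed,

    S1 = (1/(n t)) Σ_i Yc_i Yc_iᵀ     (p×p, product groups)
    S2 = (1/(n p)) Σ_i Yc_iᵀ Yc_i     (t×t, weeks)

and eigendecomposed separately.  The leading p0 eigenvectors of S1 (U1,
product loadings) and t0 eigenvectors of S2 (U2, week loadings) define a
bilinear score matrix per customer,

    Z_i = U1ᵀ (Y_i − M) U2  ∈ R^(p0×t0),

one score per (product-component, time-component) pair.  Under the
separable latent model Y_i = M + A Z_i Bᵀ + E_i this recovers span(A) and
span(B).  Any positive constant in the covariance normalisation leaves
eigenvectors and explained-variance fractions unchanged; 1/(n·t) and
1/(n·p) make the two traces satisfy tr(S1)·t = tr(S2)·p.

Usage follows the fitted-model idiom::

    model = TensorPCA(tensor)
    res = model.fit(n_product_components=18, n_week_components=6)
    scores = res.project()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tensor import PurchaseTensor

__all__ = [
    "CenteredTensor",
    "ScoreArray",
    "TensorPCA",
    "TensorPCAResults",
    "center",
    "modal_covariance",
    "fit_tpca",
    "fix_signs",
]


@dataclass
class CenteredTensor:
    """Customer slices minus the sample mean matrix."""

    values: np.ndarray       # n×p×t, mean over customers of each cell is 0
    mean_matrix: np.ndarray  # p×t


@dataclass
class ScoreArray:
    """Per-customer bilinear principal-component matrices.

    ``scores[i, j1-1, j2-1]`` is customer i's score on the pair of the
    j1-th product component and the j2-th time component.
    """

    scores: np.ndarray  # n×p0×t0
    customer_ids: list[str]

    @property
    def n_product_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_week_components(self) -> int:
        return self.scores.shape[2]

    def pair(self, j1: int, j2: int) -> np.ndarray:
        """Score vector over customers for the 1-based pair (j1, j2)."""
        p0, t0 = self.scores.shape[1:]
        if not (1 <= j1 <= p0 and 1 <= j2 <= t0):
            raise ValueError(f"pair ({j1}, {j2}) outside fitted ranks ({p0}, {t0})")
        return self.scores[:, j1 - 1, j2 - 1]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (customer_id, j1, j2, score)."""
        n, p0, t0 = self.scores.shape
        ci, j1, j2 = np.unravel_index(np.arange(n * p0 * t0), (n, p0, t0))
        return pd.DataFrame(
            {
                "customer_id": np.asarray(self.customer_ids, dtype=object)[ci],
                "j1": j1 + 1,
                "j2": j2 + 1,
                "score": self.scores.ravel(),
            }
        )


def center(tensor: PurchaseTensor | np.ndarray) -> CenteredTensor:
    """Subtract the elementwise mean slice over customers."""
    values = tensor.values if isinstance(tensor, PurchaseTensor) else np.asarray(tensor, float)
    if values.shape[0] < 2:
        raise ValueError("centering needs at least 2 customers")
    M = values.mean(axis=0)
    return CenteredTensor(values - M[None], M)


def modal_covariance(centered: CenteredTensor | np.ndarray, mode: int) -> np.ndarray:
    """Modal covariance matrix of the centered tensor.

    Mode 1 aggregates over weeks to measure linear dependency among
    product groups; mode 2 aggregates over groups for the weeks.
    """
    values = centered.values if isinstance(centered, CenteredTensor) else np.asarray(centered)
    n, p, t = values.shape
    if mode == 1:
        S = np.einsum("ipt,iqt->pq", values, values) / (n * t)
    elif mode == 2:
        S = np.einsum("ipt,ips->ts", values, values) / (n * p)
    else:
        raise ValueError("mode must be 1 (product groups) or 2 (weeks)")
    return (S + S.T) / 2.0  # symmetrize against roundoff


def fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign ambiguity deterministically.

    For each column the entry of largest absolute value (ties → lowest
    index, via argmax) is made positive, so loadings are reproducible
    across runs and linear-algebra backends.
    """
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _eig_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    return lam[order], fix_signs(vec[:, order])


class TensorPCA:
    """Tensorial PCA model for a labelled purchase tensor.

    Parameters
    ----------
    tensor : PurchaseTensor
        Data with at least two customers.

    Notes
    -----
    Construction computes the mean matrix, both modal covariances and
    their full eigendecompositions once; :meth:`fit` then selects the
    numbers of components per mode.
    """

    def __init__(self, tensor: PurchaseTensor):
        if tensor.n_customers < 2:
            raise ValueError("tensorial PCA needs at least 2 customers")
        self.tensor = tensor
        self.centered = center(tensor)
        self.S1 = modal_covariance(self.centered, mode=1)
        self.S2 = modal_covariance(self.centered, mode=2)
        self._lam1, self._vec1 = _eig_descending(self.S1)
        self._lam2, self._vec2 = _eig_descending(self.S2)

    @classmethod
    def from_transactions(
        cls,
        path: str | Path,
        week_range: tuple[int, int],
        group_list: Sequence[str] | None = None,
    ) -> "TensorPCA":
        from .tensor import assemble_tensor, read_transactions

        return cls(assemble_tensor(read_transactions(path), week_range, group_list))

    def fit(self, n_product_components: int, n_week_components: int) -> "TensorPCAResults":
        """Select the leading components per mode and return the results."""
        p, t = self.tensor.n_groups, self.tensor.n_weeks
        p0, t0 = int(n_product_components), int(n_week_components)
        if not (1 <= p0 <= p):
            raise ValueError(f"n_product_components must be in 1..{p}, got {p0}")
        if not (1 <= t0 <= t):
            raise ValueError(f"n_week_components must be in 1..{t}, got {t0}")
        return TensorPCAResults(self, p0, t0)


class TensorPCAResults:
    """Fitted tensorial PCA: loadings, spectra and bilinear projections."""

    def __init__(self, model: TensorPCA, p0: int, t0: int):
        self.model = model
        self.n_product_components = p0
        self.n_week_components = t0
        self.mean_matrix = model.centered.mean_matrix
        self.U1 = model._vec1[:, :p0]
        self.U2 = model._vec2[:, :t0]
        self.eigenvalues_products = model._lam1
        self.eigenvalues_weeks = model._lam2

    # -- spectra ---------------------------------------------------------
    @property
    def explained_variance_products(self) -> float:
        lam = np.clip(self.eigenvalues_products, 0.0, None)
        return float(lam[: self.n_product_components].sum() / lam.sum())

    @property
    def explained_variance_weeks(self) -> float:
        lam = np.clip(self.eigenvalues_weeks, 0.0, None)
        return float(lam[: self.n_week_components].sum() / lam.sum())

    @property
    def loadings_products(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.U1,
            index=self.model.tensor.group_labels,
            columns=[f"PC{j + 1}" for j in range(self.n_product_components)],
        )

    @property
    def loadings_weeks(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.U2,
            index=self.model.tensor.week_labels,
            columns=[f"PC{j + 1}" for j in range(self.n_week_components)],
        )

    # -- projections -----------------------------------------------------
    def project(self, tensor: PurchaseTensor | None = None) -> ScoreArray:
        """Bilinear scores Z_i = U1ᵀ (Y_i − M) U2 for every customer."""
        if tensor is None:
            tensor = self.model.tensor
        else:
            if tensor.group_labels != self.model.tensor.group_labels or not np.array_equal(
                tensor.week_labels, self.model.tensor.week_labels
            ):
                raise ValueError("tensor labels do not match the fitted model")
        Yc = tensor.values - self.mean_matrix[None]
        Z = np.einsum("pj,ipt,tk->ijk", self.U1, Yc, self.U2)
        return ScoreArray(Z, list(tensor.customer_ids))

    def reconstruct(self, scores: ScoreArray) -> np.ndarray:
        """Rank-(p0, t0) approximation M + U1 Z_i U2ᵀ of each slice."""
        Z = scores.scores
        if Z.shape[1:] != (self.n_product_components, self.n_week_components):
            raise ValueError("score dimensions do not match the fitted ranks")
        return self.mean_matrix[None] + np.einsum("pj,ijk,tk->ipt", self.U1, Z, self.U2)

    # -- reporting -------------------------------------------------------
    def spectra_dict(self) -> dict:
        return {
            "eigenvalues_products": self.eigenvalues_products.tolist(),
            "eigenvalues_weeks": self.eigenvalues_weeks.tolist(),
            "n_product_components": self.n_product_components,
            "n_week_components": self.n_week_components,
            "explained_variance_products": self.explained_variance_products,
            "explained_variance_weeks": self.explained_variance_weeks,
        }

    def summary(self) -> str:
        tns = self.model.tensor
        lines = [
            "Tensorial PCA results",
            "=" * 54,
            f"customers: {tns.n_customers}   product groups: {tns.n_groups}   "
            f"weeks: {tns.n_weeks}",
            f"components: {self.n_product_components} (products) x "
            f"{self.n_week_components} (weeks)",
            f"explained variance, product mode: "
            f"{100 * self.explained_variance_products:.1f}%",
            f"explained variance, week mode:    "
            f"{100 * self.explained_variance_weeks:.1f}%",
            "-" * 54,
            "leading product eigenvalues: "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues_products[:5]),
            "leading week eigenvalues:    "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues_weeks[:5]),
        ]
        return "\n".join(lines)


def fit_tpca(tensor: PurchaseTensor, p0: int, t0: int) -> TensorPCAResults:
    """One-call convenience wrapper: ``TensorPCA(tensor).fit(p0, t0)``."""
    return TensorPCA(tensor).fit(p0, t0)
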