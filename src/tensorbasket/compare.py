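"""Standard PCA on matricized tensors, compared against tensorial PCA.

A 3-way purchase tensor can be flattened for ordinary PCA in three ways:
summing over weeks (n×p product-group totals), summing over groups (n×t
weekly totals), or vectorizing each p×t slice into a length-p·t row by
stacking its columns (week-major order).  Each flattening can expose some
of the structure — product patterns, time patterns, or both mixed — and
this module quantifies what survives, including the correlation between
the first standard-PCA scores and the tensorial (1,1) pair scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ScoreArray, fix_signs
from .tensor import PurchaseTensor

__all__ = [
    "MatricizedData",
    "PCAResult",
    "matricize",
    "standard_pca",
    "score_correlation",
    "comparison_report",
]

SCHEMES = ("sum_over_weeks", "sum_over_groups", "vectorized")


@dataclass
class MatricizedData:
    """A customer-by-feature flattening of the purchase tensor."""

    scheme: str
    matrix: pd.DataFrame  # rows = customers

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PCAResult:
    """Ordinary PCA of column-centered matricized data."""

    scheme: str
    loadings: np.ndarray        # d×k, orthonormal sign-fixed columns
    scores: np.ndarray          # n×k
    eigenvalues: np.ndarray     # full spectrum, descending
    feature_labels: list

    @property
    def explained_variance(self) -> np.ndarray:
        lam = np.clip(self.eigenvalues, 0.0, None)
        return lam / lam.sum()


def matricize(tensor: PurchaseTensor, scheme: str) -> MatricizedData:
    """Flatten the tensor into a customer-by-feature matrix.

    ``vectorized`` columns are week-major — feature (w, g) sits at column
    w·p + g — matching the column-stacking vec() of each p×t slice, so
    Kronecker identities against the modal eigenvectors hold without
    permutation.
    """
    if scheme == "sum_over_weeks":
        frame = pd.DataFrame(
            tensor.values.sum(axis=2), index=tensor.customer_ids, columns=tensor.group_labels
        )
    elif scheme == "sum_over_groups":
        frame = pd.DataFrame(
            tensor.values.sum(axis=1), index=tensor.customer_ids, columns=tensor.week_labels
        )
    elif scheme == "vectorized":
        n, p, t = tensor.shape
        flat = tensor.values.transpose(0, 2, 1).reshape(n, t * p)  # week-major
        cols = pd.MultiIndex.from_product(
            [tensor.week_labels, tensor.group_labels], names=["week", "group"]
        )
        frame = pd.DataFrame(flat, index=tensor.customer_ids, columns=cols)
    else:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    return MatricizedData(scheme, frame)


def standard_pca(data: MatricizedData, k: int) -> PCAResult:
    """PCA via eigendecomposition of the sample covariance (1/n).

    Columns are centered; scores are the centered data projected on the
    leading k eigenvectors, with the same deterministic sign convention
    as the tensorial decomposition.
    """
    X = data.matrix.to_numpy(dtype=float)
    n, d = X.shape
    if not (1 <= k <= d):
        raise ValueError(f"k must be in 1..{d}")
    if n < 2:
        raise ValueError("need at least 2 customers")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    lam, vec = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], fix_signs(vec[:, order])
    return PCAResult(
        scheme=data.scheme,
        loadings=vec[:, :k],
        scores=Xc @ vec[:, :k],
        eigenvalues=lam,
        feature_labels=list(data.matrix.columns),
    )


def score_correlation(
    tpca_scores: ScoreArray,
    pca_result: PCAResult,
    pair: tuple[int, int] = (1, 1),
    component: int = 1,
) -> tuple[float, float]:
    """Pearson correlation between a tensorial pair score and a PCA score.

    Returns ``(r, |r|)``; the absolute value is reported alongside because
    loading signs are a convention, not a finding.
    """
    x = tpca_scores.pair(*pair)
    y = pca_result.scores[:, component - 1]
    if x.size != y.size:
        raise ValueError("score vectors have different lengths")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance scores have no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, abs(r)


def _subspace_overlap(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared cosine of principal angles between two column spans."""
    Qe, _ = np.linalg.qr(estimated)
    Qt, _ = np.linalg.qr(truth)
    sv = np.linalg.svd(Qe.T @ Qt, compute_uv=False)
    return float(np.mean(sv**2))


def comparison_report(
    tensor: PurchaseTensor,
    tpca_results,
    truth=None,
    k: int = 3,
    overlap_threshold: float = 0.7,
) -> dict:
    """Run all three matricized PCAs and summarize what each can detect.

    Reports per-scheme explained variances and the correlation of the
    first component's scores with the tensorial (1,1) scores.  When the
    generating bases are known (``truth``), adds qualitative booleans:
    whether the scheme's leading loadings overlap the true product basis
    span, the true time basis span, or (vectorized only) their Kronecker
    products — automating the can-it-find-product/time-patterns reading
    of the flattening comparison.
    """
    scores_t = tpca_results.project(tensor)
    report: dict = {"schemes": {}}
    for scheme in SCHEMES:
        data = matricize(tensor, scheme)
        kk = min(k, data.n_features)
        res = standard_pca(data, kk)
        r, abs_r = score_correlation(scores_t, res, pair=(1, 1), component=1)
        entry = {
            "n_features": data.n_features,
            "explained_variance_first": float(res.explained_variance[0]),
            "corr_with_tpca_11": r,
            "abs_corr_with_tpca_11": abs_r,
        }
        if truth is not None:
            A, B = truth.A, truth.B
            if scheme == "sum_over_weeks":
                entry["finds_product_patterns"] = bool(
                    _subspace_overlap(res.loadings[:, : A.shape[1]], A) > overlap_threshold
                )
                entry["finds_time_patterns"] = False
            elif scheme == "sum_over_groups":
                entry["finds_product_patterns"] = False
                entry["finds_time_patterns"] = bool(
                    _subspace_overlap(res.loadings[:, : B.shape[1]], B) > overlap_threshold
                )
            else:
                kron = np.column_stack(
                    [np.kron(B[:, j2], A[:, j1])
                     for j1 in range(A.shape[1]) for j2 in range(B.shape[1])]
                )
                m = min(res.loadings.shape[1], kron.shape[1])
                entry["finds_joint_patterns"] = bool(
                    _subspace_overlap(res.loadings[:, :m], kron) > overlap_threshold
                )
        report["schemes"][scheme] = entry
    report["tensorial"] = {
        "explained_variance_products": tpca_results.explained_variance_products,
        "explained_variance_weeks": tpca_results.explained_variance_weeks,
    }
    return report
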