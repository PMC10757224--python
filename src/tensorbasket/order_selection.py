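"""Augmentation (ladle-type) estimation of the number of components.

For each mode the data tensor is augmented with pure-noise coordinates:
every centered slice gets ``r`` extra rows (product mode) or columns
(week mode) of iid Gaussian noise whose scale matches the trailing
eigenvalues of that mode's modal covariance.  Informative eigenvectors of
the augmented covariance stay essentially out of the noise block, while
noise eigenvectors leak into it; averaging the leaked mass over replicates
gives a variation curve f̃ that is small up to the true rank and grows
beyond it.  Adding the normalised scree curve φ (which decays until the
true rank) yields the criterion

    g(k) = f̃_k + φ_k,   k = 0..K_max,

whose argmin estimates the rank.  Ties resolve toward smaller k
(parsimony); φ uses the original spectrum so the eigenvalue term is
deterministic given the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np

from .model import center, modal_covariance
from .tensor import PurchaseTensor

__all__ = ["OrderSelectionResult", "OrderSelection", "augmentation_order", "select_orders", "scree_elbow"]


@dataclass
class OrderSelectionResult:
    """Criterion curve and chosen rank for one mode."""

    mode: int                  # 1 = product groups, 2 = weeks
    k_hat: int
    criterion: np.ndarray      # g(k), k = 0..K_max
    eigen_term: np.ndarray     # φ_k
    variation_term: np.ndarray  # f̃_k, with f̃_0 = 0
    replicates: int
    augmentation_size: int
    noise_scale: float         # σ̂ used for the augmented coordinates
    seed: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k_hat": self.k_hat,
            "criterion": self.criterion.tolist(),
            "eigen_term": self.eigen_term.tolist(),
            "variation_term": self.variation_term.tolist(),
            "replicates": self.replicates,
            "augmentation_size": self.augmentation_size,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class OrderSelection:
    """Chosen ranks for both modes with their criterion curves."""

    n_product_components: int
    n_week_components: int
    product_result: OrderSelectionResult
    week_result: OrderSelectionResult


def augmentation_order(
    tensor: PurchaseTensor,
    mode: int,
    r: int | None = None,
    n_replicates: int = 50,
    k_max: int | None = None,
    seed: int = 0,
    weight: float = 1.0,
) -> OrderSelectionResult:
    """Estimate the rank of one mode by noise augmentation.

    Parameters
    ----------
    mode : {1, 2}
        1 selects product components, 2 week components.
    r : int, optional
        Number of augmented noise coordinates; default ``max(1, ⌈d/5⌉)``
        where d is the mode dimension.
    n_replicates : int
        Independent augmentations averaged into the variation curve.
    k_max : int, optional
        Largest candidate rank; default ``min(d − 1, 30)``.
    weight : float
        Weight of the variation term relative to the eigenvalue term in
        ``g(k) = weight·f̃_k + φ_k``.
    """
    if mode not in (1, 2):
        raise ValueError("mode must be 1 or 2")
    if n_replicates < 2:
        raise ValueError("need at least 2 augmentation replicates")
    centered = center(tensor)
    values = centered.values
    if not np.any(values):
        raise ValueError("degenerate all-zero (constant) tensor")
    n, p, t = values.shape
    d = p if mode == 1 else t
    if r is None:
        r = max(1, ceil(d / 5))
    if k_max is None:
        k_max = min(d - 1, 30)
    if not (0 < k_max < d):
        raise ValueError(f"k_max must be in 1..{d - 1}")

    S = modal_covariance(centered, mode)
    lam = np.sort(np.linalg.eigvalsh(S))[::-1]
    # noise scale from the flat tail of the spectrum
    sigma2 = float(np.mean(lam[-ceil(d / 2):]))
    sigma = float(np.sqrt(max(sigma2, 0.0)))

    other = t if mode == 1 else p
    rng = np.random.default_rng(seed)
    f = np.zeros(k_max + 1)
    for _ in range(n_replicates):
        noise = rng.normal(0.0, sigma if sigma > 0 else 1.0, size=(n, r, other))
        if mode == 1:
            aug = np.concatenate([values, noise], axis=1)           # rows
            S_aug = np.einsum("ipt,iqt->pq", aug, aug) / (n * t)
        else:
            aug = np.concatenate([values, noise.transpose(0, 2, 1)], axis=2)  # columns
            S_aug = np.einsum("ipt,ips->ts", aug, aug) / (n * p)
        lam_aug, vec_aug = np.linalg.eigh((S_aug + S_aug.T) / 2.0)
        vec_aug = vec_aug[:, np.argsort(lam_aug)[::-1]]
        leak = np.sum(vec_aug[d:, : k_max] ** 2, axis=0)  # ‖noise block‖² per eigvec
        f[1:] += np.cumsum(leak)
    f /= n_replicates
    f[0] = 0.0
    f_tilde = f / (1.0 + f.sum())

    total = lam[: k_max + 1].sum()
    phi = lam[: k_max + 1] / total  # φ_k = λ_{k+1}/Σ_{j≤K_max+1} λ_j, k = 0..K_max
    g = weight * f_tilde + phi
    k_hat = int(np.argmin(g))  # argmin takes the smallest index on ties
    return OrderSelectionResult(
        mode=mode,
        k_hat=k_hat,
        criterion=g,
        eigen_term=phi,
        variation_term=f_tilde,
        replicates=n_replicates,
        augmentation_size=r,
        noise_scale=sigma,
        seed=seed,
    )


def select_orders(
    tensor: PurchaseTensor,
    r: int | None = None,
    n_replicates: int = 50,
    k_max: int | None = None,
    seed: int = 0,
    weight: float = 1.0,
) -> OrderSelection:
    """Run the augmentation estimator for both modes.

    The two modes use independent noise streams split from ``seed``.
    """
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    res1 = augmentation_order(
        tensor, 1, r, n_replicates, k_max, int(np.random.default_rng(s1).integers(2**31)), weight
    )
    res2 = augmentation_order(
        tensor, 2, r, n_replicates, k_max, int(np.random.default_rng(s2).integers(2**31)), weight
    )
    return OrderSelection(res1.k_hat, res2.k_hat, res1, res2)


def scree_elbow(eigenvalues: np.ndarray, k_max: int | None = None) -> int:
    """Fallback rank estimate: the largest consecutive-ratio drop.

    Returns the k maximising λ_k/λ_{k+1} over 1 ≤ k ≤ K_max.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = np.clip(lam, np.finfo(float).tiny, None)
    if k_max is None:
        k_max = lam.size - 1
    ratios = lam[:k_max] / lam[1 : k_max + 1]
    return int(np.argmax(ratios)) + 1
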