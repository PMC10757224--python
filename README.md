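# tensorbasket

Tensorial principal component analysis for longitudinal grocery-purchase
data, written for nutrition and public-health researchers who work with
loyalty-card expenditure records.

A year of purchase history for a cohort is naturally a 3-way array
**X** ∈ ℝ^(n×p×t): *n* customers, *p* product groups, *t* weeks. Ordinary
PCA forces a choice — aggregate away the weeks, aggregate away the
groups, or vectorize each customer's p×t matrix into a huge, barely
interpretable loading vector. Tensorial PCA (higher-order SVD, also known
as 2-directional 2D PCA) keeps the two dimensions separate and reduces
them simultaneously.

## The decomposition

Center the customer slices **Y**ᵢ ∈ ℝ^(p×t) at the sample mean matrix
**M**, then form two *modal covariance matrices*

    S₁ = (1/nt) Σᵢ (Yᵢ − M)(Yᵢ − M)ᵀ      (p×p, product groups)
    S₂ = (1/np) Σᵢ (Yᵢ − M)ᵀ(Yᵢ − M)      (t×t, weeks)

S₁ measures dependency among product groups aggregating over time; S₂
the reverse. The leading p₀ eigenvectors **U₁** of S₁ and t₀ eigenvectors
**U₂** of S₂ give every customer a small bilinear score matrix

    Zᵢ = U₁ᵀ (Yᵢ − M) U₂  ∈ ℝ^(p₀×t₀),

one score per (product-component, time-component) pair — e.g. "ready-to-eat
foods × summer-vs-winter". The model assumption is the separable latent
structure **Y**ᵢ = **A Z**ᵢ **B**ᵀ with orthogonal **A**, **B** and
uncorrelated latent components, which the decomposition recovers.

The number of components per mode is chosen by an augmentation
(ladle-type) estimator: append pure-noise coordinates to a mode, measure
how much the leading eigenvectors leak into the noise block across
replicates, and minimise the combined eigenvalue + leakage criterion.

Around the core decomposition the package provides the full analysis
pipeline: transaction ingest, cohort exclusion filters (more than 8
empty weeks, or annual total under €500), rescaling of every customer to
a €1000 annual budget, peeling of atypical weeks/product groups
(|loading| > 0.3) before a refit, high/typical/low (10/80/10) score
stratification, decile trajectories, standardized group profiles,
correlation-distance clustering for heat maps, and a comparison against
standard PCA on the three flattenings of the tensor. A synthetic
loyalty-card generator with known ground truth (holiday spikes,
seasonality, zero-inflated tobacco/alcohol groups) makes every stage
testable without access to proprietary retail data.

## Worked example

```python
from tensorbasket import (SyntheticConfig, simulate_tensor, apply_exclusions,
                          rescale_annual, TensorPCA, select_orders,
                          weekly_share, stratify)

config = SyntheticConfig(n_customers=500, seed=1)   # a 500×12×52 synthetic year
tensor, truth = simulate_tensor(config)
kept, report = apply_exclusions(tensor)             # >8 empty weeks or < €500
scaled = rescale_annual(kept)                       # everyone sums to €1000
print(f"cohort after filters: {report.n_initial} -> {report.n_final}")
print(f"week 51 share: {weekly_share(scaled)[51]:.1f}%")

sel = select_orders(scaled, seed=1)                 # augmentation estimator
res = TensorPCA(scaled).fit(sel.n_product_components, sel.n_week_components)
print(res.summary())
print(stratify(res.project(), pair=(1, 1), q=0.10).counts())
```

Output:

```
cohort after filters: 500 -> 411
week 51 share: 2.4%
Tensorial PCA results
======================================================
customers: 411   product groups: 12   weeks: 52
components: 8 (products) x 5 (weeks)
explained variance, product mode: 90.7%
explained variance, week mode:    77.5%
------------------------------------------------------
leading product eigenvalues: 9.825, 4.616, 2.008, 1.695, 1.105
leading week eigenvalues:    34.81, 23.91, 19.67, 1.687, 0.7848
{'high': 41, 'typical': 329, 'low': 41}
```

89 of the 500 simulated customers fail the regular-shopper filters
(zero-inflated groups and clamping produce absentee-like records), the
pre-Christmas week carries 2.4% of yearly spending against the uniform
1.9%, and the augmentation estimator keeps 8 product and 5 week
components before the per-pair scores stratify the cohort 10/80/10.

The same analysis runs from the shell:

```sh
tensorbasket run --seed 1 --out bundle/        # full pipeline, all artifacts
tensorbasket simulate --seed 1 --out tx.csv    # synthetic transactions only
tensorbasket fit tx.csv --ranks 3 3            # tensorial PCA on a file
```

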