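# Methods

## Model

Each customer's year of purchases is a matrix **Y**ᵢ ∈ ℝ^(p×t)
(product groups × weeks). The working model is a separable bilinear
latent structure

    Yᵢ = M + A Zᵢ Bᵀ + Eᵢ,

with a population mean matrix **M**, orthonormal-column bases
**A** (p×p₀) and **B** (t×t₀), a latent score matrix **Z**ᵢ with
independent zero-mean entries of decreasing standard deviation, and iid
Gaussian cell noise **E**ᵢ. Under this model the modal covariances

    S₁ = (1/nt) Σ Yᶜᵢ Yᶜᵢᵀ,   S₂ = (1/np) Σ Yᶜᵢᵀ Yᶜᵢ   (Yᶜᵢ = Yᵢ − M̂)

have leading eigenspaces spanning col(A) and col(B), so the fitted
loadings U₁, U₂ recover the bases and the projections
Zᵢ = U₁ᵀ Yᶜᵢ U₂ recover the latent scores. The normalisation constants
1/(nt) and 1/(np) are a convention — any positive constant leaves
eigenvectors and explained-variance fractions unchanged — chosen so
that tr(S₁)·t = tr(S₂)·p (both equal the total centered sum of squares
per customer), which the tests use as an internal consistency check.

Eigenvector signs are fixed deterministically: in each column the entry
of largest absolute value (ties broken toward the lowest index) is made
positive. Loading signs only encode direction, so this is presentation,
but it makes runs reproducible across linear-algebra backends. Within a
degenerate (tied) eigenvalue block the backend's vector order is kept;
tests compare subspaces, not individual vectors, in that case.

## Rank selection by augmentation

The augmentation (ladle-type) estimator chooses p₀ and t₀ per mode:

1. Estimate the noise scale σ̂² as the mean of the smallest ⌈d/2⌉
   eigenvalues of the mode's modal covariance (d = mode dimension),
   i.e. from the flat tail of the scree curve.
2. For each of M replicates, append r rows (product mode) or columns
   (week mode) of iid N(0, σ̂²) noise to every centered slice and
   eigendecompose the augmented modal covariance.
3. fₖ = the mass of the first k eigenvectors inside the appended noise
   block, averaged over replicates, with f₀ = 0; normalised to
   f̃ₖ = fₖ / (1 + Σₖ' fₖ').
4. φₖ = λₖ₊₁ / Σⱼ₌₁^(K+1) λⱼ from the original (non-augmented) spectrum,
   so the eigenvalue term is deterministic given the data.
5. ĝ(k) = f̃ₖ + φₖ; k̂ = argmin, ties resolved toward smaller k
   (parsimony).

Informative eigenvectors stay out of the noise block (f̃ small up to the
true rank); noise eigenvectors leak into it (f̃ grows past it); φ decays
until the true rank. Defaults r = max(1, ⌈d/5⌉), M = 50,
K_max = min(d − 1, 30). The two terms are equally weighted by default;
the weight is exposed as a parameter. The estimator is scale-equivariant
because σ̂ scales with the data. A consequence of using σ̂ from the tail
eigenvalues is that the criterion needs the trailing spectrum to be
approximately flat — strongly heteroscedastic noise would bias σ̂ upward
and push k̂ down.

A scree fallback (`scree_elbow`, largest consecutive eigenvalue ratio)
is provided for cross-checking; no information-criterion or
parallel-analysis variants are implemented.

## Preprocessing conventions

- **Exclusions.** A customer is dropped with strictly more than 8
  all-zero weeks (of 52) or an annual total strictly below €500; both
  read literally, so exactly 8 zero weeks and exactly €500.00 are
  retained. Boundary totals are compared with a 1e-9 absolute tolerance
  because rescaled floats can sit at the threshold. User-listed ids
  (e.g. staff cards) are removed before the numeric criteria.
- **Rescaling.** After exclusions every customer is scaled so the annual
  total is exactly €1000, making cells read as "euros out of 1000" and
  giving all customers equal weight regardless of household size.
- **Peeling.** Removing atypical weeks/groups does *not* re-normalise
  totals; the peeled tensor keeps the already-scaled values, so customer
  totals drop below 1000 by the amount spent on removed slices.
- **Weeks** are 1-based 1..52; no ISO-week-53 handling — the year is
  modelled as exactly 52 weeks.
- **Row z-scores** (for descriptive heat maps) use the population
  standard deviation (denominator t); constant rows map to all-zeros.
- **Atypicality flags** use |loading| > 0.3 in any of the leading
  components of a first-pass fit on the unpeeled tensor; the pipeline
  then peels and refits. The 0.3 default is calibrated to wide tensors
  (p of several dozen, where a typical loading is ~1/√p); on narrow
  synthetic tensors (p ≈ 12) it flags liberally, and the pipeline
  accepts explicit peel lists for that reason.
- **Stratification/deciles** are rank-based with ties broken by stable
  customer order (ties do occur in zero-inflated data); high and low
  groups have exactly ⌊qn⌋ members; decile sizes differ by at most one
  with the larger deciles at the lowest ranks. Both are invariant under
  strictly increasing transforms of the scores.
- **Weekly trajectory percentages** exclude a customer's zero-total
  weeks rather than counting them as 0% — a customer absent that week
  expresses no purchase composition.
- **Clustering** of loadings uses correlation distance (1 − Pearson)
  with average linkage; constant rows are assigned the maximal distance
  1 to everything.
- **Vectorization** stacks slice columns (week-major), and the
  vectorized matricization uses the same order, so Kronecker identities
  between vectorized-PCA eigenvectors and the modal bases hold without
  permutation.

## Synthetic data generator

The generator emulates a loyalty-card year at the scale used throughout
the tests: by default 52 weeks and 12 named product groups, with factor
templates that mirror interpretable purchase patterns — a flat weekly
average, a first-half/second-half (spring-vs-autumn) contrast and a
one-cycle annual sinusoid (summer-vs-winter) in the time basis; a flat
average, a ready-to-eat-vs-fresh block contrast and a red-meat spike in
the product basis; remaining columns are random orthogonal fill.
Templates are orthonormalized in order by Gram–Schmidt.

Defaults, chosen as plausible study conditions: holiday weeks 12, 25
and 51 with a multiplicative mean boost of 0.25 (Christmas-week spending
in real data runs ~25% above an average week); seasonal amplitude 0.15;
per-cell mean scale 2.0 (raw annual totals ≈ €1250, comfortably above
the €500 filter); zero-inflation probabilities 0.55/0.70/0.60 for the
beer/cigarettes/wine-like groups and 0 elsewhere; latent standard
deviations (45, 30, 22, 16, 12, 9, 7, 5, 4) for ranks (3, 3), assigned
to (product-component, time-component) pairs in **row-major order** —
documented so recovery tests are unambiguous.

Two modes:

- `gaussian` returns M + A Zᵢ Bᵀ + Eᵢ exactly (values may be negative).
  Exact-recovery oracles run here: noiseless generation is separable to
  machine precision and fitted subspaces match the truth to ~1e-15.
- `expenditure` clamps at zero, masks whole customer×group rows with the
  group's zero-inflation probability, and applies the holiday boost to
  the mean matrix. This is realistic but deliberately breaks exact
  separability — clamping truncates asymmetrically and masking mixes
  modes — so pipeline-realism tests run here with directional or
  tolerance-based assertions rather than exact ones.

The holiday effect lives in the mean matrix (a population-level atypical
week) rather than in per-customer scores. It still becomes visible to
the covariance-based loadings because the €1000 rescaling multiplies
each customer by a different factor, coupling the population spike into
customer-level variance at the holiday columns; the holiday-flagging
test uses a pronounced boost (0.5) where this coupling is strong.

What the generator does **not** emulate: any real retailer's marginals, prices
or inflation, household composition, within-week purchase timing, or
non-Gaussian noise. The noise distribution of real purchase data is
uncharacterised; Gaussian-plus-clamp is a stand-in. Passing tests
therefore demonstrate correctness of the estimators under the separable
model and robustness to clamp/mask distortions at moderate strength, not
fidelity to any particular retailer's data.

## Test-design notes

Stochastic tests fix their seeds and were sized by power reasoning
before freezing: subspace-recovery checks use n ∈ {100, 500, 2000}
(error ∝ 1/√n gives clear monotone separation); rank-recovery checks
use n = 500 with an eigengap at least 4× the unit noise floor; the
mirror-profile check (high vs low groups of a block-seasonal component
pair are near-negatives, cosine ≤ −0.8) uses comparable-scale latent
components at n = 1000, because with the strongly decreasing default
spectrum the sampling noise of the dominant components in a 100-member
group mean masks the weakest pair. The seasonal-trajectory check derives
its expected direction from the fitted loading signs instead of assuming
an orientation, since the sign convention, not the data, decides which
end of a contrast is "positive".

## Pipeline and reproducibility

`run_pipeline` executes ingest → exclusions → rescale → first fit →
atypicality flags → peel → rank selection → refit → scores →
stratification/deciles/profiles/trajectories → flattened-PCA comparison,
writing every artifact plus a manifest with stage-by-stage dimensions.
All randomness derives from one root seed split per stage; a fixed seed
reproduces every numeric artifact byte for byte. Configuration is a
validated YAML/JSON file mirrored by CLI flags; exactly one of an input
transaction file or a synthetic block must be present.

`scripts/acceptance.py` re-runs the main computations on freshly
generated data at the sizes above (cohorts of 150–2000 customers, 20
replicates for the rank-recovery rates) and reports the measured
quantities; nothing in its output is hard-coded.

## Known limitations

- Dense in-memory tensors only; a 7251×55×52 cohort is a ~160 MB array,
  fine on a workstation, but there is no out-of-core path.
- No missing-data handling: absence of a transaction means zero
  expenditure by construction, not missingness.
- No sparse, robust or functional PCA variants; heavy-tailed cells
  (e.g. a single €900 purchase) influence loadings quadratically.
- The augmentation estimator's equal weighting of its two terms is a
  defensible default, not a tuned constant; the weight is exposed.
- Score ties in zero-inflated data are resolved by customer order;
  stratification boundaries can therefore depend on input order for
  exactly tied scores.
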