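# Methods

## Model

Each spot *i* carries a latent type `y_i ∈ {1..K}` (plus an optional
"unknown" state). Three likelihood/prior blocks combine:

**Marker block.** `x1_i | y_i=k ~ N(α + ρ_k ∘ β_k, diag(σ²))`. The shared
baseline α acknowledges that marker genes are expressed everywhere; the
non-negative elevation `β_jk` (only where `ρ_jk = 1`) encodes the
qualitative prior "gene j is *over*-expressed in type k" without requiring
reference expression levels. The diagonal covariance keeps the per-gene
computations closed-form and linear in m.

**Non-marker block.** `x2_i = L z_i + e_i`, `z_i | y_i=k ~ N(m_k, V)`,
`e_i ~ N(0, diag(Λ))` with loading `L (p×q)` shared across types. Types
separate through the q-dimensional factor means `m_k`, so thousands of
non-marker genes contribute to the assignment through a low-dimensional
bottleneck instead of p free mean parameters per type. The marginal used in
the label posterior, `N(L m_k, L V Lᵀ + diag(Λ))`, is always evaluated in
the q-dimensional Woodbury/determinant-lemma form; the p×p covariance is
never formed. The label-conditional factor posterior is Gaussian with
covariance `M⁻¹ = (V⁻¹ + Lᵀ Λ⁻¹ L)⁻¹`, shared across spots and types, which
makes the E-step cheap.

**Spatial prior.** Labels follow a Potts model on the spot neighbor graph:
`p(y) ∝ exp{−ξ Σ_{i~i'} [1 − I(y_i = y_{i'})]}`. During fitting only the
*local conditionals* are used (pseudo-likelihood form); on any graph these
local conditionals coincide exactly with the full conditionals of the joint
distribution, a fact the test suite verifies against brute-force enumeration
of the partition function on tiny graphs. The partition function is never
computed during fitting.

**Unknown component.** Realized as an explicit (K+1)-th mixture component
with marker mean fixed at α (its β column is identically zero) and its own
free factor mean; a posterior-confidence threshold (off by default; rows at
or below the threshold go to "unknown") is available as an alternative or
complement. The component form is the default because a null-elevation
component is the convention of marker-constrained mixture annotators.

## Inference: ICM-EM

Starting point: PCA of `x2` to q dimensions, k-means on the scores, and
Hungarian matching of clusters to types by mean marker-set expression.
When the unknown component is on, k-means runs with 2 surplus clusters and
all unmatched clusters seed the unknown component. This over-clustering is
deliberate: a single leftover cluster makes the unknown component lock onto
one novel population and miss others, whereas seeding it with several
unmatched clusters starts its factor mean between novel populations (the
likelihood-preferred position when more than one type is missing from the
marker list). β is initialized from within-cluster marker elevations
(clipped at zero), L from the PCA loadings, `m_k` from cluster means in PC
space, V from the pooled within-cluster covariance, and ξ at 0.5.

Each iteration then runs:

1. **ICM label sweeps** — sequential per-spot argmax of
   (marker + factor log-likelihood) − ξ·(disagreeing neighbors). The joint
   objective is non-decreasing by construction and asserted per sweep;
   sweeps stop at a fixed point (cap 10).
2. **Responsibility update** — row-wise softmax (log-sum-exp stabilized) of
   marker + factor + local Potts terms given the current labels.
3. **Marker M-step** — per gene, coordinate descent on (α_j, β_j·) for the
   responsibility-weighted squared error with β projected to ≥ 0, iterated
   to 1e-8; σ² is the weighted residual variance.
4. **Factor M-step** — closed-form mixture-of-factor-analyzers updates from
   the mixed posterior moments; L is re-orthonormalized by SVD with the
   scale pushed into the factor space (`LᵀL = I_q`, identification), and the
   `m_k` are recentered so their responsibility-weighted sum is zero
   (the data are column-centered, so the mean embedding is not
   identifiable against the means).
5. **ξ update** — grid search (0 to 2, step 0.1) of the label
   pseudo-log-likelihood `Σ_i log p(y_i | y_neighbors, ξ)`.

The loop stops when the relative change of the pseudo marginal
log-likelihood `Σ_i logsumexp_k(...)` falls below `tol` (default 1e-6,
cap 30 iterations). Final outputs are recomputed once with the converged
parameters. Embeddings are the responsibility-weighted posterior factor
means.

### Numerical choices

- Variance floors of 1e-6 on σ² and Λ prevent degenerate spikes.
- A 1e-8 ridge is added to the factor second-moment matrix if it is
  rank-deficient or ill-conditioned (warned).
- Argmax ties break toward the lowest type index, logged.
- All mixture arithmetic is in log space with log-sum-exp stabilization.
- Components that receive zero responsibility keep their factor mean
  unchanged (warned) rather than producing 0/0.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 15 | embedding dimension of the factor model |
| `max_iter` / `tol` | 30 / 1e-6 | outer ICM-EM loop control |
| `unknown` | on | extra null-elevation component |
| `unknown_threshold` | 0 (off) | posterior floor below which spots go "unknown" |
| `fix_xi` | none | pin ξ instead of grid search (0 disables smoothing) |
| `use_factor` | on | off pins L = 0 (marker-only behavior) |
| `icm_sweeps` | 10 | label sweeps per iteration |
| `unknown_init_clusters` | 2 | surplus k-means clusters seeding "unknown" |
| neighbor rule | `visium_hex` | ≤ 6 nearest within 1.2× min spacing; also `st_square`, `knn`, `radius` |

The Visium hexagonal rule (up to six nearest spots within 1.2× the minimal
positive inter-spot distance) is one reasonable reading of "adjacent spots
on a hex lattice" and is exposed as configuration rather than hard-coded.

## Normalization

Default: library-size scaling to the median library size, `log1p`, then
per-gene centering (`log(1 + c_ij · median(lib)/lib_i)`). This is a simple,
dependency-free variance-stabilizing transform; pre-normalized matrices can
be passed through with centering only (`center_only`). Spots with zero
total count are rejected by name. Gene selection, when requested, is plain
variance ranking with marker genes always retained — spatially aware
selection methods are intentionally out of scope since selection only
filters the input and is not part of the model.

## Synthetic data

The generator emulates a laminar tissue section in the style of cortical-
layer benchmarks: Potts-distributed labels on a lattice (or any supplied
layout) sampled by a chromatic block Gibbs sampler, K types with
`m_per_type` markers each (default 7 types × 5 markers = 35 markers, 2000
non-markers, ≈3600 spots), and factor-driven non-marker covariance with
type means on a regular simplex. Defaults: marker elevations drawn
uniformly from [0.5, 1.5]·`effect` with `effect = 1` (heterogeneous marker
strength, as log-fold changes are), unit marker noise, simplex edge
3·`effect`, V = I, Λ = 1, ξ = 1. The `effect` default was fixed by pilot
runs so that the reference fit sits in a high-but-not-saturated accuracy
band (≈0.95 on the 30×30, K=4 recovery design), making degradation
scenarios informative.

Two output modes: `gaussian_model` draws exactly from the annotation model
(used for parameter-recovery tests, where truth parameters are recorded);
`nb_counts` draws negative-binomial counts (size 10, log-normal library
sizes, same mean structure on the log scale) and exercises the
normalization path. What the generator does *not* emulate: empirical
mean-variance relationships of real platforms, zero-inflation, segmentation
errors, histology-derived layout irregularities, or marker lists curated
from imperfect references. Passing tests therefore demonstrate correctness
of the algorithm under its own assumptions and robustness to the structured
misspecifications modeled (wrong type counts, corrupted marker matrices,
varying non-marker counts) — not performance claims on any real tissue.

Scenario builders produce the structural stress tests: `fewer_types`
(markers for 2 types withheld; their spots should go "unknown"),
`extra_types` (markers for 2 absent types added), `flip_10_20_30`
(two-step random corruption of ρ that preserves the total count of ones),
and `vary_nonmarkers` (p ∈ {60, 100, 500, 1000, 2000}).

## Evaluation

ACC is exact-match proportion; Cohen's kappa corrects agreement for chance
(degenerate single-class marginals return 0 with a warning); mF1 is the
unweighted mean of one-vs-rest F1 over the types present in the truth
(types in the marker list but absent from truth are excluded — averaging
over truth-present classes is the convention of cell-annotation
benchmarks); ARI is the standard pair-counting adjusted Rand index. An
"unknown" prediction counts as correct only when the true type is outside
the provided marker set. Kappa and ARI delegate to scikit-learn internally;
all four metrics are verified against independent brute-force oracles in
the tests.

## Design decisions and open trade-offs

- **ICM-EM with pseudo-likelihood ξ** was chosen over mean-field or exact
  MRF inference for speed and monotonicity guarantees; all approximation
  choices sit behind the fit loop so an alternative can be swapped in.
  Hard ICM labels (not responsibilities) define the Potts context in both
  the E-step and the ξ search.
- **Identifiability** of the factor block is fixed by `LᵀL = I_q` plus the
  weighted recentering of `m_k`; labels, metrics and subspace angles are
  invariant to this choice.
- **Unknown seeding** by over-clustering (above) trades a few percent
  accuracy when the marker list is actually complete (the unknown component
  retains small fragments on some runs) for substantially more reliable
  novel-type detection when it is not.
- **Sizes in tests and the acceptance script** are desk-scale reductions of
  the generator defaults (400–900 spots, 100–200 non-markers, 5–20
  replicates), chosen so the whole suite runs in about a minute while
  leaving each check statistically meaningful.

## Known limitations

- One shared V across types; one unknown component (several well-separated
  novel types are summarized by a single factor mean, which caps unknown
  recall; the over-clustered initialization mitigates but does not remove
  this).
- No model selection over q or K; no multi-slide integration; no
  deconvolution for spots mixing several cell types; exact MRF inference is
  out of scope.
- The ξ grid (0–2 by 0.1) bounds the estimate; fields smoother than ξ = 2
  saturate at the grid edge.
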