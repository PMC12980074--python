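# Methods

## The model

`kann` estimates individual-level genetic ancestry profiles by k-nearest-
neighbor regression in the space of principal components (PCs) of genetic
structure (haplotype components are consumed identically — any component
matrix with per-component eigenvalues works).

Each of n_R reference samples j carries a known ancestry profile
**r**_j = (r_{j,1}, …, r_{j,S}) over S predefined source populations,
a point on the probability simplex.  The profile may be *discrete*
(one-hot, the conventional reference format) or *continuous* (e.g.
produced by a haplotype-based method such as SOURCEFIND, or by
ADMIXTURE).  For a query sample i, the distance to reference j is the
eigenvalue-weighted Euclidean distance over the top M components,

    d(i, j) = sqrt( Σ_{m=1..M} λ̂_m (x_{i,m} − x_{j,m})² ),

where the λ̂_m are the M eigenvalues normalized to sum to one.  The
estimate is a convex combination of the k nearest reference profiles:
the arithmetic mean when the inverse-distance-weighting exponent p = 0,
and otherwise

    q_{i,s} = Σ_{j∈J} w(i,j) r_{j,s} / Σ_{j∈J} w(i,j),
    w(i,j) = max(d(i,j), ε)^(−p),

with J the index set of the k nearest references.  The ε floor
(substitution, not addition; default 0.1) caps the weight of a reference
essentially coincident with the query.  Because the output is a convex
combination of simplex rows, every estimated profile is itself a valid
profile — simplex membership is a structural guarantee, not a
post-processing step.

The modeling assumption that makes this sensible is that source
populations form clusters in component space and an admixed individual
sits, to first order, at the profile-weighted average of the population
centroids.  Distance-weighted neighbor averaging then interpolates
profiles smoothly across the space between clusters.

Complexity: the distance matrix costs O(n_Q n_R M) and neighbor
selection is a stable sort per query row, so the whole estimate is
O(n_Q n_R (log n_R + M)).  Selection is exact — at the panel sizes this
method targets (tens of thousands of references) exact computation is
cheap, and exactness lets every optimization be checked against a
brute-force oracle.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 25 | neighbor count; small k resolves local structure, k = n_R collapses every estimate to the (weighted) global mean |
| p | 3 | IDW exponent; p = 0 disables weighting entirely (exact mean, no 0^0 edge case) |
| ε | 0.1 | distance floor before exponentiation (units of the normalized-eigenvalue distance) |
| M | 10 | top components used; eigenvalues are renormalized after truncation |

Defaults suit the large-reference-panel regime.  With small panels
(n_R below roughly 1500) much larger k — up to n_R — tends to be
preferred, and k and p should be chosen jointly: p matters most when k
is a sizable fraction of n_R.  When profiles of known quality exist for
a subset of the data, `optimization.grid_search` /
`optimization.cross_validate` select (k, p) by minimizing mean TVD.

Non-integer p is accepted (the formula poses no constraint) although the
default search grid is integer 0–10.

## Numerical and design choices

* **Tie-breaking.** Neighbor ties at the k-th distance go to the smaller
  reference row index; the selection equals a stable sort of
  (distance, index) pairs truncated at k, which is also the test oracle.
  Grid-search argmin ties break toward smaller k, then smaller p.
  Argmax thresholding (`threshold_to_discrete`) ties go to the first
  label.  All three rules exist purely for determinism.
* **Eigenvalue normalization after truncation.**  λ̂ is computed over the
  M components in use, so results do not depend on how many extra
  components the input file carries, and multiplying all raw eigenvalues
  by any positive constant changes nothing.
* **Standardization.**  `knn_core.standardize` transforms columns to
  zero mean / unit variance using population SD (divide by n), either
  from the matrix itself or from an external statistics source
  (reference-derived statistics are the only option when queries arrive
  after the panel was fixed; `joint_standardize` pools both, matching a
  single standardization over all samples before splitting).  The
  library never standardizes implicitly — input PCs are often already
  standardized — and the CLI default is `--standardize none`, with
  `joint` the documented choice when standardization is requested and
  both matrices are at hand.
* **Self-exclusion.**  When a query sample ID also occurs in the
  reference set, that reference row is excluded from its own neighbor
  search (leave-one-out semantics); keyed by sample ID, default on.
  Cross-validation gets the same guarantee structurally from disjoint
  folds.
* **Degenerate inputs.**  k = 1 copies the neighbor's profile verbatim
  (bitwise, for any p).  Overflowing weights (d^−p non-finite) and
  all-zero weight sums are hard errors with advice, never NaN
  propagation.  All-zero eigenvalue vectors cannot be normalized and
  error out.  Profile rows whose sums deviate from 1 by more than 1e-3
  are rejected as malformed; smaller deviations (rounded upstream
  output) are renormalized with a warning.
* **Profile output format.**  Tables are written with 6-decimal
  largest-remainder rounding so each printed row sums to exactly 1 and
  read-back never renormalizes; write→read round-trips to within 1e-6
  per entry and repeated runs are byte-identical.
* **Mix-up attribution.**  For each target population and sign, the
  group holds samples whose signed difference matches the sign with
  magnitude ≥ the threshold (0.05 default; zero differences belong to
  neither group).  Group means of the other populations are computed
  over group members only; populations whose mean runs in the same
  direction as the target contribute 0, and if *every* other population
  is same-sign (possible with S ≥ 3) the attribution is left empty with
  a warning rather than normalizing an empty set.
* **Confidence intervals.**  The mean-TVD 95% CI is the normal
  approximation mean ± 1.96·sd/√n and is labeled as such.  Undefined
  Pearson correlations (zero-variance components) are excluded from the
  mean correlation with a warning, not set to 0.
* **Monotonicity of p.**  Increasing p monotonically increases the
  nearest neighbor's normalized weight and the estimate converges to the
  nearest profile as p → ∞; the TVD between the estimate and the nearest
  profile, however, is *not* monotone in p in general (the estimate
  traces a curve through the simplex), and the tests assert the former,
  correct property.

## The synthetic-data generator

`synthetic.simulate` produces component-space data with known ground
truth, the basis of all quantitative tests: S population centroids are
drawn N(0, sep²·I) in the structured subspace with rejection until all
pairwise distances are ≥ `centroid_separation` (error after 1000
attempts); each individual draws π ~ Dirichlet(α) (or is forced one-hot,
round-robin over populations, for the `frac_pure` fraction of the
reference panel and `frac_pure_query` of the queries); coordinates are
π-weighted centroid averages plus isotropic noise whose per-component SD
decays geometrically (`eigenvalue_decay`).  Reported eigenvalues are the
*theoretical* per-component variances, derived in closed form from the
Dirichlet first and second moments and the pure-fraction mixture, so
outputs are exactly reproducible and independent of empirical column
variance.  One seeded generator with per-purpose substreams drives all
randomness: adding draws to one stage never shifts another.

Defaults — S = 4, M = 6, 800 reference / 200 query samples,
separation 8 with noise SD 1 (centroids eight noise-SDs apart: clusters
clearly separated but overlapping through admixture), Dirichlet(0.5)
(sparse, realistic admixture with most mass on one or two sources),
decay 0.7 (a visibly decaying spectrum) — describe a moderately hard
recovery problem on which the estimator at (k = 25, p = 3) beats the
global-mean baseline several-fold in mean TVD.  `n_structured` confines
centroid differences to the leading components, leaving the rest pure
noise; this isolates how estimation accuracy saturates once all
structured components are included.

What the generator does *not* emulate: genotypes and allele frequencies
(no coalescent; it works directly in component space), linkage
disequilibrium, PC shrinkage of projected samples, non-linear or
curved admixture clines, family structure, and reference profiles that
are themselves noisy estimates rather than truth.  Passing tests
therefore demonstrate the estimator's correctness and its qualitative
behavior under the stated geometric model, not accuracy on any
particular real cohort.

## Test problem sizes

Property suites run ~1000 random instances with n_R ≤ 200 and M ≤ 10
against brute-force oracles; trend checks (continuous vs discretized
references, weighting at maximal k, noise monotonicity) use 300
reference / 100 query samples per seed over 10 (or 5) seeds; the
component-saturation sweep uses 250/80 with M = 8 and structure in 3
components.  These sizes give stable majorities across seeds while
keeping the full suite fast.  `scripts/acceptance.py` re-runs the same
pipeline at the generator defaults (800/200) plus a 400/150 grid search
and a 10-fold cross-validation on 800 samples.

## Known limitations

* Accuracy inherits everything that degrades the input decomposition:
  ascertainment of variants, LD pruning choices, and the shrinkage of
  projected samples toward the PC origin.
* Reference profiles are treated as exact; uncertainty in them (and in
  the estimates) is not quantified.
* The estimator cannot extrapolate: a query outside the convex hull of
  its neighbors' profiles still receives a convex combination.
* Exact neighbor search is quadratic in panel × query size; this is
  deliberate (exactness is part of the contract) and fast at the scales
  the method targets, but no approximate index is provided.
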