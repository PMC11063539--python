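# Methods

## Model and procedure

`icluf` treats subtype discovery as iterative fusion of per-omic patient
similarity networks. Its assumptions are: (i) each omic layer measures
the same cohort, with samples matched across layers; (ii) patient
proximity within one omic is meaningful under the Euclidean metric on
that layer's (preprocessed) features; (iii) the subtype structure is
expressed as block structure in the patient–patient similarity matrices,
possibly distributed complementarily across layers, so that repeatedly
passing similarity information between layers lets each matrix converge
toward the shared structure.

**Phase 1.** For each omic the similarity matrix is
`A_ij = exp(-alpha * ||p_i - p_j||^2)` on patient feature profiles. The
exponent uses the squared norm (the standard Gaussian interaction-profile
kernel form); a plain-distance variant is available via
`kernel_squared=False`.

**Phase 2.** Each omic's current matrix is spectrally clustered at the
run's K (normalized Laplacian on the affinity; a K-means-on-rows variant
exists). Patients are represented by their rows of the current similarity
matrix — their similarity profiles — because after the first update the
original feature space plays no further role and the geometry must be
re-derivable from the current matrix at every iteration. From centroids
`v_c`, per-member centroid distances, and per-cluster mean distances
`md_c`, the neighborhood matrix is

    Abar_ij = 2 * A_ij^2 / ( D(c_i, c_j) * (mu + md_{c_i} + md_{c_j}) )
    D(c_i, c_j) = exp( beta * ||v_i - v_j||^2 / (eta + 1) )
    eta = ( md_{c_i} + md_{c_j} + ||v_i - v_j|| ) / 3

Two typographically plausible alternative groupings are selectable
(`eq2_parse="additive"`: denominator `D*mu + md_i + md_j`;
`eq3_parse="outer_division"`: `exp(beta d^2)/(eta+1)`). The defaults are
the readings under which `mu` is actually needed to prevent a vanishing
denominator and under which `eta` normalizes the distance inside the
exponential; both properties fail under the alternatives.

**Phase 3.** The update per omic is a sum of sandwich products over the
other omics, `A_o <- sum_{o' != o} R_o A_{o'} R_o^T`, iterated a fixed
number of times (default 7), then averaged elementwise and clustered with
K-means (k-means++, 10 restarts) on the integrated matrix rows. A
silhouette of a K-clustering of the integrated matrix is recorded after
every iteration as a convergence diagnostic; it never stops the loop.

## Stabilizing the iteration

The literal iteration — sandwiching with the raw neighborhood matrix and
dividing each update by its maximum entry — is unstable, and the failure
modes are instructive:

* **Scalar rescaling collapses.** The update makes entries approximately
  multiplicative in per-patient connectivity (`A_ij ~ r_i r_j`), and the
  `A^2` term doubles the log-spread of the `r_i` every iteration. Under
  any scalar normalization the mass concentrates onto a few entries and
  the clustering degenerates into singletons by roughly iteration 4–5.
* **Dense smoothing flattens.** Row-stochastic or diagonal normalization
  with a dense sandwich operator mixes whole blocks per iteration; any
  uninformative layer injects uniform similarity, and every matrix
  saturates to the constant matrix within a few iterations. A dense
  block-constant operator also provably erases the fine distinctions the
  *other* omics carry (the product of block-constant factors is
  block-constant on the operator's own partition) — precisely the
  information complementary designs need to survive.

The implementation therefore uses, by default:

* an **identity-anchored message operator**
  `R = (I + rownorm(offdiag(Abar))) / 2`: half of each patient's mass
  stays on itself, the other half spreads over neighbors in proportion to
  the neighborhood weights. The `A^2` sharpening and the `D` damping then
  act as a soft nearest-neighbor selection, while the anchor passes
  fine-grained cross-omic structure through unharmed;
* **kernel renormalization between iterations**,
  `A <- D^{-1/2} A D^{-1/2}` with `D = diag(A)`, restoring the unit
  self-similarity that the Phase-1 kernel has and removing the
  connectivity factor `r_i r_j` exactly.

With these defaults the iteration is stable over (and well beyond) the
default seven rounds, recovers planted structure exactly on concordant
designs, and resolves complementary designs in which no single layer
separates all groups. `message_operator="raw"` and
`rescale_method="max"|"row"` retain the literal variants for comparison;
`fusion_step` with the raw operator and rescaling disabled computes the
exact triple-product sum.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.5 | kernel bandwidth; larger = faster similarity decay with distance (dimensionless, applied to squared distance) |
| `beta` | 0.5 | inter-cluster separation gain; recommended range 0.1–1 |
| `mu` | 1.0 | additive guard in the neighborhood denominator; must be > 0 |
| `k` | — | number of clusters, used for Phase-2 clustering and the final K-means alike |
| `iterations` | 7 | fixed message-passing rounds; no tolerance-based stopping |
| `seed` | 0 | seeds every stochastic step (spectral embedding K-means, final K-means, forests) |

One `alpha` is shared across omics. Preprocessing aligns samples across
layers first (lexicographic canonical order), then drops every feature
whose zero-or-missing count strictly exceeds 20% of the cohort, then
mean-imputes remaining missing values (zero-imputation and fail-fast are
selectable); no per-feature standardization is applied unless the
`zscore` switch is set, since the kernel is sensitive to feature scale
and input scaling conventions differ across omic types.

## Synthetic cohorts

The generator plants K patient groups and gives each omic layer a *merge
map* deciding which groups that layer can distinguish. Informative
features carry a group-dependent mean offset of `separation`
within-group standard deviations; remaining features are noise. All
features are drawn at per-feature s.d. `0.5/sqrt(n_features)`, so the
expected within-group squared profile distance is 0.5 and within-group
kernel similarities sit near `exp(-0.75) ≈ 0.47` — the informative
operating range of the default bandwidth, emulating bounded scales such
as methylation beta values or normalized expression. Survival times are
exponential per group; censoring is an independent exponential whose
per-group rate is chosen so the marginal censored fraction equals the
requested rate exactly.

What the generator does *not* emulate: heavy-tailed or overdispersed
count distributions, beta-distribution shapes of methylation, correlated
feature blocks, batch effects, or structured (informative) missingness.
Tests passing on these cohorts therefore demonstrate the mechanics of
the method — kernel, reweighting, message passing, metric correctness,
calibration — not robustness to real-data artifacts.

Default study conditions used by the tests and the acceptance script:
K = 3 groups of 20 (60 patients; 75 for the contribution analysis),
three omic layers of 40–60 features with a quarter informative,
separation 6, and the default pipeline parameters above. These sizes keep
a full pipeline run under a second while leaving the planted structure
unambiguous.

## Evaluation and contributions

Cluster agreement uses the standard pair-counting adjusted Rand index and
Fowlkes–Mallows score; silhouette is computed on Euclidean distances
between integrated-matrix rows, the same representation the final
K-means clusters (a `1 - similarity` dissimilarity variant is
selectable). Survival differences between predicted subtypes use the
K-sample log-rank test (pooled risk sets, hypergeometric variance for
ties, chi-square with K−1 degrees of freedom); a proportional-hazards
regression is deliberately not included — only the log-rank p is
consumed downstream. Cluster-subset comparisons rerun the log-rank test
on every combination of clusters of a requested size and report raw
p-values (a Benjamini–Hochberg column can be added by the caller; the
subset p-values are exploratory).

Per-omic contributions train one seeded random forest per omic (500
trees, sqrt-features per split) predicting the fused subtype labels, sum
each omic's top-quartile Gini importances (ceiling rounding, so small
layers keep at least one feature), and min–max normalize the sums across
omics, mapping the least informative layer to 0 and the most informative
to 1. Because each forest's importances sum to 1 regardless of feature
count, the raw sums are comparable across layers of different widths.

## Numerical choices and degenerate inputs

* Matrices are validated symmetric to 1e-10 and symmetrized
  (`(M + M^T)/2`) after every product.
* Singleton clusters are legal; their mean centroid distance is 0.
* `D(c, c) = 1` exactly; with `mu = 1` every neighborhood entry is
  bounded by `2 A_ij^2 <= 2`, so no overflow is possible regardless of
  geometry.
* An all-zero operator row (an isolated patient) keeps its mass on
  itself rather than dividing by zero.
* Non-finite values arising mid-iteration abort the run with the
  iteration index.
* Spectral clustering, K-means and the forests take explicit seeds; a
  fixed seed reproduces label files bit-identically, and matrices are
  written with `%.17g` so they round-trip through CSV exactly.

## Known limitations

* K is a user input; no automatic model selection (eigen-gap, stability)
  is provided.
* Patients missing an entire omic layer are excluded by the sample
  intersection; partial-cohort integration is out of scope.
* The kernel uses a single global bandwidth; no per-patient adaptive
  scaling.
* The fixed iteration count is a design choice: the silhouette trace is
  exposed for inspection, and an early-stop flag is intentionally absent
  from the defaults.
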