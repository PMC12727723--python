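# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the design decisions behind `metconn`, in the order
the pipeline runs them.

## Metabolic profiles and the similarity matrix

Each retained region's profile is the per-metabolite median of its voxel
signals, z-scored across regions (population SD). Quantification
uncertainty enters through Monte-Carlo perturbation: replicate 1 is the
unperturbed data; replicates 2..K_pert resample every voxel signal from
𝒩(Y, m·σ²) with σ² the CRLB-derived variance and m the variance multiplier
(default 3, exposed as `variance_multiplier` — the factor has no deeper
justification than convention, so users can explore it). Z-scoring is done
*within* each replicate, across regions, which keeps replicates
exchangeable; the region's final profile is the concatenation of the
K_pert z-scored 5-vectors.

The MetSiM is the Spearman rank correlation between those concatenated
row vectors. Concatenation is the reading under which the perturbation
actually enlarges the rank-correlation sample size by a factor K_pert; a
per-replicate-then-average variant is available behind
`compute_metsim(..., replicate_mode="average")` and coincides with
concatenation in the noise-free limit. Even-length medians are the mean of
the two central order statistics. Correlations are clipped to
±(1 − 10⁻¹²) before any Fisher z-transform so `atanh` stays finite.
Leave-one-metabolite-out stability is implemented as omission of the
metabolite's columns from the already-perturbed profile set, so the
comparison against the full matrix shares its perturbation draws and
isolates the removed metabolite.

## The metabolic similarity mode

`reduce_mode` passes the raw similarity rows (no row preprocessing — a
deliberate choice, exposed by simply transforming the input) through PCA
(`pca_dims = min(50, n−1)`) and 1-D t-SNE with PCA initialization,
perplexity 30 and early exaggeration 12; the iteration budget (default
1000) and achieved KL divergence are recorded in the mode's metadata. A
1-D stochastic embedding has arbitrary sign and scale, so modes are
canonicalized: sign chosen so the mode increases along the
caudal-to-rostral (y) centroid coordinate when a scheme is supplied
(otherwise so the first region sits at or below the median), then min-max
scaled to [0, 1]. Orientation is a presentation convention; all inferential
quantities are invariant to it.

The filtered matrix applies the Student-t kernel to the mode with the
normalization taken over all ordered off-diagonal pairs (they sum to 1
exactly); the rescale R = 2q − 1 is applied literally, and the diagonal of
R is set to 1 by convention since the kernel is defined off-diagonal only.
ISOMAP variance fractions come from the spectrum of the double-centered
squared-geodesic Gram matrix (classical MDS reading) on a symmetrized
k-NN graph; a disconnected neighbourhood graph is an error naming k.
Structural connectopies use UMAP (1 component); note that 1-D UMAP
preserves global order reliably only on strongly one-dimensional data —
on weakly structured matrices the component can fold, which is why the
tests exercise it on overlapping-gradient structures.

## Principal paths

The mode gradient between adjacent parcels is the finite difference
(μ_j − μ_i)/d_ij; the path statistic 𝒢_μ is the mean gradient magnitude
over the path's edges (the 1/(N−1) prefactor with N the node count, i.e. a
per-edge mean — the dimensionally consistent reading). Its normalizer is a
Monte-Carlo maximum: M = 1000 (configurable) random mode sequences, iid
uniform on the global mode range with the path's endpoint values pinned and
the path's edge distances reused; 𝒢̃_μ divides by the largest 𝒢_μ among
them. Path entropy uses Rice-rule bins, N_bins = ⌈2(L+1)^⅓⌉ (a 210-node
path gets 12 bins), over the *global* mode range by default so entropies
are comparable across candidate paths (per-path range behind
`entropy_range="path"`); 0·log 0 := 0. Cost is 𝒢̃_μ/H̃, infinite when
H̃ = 0.

Path search enumerates every simple path between user-supplied endpoints
by iterative depth-first backtracking with id-sorted neighbour lists
(deterministic order), guarded by `max_paths` (default 10⁷) and an optional
edge-count bound. "Abrupt detours" are made operational as an arc-length
bound: a path is implausible when its cumulative arc length exceeds κ times
the straight-line endpoint distance (κ = 3 by default, exposed). Ties in
cost break toward the lexicographically smallest node sequence, so the
argmin is independent of enumeration order. Endpoints are user-supplied
region ids; on synthetic data the planted-axis extremes of the hemisphere's
cortical component stand in for the anatomical start/end conventions of
real parcellations. Pathfinding is run per hemisphere; when a
superregion-restricted subgraph fragments, the search operates within a
connected component.

### Significance of a path

`joint_null_test` refits the distance model to the observed MetSiM, draws
RandGeom surrogates, re-embeds each one (fresh t-SNE seed per surrogate)
and re-optimizes the path with the same endpoints and graph. Two readings
of "a null at least as good as the observed path" are provided:

* **cost** (default): null path cost ≤ observed cost. The cost totally
  orders the joint (gradient, entropy) pair in the one-tailed direction the
  search optimizes, so the add-one permutation p-value is exactly
  calibrated — measured type-I error 0.055 at nominal 0.05 with uniform
  leave-one-out p-values.
* **dominance**: null 𝒢̃_μ ≤ observed *and* null H̃ ≥ observed. This
  matches the joint-scatter picture of observed-vs-null clouds, but the two
  statistics are *positively* correlated under the null (rough random modes
  are simultaneously steep and diverse; measured r ≈ +0.7), which makes the
  bivariate dominance count anticonservative (measured type-I 0.15–0.31 at
  nominal 0.05). It is retained for descriptive use only. This is a known
  limitation of dominance-style joint permutation tests, worth keeping in
  mind when the observed statistic is not far outside the null cloud.

Surrogates admitting no valid path count as "not more extreme" and are
logged. Null paths are re-optimized per surrogate rather than re-scoring
the observed node sequence on null data: the hypothesis under test is that
*no* path this good exists under distance-only structure.

## Spatial null models

RandGeom fits an ordinary least-squares line of upper-triangle weights
versus inter-centroid Euclidean distance and pools squared residuals into
2 mm bins tiling [0, max distance]. Surrogates draw, per eligible pair, a
variance uniformly with replacement from the pair's bin pool (nearest
non-empty bin as fallback) and then a weight from the Gaussian around the
fitted line, clipped to [−1, 1] because the entries represent correlations.
Clipping slightly biases surrogate means toward zero near the range edges —
visible only when the fitted line plus residual spread crosses ±1.
Variants: within-hemisphere restricts eligibility to same-hemisphere pairs;
mirrored copies the sampled left-hemisphere block onto homotopic
right-hemisphere pairs; gray-matter-adjacent restricts to adjacency pairs.
Ineligible entries are zeroed and carried in an explicit mask so
comparisons can exclude them.

AdjPerm composes uniformly random transpositions of adjacent parcel pairs;
the value multiset is preserved exactly and duplicates are rejected until
the requested number of unique permutations exists. The swap count controls
a locality/mixing tradeoff that the correlation test's operating
characteristics depend on: measured on independent smooth fields at 60
parcels, type-I error at α = 0.05 is ≈ 0.02 at n/4 swaps, ≈ 0.05 at 3n/8,
≈ 0.08–0.15 at n, and ≈ 0.2 at 4n (by which point Moran's I of the
surrogates is indistinguishable from a free shuffle). The default is
⌈3n/8⌉ — the measured point where the test holds its nominal level while
spatial autocorrelation is demonstrably preserved; `n_swaps` is exposed.

Empirical p-values use the add-one (permutation-valid) estimator
(1 + #extreme)/(1 + n_null), which avoids p = 0 at the cost of a floor of
1/(n_null + 1).

## Synthetic study conditions

The generator is the package's testbed and defines its default conditions:

* **Geometry.** 105 parcels per hemisphere: ~72% cortex on a jittered
  ellipsoidal shell (semi-axes 42/80/58 mm, 4 mm midline gap), plus interior
  Gaussian clusters for subcortex, cerebellum and brainstem. The right
  hemisphere is sampled and mirrored about x = 0, so homotopy is exact.
  The cerebellar cluster sits near the occipital shell without being
  adjacent to it — the configuration distance-only surrogates notoriously
  fail to separate. Adjacency connects pairs within 2.2× the median
  nearest-neighbour distance, plus per-hemisphere minimum-spanning-tree
  edges guaranteeing connected hemisphere graphs. Voxel counts are
  lognormal (median 30, σ = 0.35), giving a parcel-size Gini coefficient
  ≈ 0.2, the regime of real multi-scale parcellations.
* **Metabolites.** A single latent score — the min-max-normalized
  caudal-to-rostral coordinate plus a +0.5 shift for non-cortical parcels —
  drives all five metabolite means through per-metabolite slopes (tNAA
  −0.50, tCr −0.15, Glx −0.30, Cho +0.50, Ins +0.25 relative change across
  the axis). Folding the cortical/subcortical contrast into the same score
  is deliberate: the tNAA/Cho reversal is then *the* driver of
  cortex/subcortex segregation along the mode, rather than a second,
  orthogonal direction that no one-dimensional mode could capture. On top
  of this: a Gaussian-kernel-smoothed random field (length 25 mm, amplitude
  2% of the mean — small enough that the planted axis remains the dominant
  profile direction, the regime the recovery analyses are defined for),
  voxel noise at 5% CV, and per-voxel variance estimates at 8% CV of the
  signal. Voxel positions are never materialized; a parcel is a bag of
  voxels, which is all the median and the perturbation need.
* **Structural backbone.** Poisson streamline counts with rate
  80·exp(−0.06·d) plus 40 on adjacent pairs; lengths are centroid distances
  with positive jitter; volumes scale voxel counts by 125 mm³ (5 mm
  isotropic voxels).
* **Labels and expression.** Quantile bands of the axis with a
  (1 − coupling) uniform flip rate; expression profiles mix a random gene
  weight times the z-scored axis (weight `coupling`) with Gaussian noise.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning; regeneration is bit-identical. What the generator does *not*
emulate: spectral fitting artifacts, lipid contamination, partial-volume
effects, registration error, field inhomogeneity, or any cohort-level
between-subject variability beyond fresh noise fields. Passing recovery
tests on this data therefore validates the pipeline's statistical
machinery, not the acquisition chain.

## Problem sizes

Axis recovery, distance-structure, leave-one-out and surrogate-ensemble
experiments run at the native 210-parcel scale (K_pert = 50 where the
perturbation depth matters, 1000 surrogates for the best-of-ensemble
check). Exhaustive path search and the per-surrogate re-embedding of the
calibration experiments use 16–28-parcel schemes: simple-path counts grow
combinatorially with graph size, and the calibration question (is the
rejection rate nominal?) is scale-free. The AdjPerm calibration uses a
60-parcel scheme, where the per-scheme variability of the rejection rate
is small. The path-order recovery experiment feeds the planted axis in as
the mode, isolating the search algorithm from embedding noise; the
embedding's own recovery is measured separately at full scale.

## Known limitations

* 1-D t-SNE compresses a 210-region similarity structure onto a line;
  local folds cost a few points of rank correlation even at high SNR
  (PCA-1 reaches ρ ≈ 0.94 on the same data, the embedded mode ρ ≈ 0.92).
* The dominance variant of the joint path test is anticonservative (see
  above); the cost variant is the inferential default.
* RandGeom clipping to [−1, 1] biases surrogate means where the fitted
  line approaches the boundary.
* AdjPerm calibration was established for smooth fields on ≈ 60-parcel
  schemes; very small schemes show per-realization variability of the
  rejection rate, and strongly non-smooth maps were not studied.
* The Hungarian overlap score is upper-bounded by the larger class count's
  share and is compared against permutation baselines, not an analytic
  null.
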