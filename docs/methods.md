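# Methods

## Model

A fitness compendium is a dense matrix **F** (genes × samples) of fitness
log-ratios from pooled transposon-mutant screens. The working model is

F = M·A + E,

with **M** (genes × m) sparse and heavy-tailed — each column has a small
set of member genes with large signed weights against a near-zero
background — **A** (m × samples) the per-condition activities, and **E**
i.i.d. Gaussian noise. ICA is the right estimator for this model because
the columns of **M** are (approximately) independent non-Gaussian
sources: a pathway's fitness signature is driven by few genes and few
conditions, so its weight distribution is far from normal, which is the
contrast FastICA maximizes.

Orientation: **F** is decomposed with genes as observations over the
sample dimension, so the estimated sources are gene-weight vectors
(columns of **M**) and the mixing coefficients give activities. All
components at a fixed dimension k live exactly in the k-dimensional
whitened subspace of the data — a fact with practical consequences (see
*Degenerate inputs*).

No normalization is applied to **F** beyond the ICA algorithm's internal
centering and whitening: fitness values are already normalized against
the time-zero barcode counts, replicates are deliberately not averaged,
and complete-case gene filtering (drop any gene missing in any sample) is
the only preprocessing. Explained-variance accounting therefore operates
on the column-centered matrix — the same centering FastICA applies — so
that the reconstruction M·A and the variance baseline refer to the same
object.

## Robust components

FastICA converges to different local optima from different starts, so a
single run is not trustworthy. The pipeline runs `n_runs` decompositions
(default 100, tolerance 1e-7, seeds `base_seed + run`), pools all unit-norm
components, and clusters them with DBSCAN on the precomputed distance
matrix d(x,y) = 1 − |ρ(x,y)| (Pearson). The absolute value makes the
distance sign-invariant, since ICA recovers sources only up to sign; a
signed variant (1 − ρ) is available for exact replication of workflows
that used it, but treating x and −x as distant contradicts the purpose of
the clustering and is not the default. This distance is not a metric (no
triangle inequality); DBSCAN only thresholds pairwise distances at eps,
so no metric property is assumed.

Defaults: eps = 0.1, minimum cluster size 50 out of 100 restarts. When
`n_runs` ≠ 100, the minimum scales as ⌈n_runs/2⌉, preserving the
50-of-100 ratio so desk-scale ensembles behave proportionately. Each
cluster's members are sign-aligned to its first member, averaged,
re-normalized, and oriented so the largest-magnitude weight is positive.
Activities are recomputed jointly by least squares on the centered matrix
rather than averaged from per-run mixing matrices — the centroid is not
any run's component, so its activity is best defined by projection.

Non-converged runs are flagged and kept by default (`strict=True` drops
them): their components either recur — and then deserve clustering — or
are scattered and end up as DBSCAN noise anyway.

### Degenerate inputs

Because every component at dimension k lies in the same k-dimensional
whitened subspace, the set of cluster centroids can be *exactly* linearly
dependent whenever DBSCAN finds more than k clusters (typically at
over-decomposition, where pure-noise directions form several rotated
clusters). Dependent centroid columns are pruned greedily — larger
clusters first — before activities are fit, restoring m ≤ k; the pruned
count is recorded in provenance. `compute_activities` itself refuses
rank-deficient weight matrices and names the collinear column pairs.

## Dimensionality selection

The scan runs the full pipeline at each candidate dimension and counts,
per dimension: robust components (`n_robust`), single-gene components
(`n_single`), zero-member components (`n_zero`), multi-gene components
(`n_multi = n_robust − n_single − n_zero`) and persistent components
(`n_final`: those matching a component at the largest scanned dimension
at |Pearson R| > 0.7, sign-invariant). The selected dimension is the one
with `n_final > n_multi` that minimizes `n_single` (smallest k on ties);
with no satisfier the scan falls back to minimal `n_single` and warns.
The full scan table is always written so the choice can be overridden.

Tracking `n_zero` separately is a deliberate refinement: on clean
simulated data, over-decomposition produces zero-member noise components
rather than single-gene components, and lumping those into the multi-gene
count would make the selection inequality unsatisfiable everywhere. A
component with no significant genes is degenerate, not multi-gene.

## Membership calling

Within one component most gene weights form a near-Gaussian bulk around
zero; members are the heavy-tailed outliers. Membership is called by
iteratively removing the gene with the largest |weight| (ties broken by
gene id, so the result is order-independent) and recomputing the
D'Agostino–Pearson K² omnibus statistic — squared standardized skewness
plus squared standardized kurtosis, asymptotically χ²(2) under normality
— on the remaining weights. All genes removed before K² first drops to
the cutoff are members, signed by their weights. If the initial K² is
already below the cutoff the module has zero members: a valid, flagged
outcome. The statistic requires ≥ 20 observations; running out of
evaluable genes before crossing the cutoff is a hard error. The statistic
is scale-invariant, so weights are used raw on the unit-norm component
scale.

The default cutoff is 550, the convention of ICA-module workflows on
transcriptomic compendia of ~4,000+ genes, applied as a single global
threshold across components. K² magnitudes grow with vector length and
outlier fraction, however, so a fixed number does not transfer across
data scales. Two properties make calibration well-posed:

* the removal order is cutoff-independent, so one K² trace per component
  resolves the member count at *every* cutoff;
* between "members still present" (K² in the hundreds-to-thousands) and
  "only background left" (K² of order χ²(2)) the trace collapses by one
  to two orders of magnitude, leaving a wide cutoff range on which the
  called membership of every component is constant.

`calibrate_cutoff` sweeps a log-spaced grid, finds the longest such
plateau (ignoring the all-empty regime) and recommends its geometric
midpoint; `cutoff="auto"` uses it anywhere a cutoff is accepted. One
caution the calibration makes visible: the K² trace is *not* monotone
during member removal (removing one of several sign-symmetric outliers
can transiently lower the skewness term), so a cutoff inside the member
range — rather than inside the plateau — can truncate a module's
membership early. Raising the cutoff can only shrink membership
(monotonicity), and members always dominate non-members in |weight|.

## Explained variance and module statistics

Explained variance uses the residual-reduction definition on the centered
matrix: ev = 1 − ‖F − M·A‖²_F / ‖F‖²_F, with A re-fit by least squares
for whichever component subset is scored (single column for per-module
values, all columns jointly for the total). Components are not
orthogonal, so per-module values need not sum to the total; an
energy-ratio alternative (‖M_k·A_k‖²/‖F‖²) is available behind a flag,
and every report carries its formula tag. Adding a component can never
decrease the total (nested least squares).

Gene multiplicity is the per-gene count of containing modules (ICA,
unlike hard clustering, lets one gene carry weight in several modules);
the histogram over these counts sums to the unique member-gene total.
Median module size excludes zero-member modules by default, since a
median over sizes including structurally empty components answers a
different question.

## Module comparison

Two module collections (e.g. function-derived vs regulation-derived) are
compared by exhaustive pairwise gene intersection: every pair sharing ≥ 1
gene becomes a link with its shared-gene set; the unique count of genes
grouped on both sides is reported separately, because a promiscuous gene
contributes to every pair it connects but should be counted once in the
overlap total. Links export as flat (left, right, weight) rows,
deterministically ordered, for Sankey rendering by any plotting tool.
Annotation-transfer suggestions list, for each uncharacterized module,
the annotated counterparts it shares genes with, ranked by shared count.

## Synthetic data

The generator plants exactly the model's structure: disjoint member sets
(sizes uniform in a range, default 5–15) with signed weights of magnitude
uniform in [3, 6] against an exactly-zero background; optionally a
fraction of member genes (default 5%) added to a second module to
exercise multiplicity, and optional structurally empty modules to
exercise the zero-member path. Activities are block-structured by
default: each module is active in a contiguous block of samples (blocks
partition the sample axis, making planted activities mutually orthogonal)
with standard-normal values bounded away from zero, emulating
condition-specific phenotypes; a dense Gaussian alternative exists.
Gaussian noise (default sd 0.25) and a uniform missing mask are applied
last. A single seeded generator with a fixed draw order (weights,
activities, noise, mask) makes outputs bitwise reproducible.

What the simulation does *not* emulate: correlated noise across
replicate samples, batch structure, gene-length or insertion-density
artifacts, partially overlapping pathway activities, and the long-tailed
module-size distribution of real compendia. Passing the recovery
benchmarks therefore demonstrates correctness of the estimator under its
own model assumptions — identifiability, robustness aggregation,
membership thresholding — not performance on any real organism's data.

## Benchmark problem sizes

The standard benchmark regime is 8 planted modules in an 800-gene ×
64-sample matrix (noise sd 0.25) decomposed at k = 8 with 20 restarts,
and a 6-module, 600 × 48 variant for the dimension scan over
{2, 4, 6, 8, 10} with 10 restarts per dimension. These sizes preserve the
qualitative regime of real compendia (genes ≫ samples ≫ modules; members
a few percent of genes) at a scale where the full pipeline runs in
seconds per seed, which is what makes multi-seed acceptance testing
practical. Recovery is scored by greedy Jaccard matching of member sets
plus Pearson correlation of matched activity rows, both sign-invariant.

## Known limitations

* The dimension-selection criterion inherits the ambiguity of its
  persistence heuristic; it is codified as a deterministic lexicographic
  rule and the scan table is always exported for manual override.
* A single global K² cutoff is used for all components; per-component
  cutoffs are out of scope.
* Missing data is masked and filtered, never imputed; compendia with
  pervasive missingness lose many genes to complete-case filtering.
* No statistical enrichment test accompanies module overlaps; counts
  only.
* FastICA is the only contrast family offered.
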