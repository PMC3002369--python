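# Methods

## Model and procedure

`conclust` treats a clustering result as a random object whose distribution
is induced by perturbing the data: rows are subsampled without replacement
and re-clustered, and the stability of every pairwise co-clustering relation
is estimated by its empirical frequency.  Concretely, for data with N
features and a backend fixed at cluster number k:

- each iteration draws `round(proportion · N)` distinct rows (default
  proportion 0.8, 100 iterations), clusters them, and records a binary
  connectivity matrix (pairs sharing a cluster) and a binary indicator
  matrix (pairs drawn together);
- the consensus matrix is the elementwise quotient of the two sums, with
  diagonal fixed at 1.  Pairs never drawn together (a possibility only at
  very low iteration counts) are reported as 0 and flagged
  (`never_cosampled`) rather than interpolated: absence of evidence is
  scored as no support, and the flag tells the user to raise `iterations`.

Robustness is always scored against an *explicit* reference partition — the
backend applied to the full data under identical conditions — never by
re-clustering the consensus matrix itself.  This keeps the object under
test well defined and lets the same reference be cast onto different
matrices (a single-algorithm consensus and a multi-algorithm merge), which
is what makes the merge comparison meaningful.

Cluster robustness is the mean consensus over unordered within-cluster
pairs; membership robustness is the mean consensus between one member and
the rest of its cluster.  The diagonal is excluded from both sums, and
cluster robustness is algebraically the mean of its members' membership
robustness — the test suite asserts this identity to 1e−12 as a standing
cross-check on both implementations.

Merging averages consensus matrices from different algorithms (or
conditions) elementwise with user weights normalized internally to sum to
one; equal weights are the default.  Merging is refused across different k.
A pair's never-co-sampled flag survives a merge only if every source
flagged it.

The cluster number is estimated by sweeping k, computing for each k the
empirical CDF of the off-diagonal consensus values and its stepwise
integral (AUC), and locating the peak of ΔK, the change in AUC between
adjacent k.  Two ΔK definitions are provided: `relative` (default), where
ΔK(k) = (AUC(k) − AUC(k−1)) / AUC(k−1) with the k_min entry seeded by
AUC(k_min), and plain `difference`.  The profile records which was used.
The estimate is the global argmax of ΔK excluding the k_min seed entry,
with ties broken toward smaller k; a flat profile falls back to the
smallest candidate with a `flat` flag instead of fabricating a peak.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `proportion` | 0.8 | fraction of rows per subsample (without replacement); subsample size is `round(p·N)` |
| `iterations` | 100 | resampling draws per (algorithm, k) cell |
| `k_range` | 2–7 | candidate cluster numbers for the ΔK sweep |
| `linkage` | average | hierarchical linkage (complete/single/ward selectable) |
| k-means `n_init` | 10 | restarts per fit; the best-inertia solution is kept |
| `merge_weights` | equal | per-source weights, any nonnegative scale ≤ 1, normalized internally |
| `deltak_definition` | relative | ΔK formula (see above) |

Determinism: every built-in backend is deterministic given (data, k, spec,
seed).  Per-iteration seeds derive from (master seed, iteration index) via
`numpy.random.SeedSequence`, and per-cell seeds from (master seed,
algorithm index, k), so results are identical regardless of execution
order — iterations or cells may run in parallel or be farmed out in
batches.  PAM is deterministic outright (greedy BUILD, steepest-descent
SWAP, ties toward the lowest index).  Cluster labels are canonicalised by
first appearance in row order, so identical partitions always serialize
identically.

The k-means default keeps scikit-learn's multi-restart initialisation: the
backend contract is deterministic output, and the restarts make the
reported partition a stable (near-global) optimum rather than an artefact
of one random start.  A single-start run remains available via
`extra_params={"n_init": 1}`, and the MacQueen online-update variant via
`extra_params={"variant": "macqueen"}`.

## Synthetic data generator

`simulate_profiles` emulates a four-condition expression experiment: 25
genes (default) drawn around each of the base profiles (1,0,1,1),
(0,1,1,0), (1,1,0,0), (0,1,0,0), spiked with 5 genes around each of the
deviant profiles (1,1,1,1), (0,0,1,1), (1,1,0,0), (0.5,0.5,0,0) — 120
genes in total.  Noise is i.i.d. Gaussian per condition (default
σ = 0.1 on the 0–1 profile scale: clearly visible noise that leaves the
base profiles separable).  Ground truth records each gene's base profile
(spikes are assigned their nearest base by Euclidean distance, ties to the
lower index), a spike flag, and the spike shape.  The third spike shape
coincides with base profile 3 by construction and is deliberately kept
labelled a spike, so tests can distinguish "spike by construction" from
"outlier in effect".

What the generator does *not* emulate: intensity-dependent variance, probe
effects, correlated conditions, missing values.  Passing tests on this
generator therefore demonstrate the machinery (resampling, robustness
arithmetic, merging, ΔK) and the qualitative outlier story, not performance
on raw microarray intensities — real inputs are expected to arrive already
normalized, and the variance-filter/unitise/transpose preprocessing mirrors
the usual preparation pipeline.

## Numerical and design choices

- **Subsampling**: without replacement, size `round(p·N)`; selected rows
  keep their original order (so proportion 1.0 is the identity).  With-
  replacement (bootstrap) sampling is out of scope — duplicated rows would
  break the indicator-matrix semantics of "pairs drawn together".
- **Connectivity/indicator diagonals** are 1 for sampled features; the
  consensus diagonal is fixed at 1 and excluded from all robustness sums
  and from the CDF.
- **Singleton clusters** have empty robustness sums; both robustness values
  are defined as 1.0 (a singleton is vacuously self-consistent) and the
  cluster is flagged in the report so the convention is never mistaken for
  evidence.
- **Degenerate CDF** (a single distinct off-diagonal value) yields AUC 0 by
  the empty-sum convention; `estimate_k` flags flat profiles rather than
  returning an arbitrary peak.
- **Failed cells**: an iteration whose subsample defeats the backend is
  retried with a fresh draw (bounded retries); a failed (algorithm, k) cell
  is logged and reported as partial completion instead of aborting the
  whole experiment.
- **Boxplot outliers** in the membership-robustness figures use the
  standard 1.5×IQR whisker rule, drawn as open triangles.
- **Unitisation** is row scaling to unit Euclidean norm by default, with
  mean-0/SD-1 standardization selectable; both make clustering
  shape-driven, and the variant used is recorded in the run metadata.
  Degenerate rows (all-zero, or constant under the z-score variant) are
  left unchanged and flagged.
- **Variance filter** uses sample variance (ddof = 1), keeps the original
  row order, and breaks ties at the cutoff by row order.

## Known limitations

- The ΔK estimator reads the *global* argmax of the profile.  Two regimes
  blunt it, and both are visible in the acceptance suite on the synthetic
  generator: at low noise, deterministic backends can produce *exactly*
  binary consensus matrices at several k (the stepwise AUC of Eq-style
  integration jumps to 1 only for exactly-binary matrices), creating
  spurious late-k peaks; at high noise, a genuinely ambiguous k = 2
  partition deflates AUC(2) and inflates ΔK(3).  Practitioners reading a
  delta-K plot would discount both by eye; the package reports the full
  numeric profile precisely so that judgement stays available, and the
  plot overlays every algorithm plus the merge.
- The agglomerative backend's characteristic failure on spiked data (fusing
  the two closest base profiles while splitting off a spike group) is
  reproduced structurally at k = 4, but the k at which its ΔK profile peaks
  depends on where its ambiguity stabilises (k = 5 when one spike group
  dominates; k = 6–7 when both spike groups and the fused-pair split must
  settle), which shifts with the noise level.
- Divisive hierarchical clustering and affinity propagation are not built
  in; they are registry extension points (wrap an implementation in the
  runner contract and `register_algorithm` it).
- Column (condition) resampling, feature weighting during sampling,
  significance tests on robustness values, and alternative cluster-number
  criteria (gap statistic, silhouette) are out of scope.
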