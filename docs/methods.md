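# Methods

This note documents the models, estimators and numerical choices behind
`chickn`, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model

The unit of analysis is the **chromatographic elution profile**: a
non-negative intensity time series, one column of a spectra × chromatograms
matrix. Two construction routes exist.

**Resampled spectra.** Raw MS1 scans (mzML/mzXML) are interpolated onto a
non-uniform m/z grid whose spacing follows the instrument's resolving
power: starting from m₁ = mz_min, the recursion
m_{i+1} − m_i = 0.015·m_i^{3/2}/Res gives finer sampling at low m/z
(about 0.5 mTh at 400 Th for Res = 240,000) and coarser at high m/z, so a
profile-mode peak spans a similar number of nodes anywhere in the range.
Intensities at each node are linear interpolations of the two neighboring
recorded peaks; nodes outside a spectrum's recorded support are set to 0
(absent signal is zero ion count). Columns that are all-zero are deleted;
"empty" means strictly zero by default, with an `empty_threshold` knob for
noisy profile-mode data. Rows keep acquisition order by retention-time
stamp, ties broken by file order; retention times are used as recorded,
without resampling to a uniform grid.

**Pre-traced points.** A five-column CSV (m/z, retention time, intensity,
trace label, envelope label) is loaded with one column per trace; labels −1
and 0 mark noise points and are dropped (the label set is configurable
because the package's own exporter uses 0-based column indices as trace
labels). Envelope labels, when present, serve as clustering ground truth.

Matrices can be file-backed (HDF5, column-chunked) so that column slices
are read without loading the full array; every pipeline stage accesses data
through column-slice streaming.

## Similarity

Profiles are compared after normalization to unit mass, so only elution
*behaviour* matters, not abundance. The 1-D Wasserstein distance reduces to
the L1 difference of cumulative distributions and is computed vectorized on
cumulative profiles (an LP transport solver is used as an independent
oracle in the tests, never in the pipeline). The kernel
exp(−γ·d^p) is positive definite for p = 1 (Laplacian W1); for p = 2
(Gaussian W1) PSD-ness is only empirical, and the test suite bounds the
negative eigenvalue tail rather than asserting strict PSD. In practice the
rank-restricted Nyström factors clip any slightly negative directions.

**Bandwidth γ.** Estimated from the landmark sample: for each landmark, the
W1 distances to its ν nearest landmark neighbours (ν = 32 by default,
clamped to l−1) are raised to the power p and averaged. Two conventions are
exposed: the *mean* itself (`estimate_gamma` default) and its *reciprocal*.
The pipeline uses the reciprocal: a bandwidth must scale as one over the
distance scale of the data for the kernel to discriminate at that scale
(with the mean convention, γ·d^p ≈ d^{2p} ≫ 1 and all similarities collapse
to zero whenever typical distances exceed 1). The reciprocal convention also
matches the magnitudes a practitioner obtains on real trace data (γ ~ 10⁻⁶
when squared distances are ~10⁶). γ is estimated once at the root and reused
at every level, as is the frequency sample.

## Compression

**Nyström.** l landmarks are drawn uniformly without replacement (seeded).
The landmark Gram W is eigendecomposed; eigenvalues below 10⁻¹² of the top
one are clipped; the top r = l/2 pairs are kept; a second rank-s SVD of the
embedded landmark block Σ_r^{−1/2}U_rᵀW stabilizes the final factors. The
feature map is φ̃(x) = Σ_s^{−1/2}U_sᵀk_x with k_x the landmark similarity
vector, so Φ̃ᵀΦ̃ ≈ K (the Σ^{−1/2} scaling is required for the self-inner
product to reproduce the kernel; a λ-scaled map does not). At full sampling
(l = r = s = N, PD Gram) the reconstruction is exact to 10⁻⁶, and the
Frobenius error is non-increasing in s — both are asserted in the tests.

**Frequency scale σ².** The sampling law Ω = N(0, σ⁻²I) needs the spread of
the embedded data. The default estimator is the mean squared norm of the
embeddings over a subsample of min(1000, N) columns — reproducible, scale
-equivariant (doubling the embeddings quadruples σ²), and within 50% of s·v
for isotropic Gaussian data of per-coordinate variance v. A regression-based
estimator of the empirical characteristic function decay could be plugged in
through the same interface.

**Sketch.** SK = (1/(n√m))·[Σᵢ exp(−i wⱼᵀφ̃(xᵢ))]ⱼ, evaluated in streamed
column chunks. Exact contracts: every component has modulus ≤ 1/√m; the
sketch of a disjoint union is the size-weighted mean of the parts'
sketches; zero frequencies give 1/√m per component.

## Compressive k-means

The sketch-matching objective ‖SK(data) − Σᵢ αᵢSK(cᵢ)‖² is minimized by a
matching-pursuit scheme:

- **Expansion** (k rounds): a new centroid maximizing the real correlation
  between its (unit-norm) sketch and the current residual. Candidate starts
  are the members of an init cloud ranked by that correlation (cheap,
  vectorized), with the top few plus one random start refined by gradient
  ascent with backtracking line search. After each expansion the weights
  are re-solved by non-negative least squares (complex system stacked to
  real).
- **Replacement** (k more proposals): each centroid in turn is tentatively
  replaced by a fresh proposal against the residual without it; kept only
  if the objective drops.
- **Joint polish**: alternating a backtracking gradient step on all
  centroids with an exact NNLS re-weighting — each half-step cannot
  increase the objective, so the polish is monotone; stopping at relative
  change < 10⁻⁶ or 300 iterations. Because the objective is multimodal,
  the polish is restarted from a few random k-subsets of the init cloud and
  the lowest final objective wins; the result is never worse than the
  greedy phase.

m of order k·s suffices for the sizes the derivation produces, but the
objective landscape at such small m is noisy; the restarts are the cheapest
effective global search. A warning (not an error) is raised when m < k·s.

## Hierarchy

`derive_parameters` uses the ceiling convention (l = ⌈√N⌉, s = ⌈√k·N^¼⌉,
m = ⌈k^{3/2}N^¼⌉), which uniquely reproduces the published benchmark table
for the 57,140-trace dataset, and computes T = ⌊log_k k_total⌋ by exact
integer arithmetic (floating logs misround at powers of k).

The root fit (landmarks → γ → feature map → σ² → one frequency sample) is
done once; every split re-sketches only the node's columns with the same
frequencies and feature map. Per split, the CKM is restarted up to 3 times
(seeded) and the lowest-objective solution that actually separates the node
is kept; a node whose restarts all collapse to one child stays a leaf, with
a logged warning. Candidate init clouds are drawn from the node's own
members (up to 64), since global landmarks can lie outside a sub-cluster
and absorb an atom. Nodes smaller than min_split_size (default ν: a cluster
smaller than the pre-image neighborhood is not worth splitting) or at depth
T are leaves.

After the tree is built, a **final global assignment** maps every column to
the most similar leaf centroid (⟨φ̃(x), c/‖c‖⟩ argmax, ties to the lowest
index). Per-level routing can strand borderline columns in a neighboring
subtree; the global argmax over the final centroid set repairs this and
never performed worse in our measurements. Leaves emptied by the
reassignment are allowed. Consensus chromatograms are then computed per
leaf as the arithmetic mean of the q = min(ν, size) members most similar to
the centroid — a local mean, because the global cluster mean can lie
outside the cluster under the non-linear feature map.

Reruns with the same seed are bit-identical; all derived randomness flows
from one seed sequence.

## Evaluation

Pair counts (TP/TN/FP/FN over all C(N,2) pairs) come from the contingency
table and are cross-checked in tests against exhaustive pair enumeration
and an independent library implementation. Rand index, pairwise precision
and recall follow; undefined ratios (zero denominators) are reported as
absent, never silently as 0. Noise-labelled ground-truth elements are
excluded before pair counting. The Davies–Bouldin index uses W1 distances
in the chromatogram space with the consensus chromatograms as cluster
centers — the same metric the clustering itself optimizes, as an internal
score must.

## Synthetic generator

Each column is scale·Gaussian(apex + jitter, width), optionally convolved
with an exponential tail for chromatographic realism, plus additive noise
clipped at zero. Cluster identity sets the apex and width; within-cluster
variation comes from apex jitter and intensity scaling. Defaults: peak
widths of a few time samples, apex jitter of half a width or less, 2%
additive noise, intensities spanning one decade — a clean, well-separated
regime. The eight-cluster preset uses 256 columns per cluster (N = 2048) so
that the derived target rank s = 10 exceeds the number of generating
clusters; with much smaller N the s ≈ √k·N^¼ rule yields a feature space
too small to represent the partition, a regime the sizing formulas were
never meant for.

What the generator does **not** emulate: m/z fluctuation across scans
(column discontinuity), isotopic envelopes and charge states, co-eluting
interferences, heteroscedastic detector noise, retention-time drift between
runs, and the heavy-tailed cluster-size distribution of real maps. Passing
the end-to-end tests therefore demonstrates the machinery — compression
fidelity, centroid recovery, hierarchy bookkeeping — under favourable
separations, not clustering accuracy on raw instrument data.

## Numerical choices and degenerate inputs

- Eigenvalue clipping at 10⁻¹² relative; rank-deficient landmark Grams
  (rank < s) raise an error suggesting larger l or smaller s.
- Zero-mass columns are rejected at distance level and excluded at
  matrix-build time; identical landmark sets yield a degenerate-bandwidth
  error (γ must be > 0).
- Assignment ties break to the lowest centroid index; nearest-neighbour
  ties in γ estimation break by index; both make reruns deterministic.
- Complex sketches are kept as complex arrays; NNLS solves the stacked
  real system.
- Coincident DB centroids (d_W1 = 0) raise an error naming the pair.

## Limitations

- The sketch objective at m ≈ k·s is noisy: on hard instances the global
  optimizer can legitimately prefer an uneven split, which a zero-slack
  budget (k_total equal to the true cluster count) cannot absorb. Real use
  should give k_total slack, as cluster counts are never known exactly.
- γ and σ² are estimated once at the root; deep sub-clusters with very
  different internal scales would be better served by per-level
  re-estimation, at the cost of the shared-frequency design.
- The W1 kernel with p = 2 has no PD guarantee; small negative eigenvalues
  are clipped by the rank restriction rather than corrected.
- Out-of-core support covers column streaming; the landmark Gram and its
  decomposition are dense in memory (l×l, fine for l ≈ √N at any realistic
  N).
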