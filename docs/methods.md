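# Methods

This note documents the models, numerical conventions and design choices
behind `connectopred`, in the order data flows through the pipeline.

## Connectivity construction

**SC weights.** `W_ij = (M_ij + M_ji) / ((N_i + N_j) · S)` normalises the
two-way streamline traffic between regions *i* and *j* by the maximum number
of streamlines the pair could exchange (`N` seed voxels per region, `S`
streamlines per voxel, default 5000). The weight is a connection density per
unit seed volume: symmetric by construction, in [0, 1], and insensitive to
region size. Regions with zero seed voxels are rejected as invalid.

**FC weights.** Fisher-z matrices are inverted with `tanh` and folded
positive by absolute value, in that order, before thresholding. `|tanh|`
keeps weights in [0, 1), so both modalities share the same weight scale and
the inverse-weight distance convention below is well defined for both.

**Proportional threshold.** "Keep the strongest fraction" is parameterised by
`retain_fraction`, default **0.20** — an 80% threshold is read as discarding
the weakest 80%, consistent with the moderate-to-high thresholding rationale
for structural networks; the opposite reading (retain 0.8) is available by
passing 0.8. The quota is computed over the upper triangle and applied
symmetrically. For SC only nonzero entries are candidates (an absent tract is
not a weak edge); for dense FC every off-diagonal pair is. Boundary ties are
broken by (weight desc, row asc, col asc) so surviving edge sets are
deterministic and nested across retain fractions; re-applying the same
fraction is a no-op.

## Graph metrics

All measures operate on weighted undirected graphs with weights in [0, 1].

* **Distances**: edge length = 1/weight; all-pairs shortest paths by
  Floyd–Warshall (scipy csgraph). Disconnected pairs are infinite.
* **Clustering / transitivity**: Onnela's geometric-mean triangle intensity
  with weights normalised by the global maximum; transitivity is the ratio
  form (total triangle intensity over total connected triples).
* **Modules**: Newman's spectral method — recursive leading-eigenvector
  bipartition of the (generalised) modularity matrix with Kernighan–Lin
  refinement; the eigenvector sign convention makes the partition
  deterministic. Within-module degree is the z-scored within-module *binary*
  degree (z = 0 in zero-variance modules); participation uses per-module
  strength fractions, clamped to [0, 1] against float error.
* **Centralities**: eigenvector centrality is the leading eigenvector of W on
  the largest connected component (nonnegative, unit L2 norm, zeros
  elsewhere — it is non-unique on disconnected graphs otherwise). Node and
  edge betweenness count shortest-path multiplicities exactly on the
  inverse-weight metric (Brandes accumulation; equal-length paths split
  fractionally).
* **Matching index**: weighted Jaccard overlap of the two nodes'
  neighbourhoods, excluding the pair itself: Σ min(w_ik, w_jk) / Σ max(...).
  1 for identical neighbourhoods, 0 for disjoint ones.
* **Path transitivity**: the mean matching index over all node pairs on the
  shortest path between *i* and *j*; defined as the pair's own matching index
  when the path is a direct edge, and 0 for disconnected pairs. The
  literature leaves the normalisation of this construction open; the mean
  over path-node pairs keeps the value in [0, 1] at every path length.
* **Degenerate inputs**: characteristic path length and eccentricity are
  computed over finite distances only (with a logged warning) because 20%
  thresholding can disconnect graphs; a fully isolated node has NaN
  eccentricity. Assortativity (Pearson correlation of endpoint strengths over
  edges, both orientations) is NaN on strength-regular graphs. NaN is the
  sentinel throughout; imputation happens downstream, never inside metrics.
* **Small-world propensity**: `phi = 1 − sqrt((ΔC² + ΔL²)/2)`, with
  `ΔC = (C_latt − C_obs)/(C_latt − C_rand)` and
  `ΔL = (L_obs − L_rand)/(L_latt − L_rand)`, each clamped to [0, 1] and
  guarded when a denominator vanishes (Δ = 0 if the numerator is ≤ 0, else
  1). The lattice null re-places the observed weights on a ring (strongest
  weights at the shortest ring distances); the random null places them on
  uniformly random pairs. Ten null instances per type are averaged by
  default; a ring lattice evaluates to ≈ 1 − sqrt(1/2) ≈ 0.293 as expected.
* **Core–periphery**: two-block partition maximising
  Σ (w − w̄) over pairs touching the core minus the same sum over
  periphery-periphery pairs (w̄ = mean off-diagonal weight). Seeded
  steepest-ascent single-node flips from 22 starts; quality-neutral flips are
  accepted only when they grow the core, so fully tied landscapes (complete
  graphs) resolve to the all-core solution and a star resolves to its centre.

The battery totals 20 measures (9 node, 3 edge, 8 global); the count is
exposed as `metrics.N_MEASURES`.

## Feature assembly

Five feature families per modality: `raw` (vectorised upper triangle of the
thresholded matrix), `global` (8 columns), `node` (9·n columns), `edge`
(3·|E| columns over the union of edges present in any subject, zero where a
subject lacks the edge), `local` (node ∥ edge) and `global_and_local`.
`CC` concatenates the SC and FC blocks column-wise. Every column carries a
(modality, measure, element) label; the mapping is bijective. NaN sentinels
pass through assembly and are imputed with **training-fold** column means
inside cross-validation; constant columns are dropped at fit time, again per
training fold, so no statistic ever leaks from held-out subjects.
Standardisation (zero mean, unit sd per column) is on by default before PCA —
the measures live on wildly different scales — and its parameters are stored
so held-out folds are transformed with training parameters only.

## SWR-PCR

PCA retains every rank-supported component of the centred, standardised
design (no variance cutoff: the stepwise stage is the filter). The stepwise
search is bidirectional and greedy: from the intercept-only model, every
single addition and removal is evaluated and the move with the largest
*strict* BIC decrease is applied; ties go to the smaller model, then the
lower component index; the search also refuses additions that would make the
parameter count reach the sample size. BIC is the Gaussian profile-likelihood
form `n ln(RSS/n) + k ln(n)` with k counting intercept and slopes (the error
variance is profiled out consistently, so only differences matter; RSS = 0
returns a large negative sentinel with a warning). Because centred PCA scores
are exactly orthogonal, the RSS of any subset is the centred TSS minus each
selected component's independent contribution — the search is exact and fast.
Back-projection multiplies the selected loadings by the PC coefficients;
PC-space and feature-space predictions agree to machine precision, which the
tests assert at 1e-10.

A forward-only variant is available (`bidirectional=False`); bidirectional is
the default.

## Validation

**BBC-CV.** K = 10 folds by default, stratified by outcome quantile, seeded.
The whole pipeline (imputation → constant-drop → standardise → PCA →
stepwise) is refitted inside each training fold. Pooled out-of-fold
predictions are resampled B = 1000 times (bootstrap over subjects); each
resample is scored on its out-of-bag complement, and the corrected estimate
is the bootstrap mean. This is the bias-corrected *performance estimation*
use of the procedure; no configuration selection is performed (one
configuration per feature set), which is the one deliberate departure from
the more general protocol.

**Permutation test.** The pooled predictions are re-paired with permuted
outcomes and R² recomputed; null values at least as high as the observed
statistic count against the model. The add-one correction
`p = (1 + exceedances)/(1 + n_perm)` keeps p strictly positive (the plain
proportion is available by flag). Permutation operates on the pooled
predictions once, not per bootstrap resample.

**Contrasts.** ΔBIC = BIC(M1) − BIC(M2), positive favouring M2, banded 1–3 /
3–20 / 20–150 / >150 (weak / positive / strong / very strong); |Δ| < 1 is no
meaningful evidence. The Wilcoxon rank-sum test on bootstrap R² distributions
uses midranks, tie-corrected variance and a continuity correction; Z > 0
means the first sample is stochastically larger. The asymptotic p tracks
exhaustive enumeration to within 0.02 for sample sizes from about 3+3
upward; below that the exact null is too granular (steps of 1/6) for any
smooth approximation, which the test suite makes explicit. Whether to gate
contrasts on both models beating chance (permutation p < .05) is caller
policy, not enforced by `compare_models`.

## Synthetic cohorts

The generator produces what the pipeline consumes, not raw images:

* **SC**: a cohort template fixes region sizes (uniform in
  `voxels_per_region`, default 50–200), the edge set (Bernoulli with
  `sc_density`, default 0.35) and per-pair streamline success rates
  (Beta(2, 18), mean ≈ 0.1). Each subject multiplies the rates by a lognormal
  jitter of scale `subject_deviation` (default 0.25) and draws binomial
  counts over the `N_i · S` seeded streamlines, so count invariants hold by
  construction and the expected nonzero fraction equals `sc_density`.
* **FC**: an equal-communality latent-factor model — every region loads
  `h·u_i` (default h = 0.6, ‖u_i‖ = 1, `latent_dim` = 6 factors) so
  `r_ij = h²·u_i·u_j` is a valid correlation matrix with unit diagonal by
  construction; subjects jitter the loading directions; Gaussian noise of sd
  `fc_noise_sd` (default 0.05) is added on the z scale. With one latent
  factor and no noise all off-diagonal |z| coincide — the documented
  degenerate case.
* **Scores**: y = Xβ + ε per domain, where X is the designated planted
  feature set *as computed by the downstream pipeline on the generated
  matrices* (thresholding included), β is supported on `n_signal_features`
  standardised columns (default 5), the signal is rescaled so
  var(Xβ)/var(y) = `planted_r2` in expectation, and ε is i.i.d. Gaussian.
  Ground truth (features, effective coefficients, noise sd) is recorded.

Everything is a pure function of (config, seed): templates, subjects and
scores draw from independent, tagged generator streams, and a written cohort
is byte-identical across reruns.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: empirical streamline-count distributions,
distance-dependent connection probability, hemispheric or modular anatomy,
realistic FC spectral structure, site/motion artefacts, and any
correspondence to a specific atlas. The generator's purpose is invariant
satisfaction and a recoverable ground truth, not distributional realism.

## Problem sizes used in the tests

The oracle suite checks all deterministic measures against exhaustive
enumeration on 100 random connected graphs of 4–8 nodes (unique shortest
paths almost surely, so path-dependent measures are well defined). The
cross-validation honesty and permutation-calibration simulations run on
200-subject cohorts at a 16-region parcellation — the generator's default
conditions otherwise — with 50–200 replicates. The stepwise-recovery
simulations use a 6-component candidate pool, the smallest that contains the
planted component indices (1 and 5); with larger pools the expected
intercept-only rate under pure noise decays like (1 − P[χ²₁ > ln n])^p, which
is a property of BIC selection itself, not of this implementation. The
end-to-end smoke test runs 60 subjects at 20 regions.

## Known limitations

* Stepwise-BIC PCR overfits when the candidate-component count approaches the
  sample size (large `local`/`global_and_local` sets at small n): in-sample
  BIC keeps improving while out-of-sample R² collapses. BBC-CV reports this
  honestly (strongly negative corrected R²); it is a property of the method.
* Out-of-sample recovery of planted signal is bounded well below the planted
  variance share on sparse thresholded connectivity: on 200-subject cohorts
  with planted R² = 0.3, even an oracle regression on the true columns
  attains only ≈ 0.25 and the full learner ≈ 0.13–0.15.
* The core–periphery and community searches are seeded heuristics; on large
  graphs different seeds may return different local optima (sizes agree on
  the small graphs the tests exercise exhaustively).
* Graphs disconnected by thresholding use finite-distance conventions; there
  is no connectedness repair.
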