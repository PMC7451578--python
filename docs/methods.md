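# Methods

`eigenalign` compares groups of weighted functional-connectivity
matrices through the geometry of their dominant eigenvectors. This note
records the model, the numerical conventions, and the design decisions a
maintainer or reviewer would want spelled out.

## The pipeline

Each subject contributes one square, symmetric, zero-diagonal matrix of
ROI-to-ROI connectivity weights (Fisher z-transformed correlations in
the intended application). The per-subject chain is:

1. **Cluster-span threshold (CST).** Binarizing at a cutoff t keeps
   edges with w ≥ t. A *triple* is a centre node with two distinct
   neighbours; it is *clustered* if the neighbours are adjacent (each
   triangle yields three clustered triples) and *spanning* otherwise.
   The CST is the cutoff at which clustered and spanning triples
   balance. Surviving edges keep their weights; only the selection step
   binarizes.
2. **Spectral embedding.** The k most dominant eigenpairs of the
   thresholded matrix — dominant by eigenvalue magnitude — define a
   Euclidean frame; node i's position vector is row i of the n×k
   eigenvector block. Default k = 3: two eigenvectors are too few to
   express more than one contrast of community structure, while four or
   five dilute the frame with low-influence modes.
3. **Scaling.** In the default `cdi` convention the first eigenvector is
   stretched so its largest entry equals the largest absolute entry of
   the remaining k−1 eigenvectors (`multiplier` scans around that
   convention, e.g. ±20%). `unit` leaves all eigenvectors at unit norm.
   The same scaled frame is used for both the community detection and
   the alignment angles, since both views are presented in one frame;
   `unit` is available as an explicit knob because the scaling is only
   *defined* in the community-detection context and a user may
   legitimately want raw-frame angles.
4. **Alignment angles.** For nodes with position vectors r, s the
   alignment is θ = arccos(r·s / |r||s|) ∈ [0, π]; smaller is more
   aligned. The cosine is clamped to [−1, 1] (parallel vectors overshoot
   by ~1e−16). A node with no surviving edges has an exactly-zero
   position; it is nudged to (1e−12, 0, …, 0) and flagged isolated so
   every pair has a defined angle.
5. **Eigenvector centrality (EC).** The unit-norm, sign-fixed dominant
   eigenvector; non-negative on a connected non-negative matrix. EC is
   scaling-invariant by construction.
6. **Communities of dynamical influence (CDI).** Leaders are nodes
   strictly farther from the frame origin than every neighbour; each
   remaining node joins the leader, within its own connected component,
   whose position vector gives the largest dot product with its own;
   communities are ranked by their maximum member EC. The procedure is
   deterministic: identical input always yields identical partitions.

## Group statistics

All group contrasts use Welch's unequal-variance t test (two-sided),
the appropriate choice for small samples of unequal size — typically
ten subjects against hundreds of null models. No multiple-testing
correction is applied; instead false positives are screened by a
**random-model filter**: a ROI pair enters a group-vs-group alignment
comparison only if at least one of the two groups differs from matrices
of iid U(0, 1) weights (Welch p ≤ α, OR over the two groups) in *every
one* of several independently generated null sets (default three sets;
1000 models each at full scale, 200 in the fast mode). Null matrices
run through the *identical* pipeline as subjects, CST included; a
`use_cst=False` switch embeds the raw weights instead, since one could
also read the null construction as unthresholded. This is a screening
heuristic, not an error-rate guarantee — a statistical caveat users
should keep in mind.

Direction vocabulary: an *increase in alignment* is a decrease in θ
for the first group relative to the second. Per-ROI change counts are
row sums over significant pairs, so their total is twice the number of
significant pairs.

Group-vs-null comparisons use subject-level angle samples (n ≈ 10) per
pair against the R null angle samples; that asymmetry in sample size is
exactly why Welch df is used.

The ROI-substitution experiment replaces one region's row and column in
each host subject with a donor subject's (symmetry and zero diagonal
preserved), pairing subjects by manifest order (a `pairing` argument
permutes it). It isolates the marginal effect of one region's
connectivity change from everything else that differs between groups.

## CST selection: the normalized objective

Exact equality of the integer counts is rarely attainable, so the
selected cutoff minimizes the normalized imbalance
|clustered − spanning| / total over admissible candidates (those with at
least one triple), ties toward the smaller cutoff (denser graph, less
disconnection before the spectral step). Two refinements matter in
practice, and both were adopted after measuring the alternatives on
random weighted matrices:

* **Normalization.** The raw count difference |clustered − spanning| is
  minimized trivially by near-empty topologies (a lone open triple
  scores 1), so an absolute objective drifts to the extreme sparse tail
  of the weight distribution (cutoffs ≈ 0.99 on U(0, 1) weights).
  The normalized objective targets the density at which half of all
  triples close — on iid U(0, 1) weights that is a cutoff of ~0.5,
  where triangle-closure probability is one half.
* **Truncation at the balance crossing.** The scan walks candidates in
  ascending order and stops once a clustered majority has given way to
  a spanning majority: beyond that crossing only sparse-tail topologies
  remain, which occasionally tie the objective at 0 by small-count luck
  (three clustered vs three spanning triples on six edges) without
  carrying any information about the network's balance.

The candidate set is every distinct strictly-positive weight (negative
weights are scanned as-is and can never survive a positive cutoff; they
are deliberately not absolute-valued). A matrix in which no candidate
produces a triple has no meaningful CST and raises a degenerate-topology
error.

## Numerical conventions

* **Eigen-ordering.** Eigenpairs sort by descending |λ|; magnitude ties
  break toward the larger algebraic eigenvalue, then the smaller
  original index. The magnitude comparison uses a relative tolerance of
  1e−12: bipartite-like topologies have ±λ pairs equal only up to float
  rounding, and the positive (Perron) member must come first
  deterministically rather than by the sign of rounding noise.
* **Sign convention.** Each eigenvector's largest-magnitude entry is
  made positive. Downstream results are sign-flip invariant (tested);
  the convention only makes serialized embeddings reproducible.
* **Degenerate spectra.** A near-zero gap between |λ_k| and |λ_k+1|
  flags the embedding as basis-dependent (`degenerate=True`); a
  disconnected thresholded topology sets `disconnected=True`. Both are
  warnings, not errors.
* **Leader strictness.** "Farther than every neighbour" is evaluated
  with a relative tolerance of 1e−12; embeddings of symmetric graphs
  place nodes at distances equal up to ~1e−16, and such ties must fall
  through to the deterministic fallback (promote the component's
  farthest node, lowest index on ties, set the degeneracy flag) rather
  than be decided by rounding.
* **Zero-position repair.** Rows with norm below 1e−100 count as zero:
  the symmetric eigensolver emits denormal noise (~1e−300) on
  degree-zero nodes, and the squared norm of such a row underflows to
  exactly 0 downstream.
* **"Lies on a path to the leader"** is implemented as same-connected-
  component reachability — the weakest faithful reading. A greedy
  edge-wise community growth would differ only in multi-leader
  components; the component-wide reading keeps assignment independent
  of traversal order.
* **Community-size tests.** When every subject in each group shows
  exactly the same size and the two values differ, the Welch statistic
  is undefined; the comparison reports the difference as exact
  (p = 0, infinite t) rather than erroring.

## The synthetic cohort generator

`CohortSpec`/`generate_cohort` emulate the gross structure of
resting-state connectivity cohorts; `bilateral_study_spec` is the
reference 20-ROI configuration used by the test bench and the
acceptance script. What it emulates:

* **Bilateral (homotopic) pairs** — left/right instances of the same
  area, coupled strongly (0.85 in Fisher-z-like units) in health.
* **Functional modules** — blocks with elevated within-block coupling
  (0.45) over background (0.2), three modules of six regions, each
  anchored by one homotopic pair.
* **Anatomical heterogeneity** — per-edge uniform jitter (±0.25) drawn
  once from a template seed shared by all cohorts of a study. This is
  essential, not cosmetic: without it homotopic partners inside one
  block are exact graph twins, and twins remain perfectly aligned no
  matter what happens to their direct edge, because alignment reads
  coupling *profiles*. No two real brain regions have identical
  profiles.
* **Disease** — a fractional reduction δ of selected homotopic
  couplings (δ = 0.8 in the degraded study condition, applied to one
  pair), emulating focal loss of interhemispheric connectivity.
* **Subject noise** — additive Gaussian noise (SD 0.08), symmetrized by
  averaging, clipped to [−1, 1].

Block strength, jitter and noise were chosen together so that the
healthy template supports the mechanism the method relies on: the three
module contrasts fill the top-3 eigenvalues with large positive values,
which keeps the antisymmetric mode of a strongly coupled pair *out* of
the frame. This matters because the matrices are thresholded
correlation-like networks: if the pair's antisymmetric mode (eigenvalue
≈ −ρ) entered the top-k by magnitude, a strong direct coupling would
*anti*-align the pair — the opposite of the empirical behaviour of
dense correlation networks, whose top eigenvalues are positive and
large.

What the generator does **not** emulate: BOLD time series, hemodynamic
or autocorrelation structure, the Fisher transform itself, global
signal effects, negative-weight structure, or realistic atlas-scale
(n = 132) heterogeneity. Passing tests therefore demonstrate that the
machinery recovers planted structure under controlled conditions, not
that it would behave identically on real imaging data.

## Problem sizes in the test bench

The acceptance checks run at desk scale: 20-ROI cohorts of 10 + 10
subjects, null screens of 3 × 200 random models, and 20 replicate
studies; the threshold and triple-count oracles sweep hundreds of random
graphs at n ≤ 15. The full-scale screen (3 × 1000 models at n = 132) is
the library default in the CLI and runs in minutes; the reduced screen
is used for the replicated studies, mirroring the reduced-model
experiment in which a 200-model screen already reproduces ~90% of the
pairs a 1000-model screen selects.

## Known limitations

* The random-model filter controls false detections only heuristically;
  pairs whose genuine group difference fails the null screen are lost
  (the screen may obscure real changes).
* CDI on near-symmetric graphs depends on the degeneracy fallback;
  partitions are then deterministic but arbitrary within the tie.
* Angles from near-degenerate eigenvalue gaps at position k are
  basis-sensitive; the embedding flags this but proceeds.
* Secondary realignments are intrinsic: removing one strong coupling
  repositions its endpoints and measurably shifts their angles to third
  parties. The filtered comparison reports those shifts as significant
  when subject noise is small — they are real effects of the planted
  change, not false positives in the statistical sense, but they bound
  how "local" any edge-level intervention can appear.
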