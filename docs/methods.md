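# Methods

## Data model

A dataset is n genomic bins × m samples. Bins are half-open 0-based
intervals; within a chromosome they are sorted by start, chromosomes are
kept in first-appearance order of the input file, and every bin must be
present in every sample (missing or NaN signal is rejected rather than
imputed). BAF is mirrored onto [0, 0.5] on load, since the analysis views
only allelic imbalance (0.5 − BAF). Cluster labels are integers ≥ −2 with
−1 meaning "not clustered" and −2 "erased"; erased bins are dropped from
exports and excluded from every analytic.

The input dialect names no sample column, so `cnaseg` accepts an optional
`SAMPLE` column; without it the number of samples is inferred from the
repeat count per genomic position and sample identity is assigned by
within-position row order. This keeps single-sample files minimal while
making multi-sample files deterministic.

## Segmentation

Bins are embedded in 2m dimensions (m RDR values, then m BAF values, native
scales — no standardization by default, because the centroid-threshold
editing semantics are defined on raw RDR/BAF gaps; a z-scaling flag would
change those semantics silently).

**Global stage.** A k-component Gaussian mixture is EM-fitted to the
feature vectors (scikit-learn), diagonal covariances by default — RDR and
BAF noise scales differ by an order of magnitude and full covariance
overfits at small k; `covariance_type="full"` is exposed. Initialization is
k-means++ from the caller's seed with 10 restarts keeping the best
likelihood, `reg_covar = 1e−6` guarding degenerate components, at most 200
EM iterations. Bins take the maximum-responsibility component;
responsibility ties (measure-zero in practice) resolve to the lower
component index via first-argmax. `select_k` scans a k range and minimizes
BIC, for unattended runs where k is not known a priori.

**Local stage.** A hidden Markov model with one state per fitted component,
the component Gaussians as emissions, uniform initial distribution, and a
fixed sticky transition matrix: self-transition τ, off-diagonal
(1 − τ)/(k − 1). τ defaults to 0.99 per 50 kb bin, encoding that CNAs span
many consecutive bins; transitions are deliberately *not* re-estimated —
the HMM is a decoder for the globally fitted mixture, not a second model.
Viterbi decoding (hmmlearn) restarts at every chromosome boundary, so
chromosomes never constrain one another. At τ = 1/k the chain is memoryless
and decoding reduces to per-bin maximum-likelihood component assignment;
k = 1 returns the trivial labeling without invoking the decoder.

**Hybrid.** Global fit, then local decode. The global stage supplies
genome-wide component definitions robust to noise; the local stage smooths
isolated misassignments whose emission advantage is smaller than the
2·ln((k−1)τ/(1−τ)) transition penalty.

## Editing semantics

Merging flags a cluster pair when, in **every** sample, the absolute
centroid gaps satisfy |ΔRDR| ≤ t_RDR(p) and |ΔBAF| ≤ t_BAF(p) — a
per-dimension box test, not a pooled Euclidean one. Flagged pairs chain
into connected components; in each component the cluster with the most bins
(ties: lowest ID) keeps its label. Absorption differs by design: a From-bin
considers the To-centroids plus its own, picks the **Euclidean-nearest**
candidate in 2m dimensions, and moves only if that candidate is a To
cluster other than its own and the per-sample gaps to it pass the same box
test. A bin nearest its own centroid is held ineligible. Centroids are
frozen when a call starts, making reassignment order irrelevant within one
call; cascading is achieved by calling again.

"Next cluster ID" is max-in-use + 1 (or 0), never the smallest unused ID,
so an ID the user previously emptied is not silently recycled. Every
operation records the affected indices with previous and new labels;
replaying the log from the initial labels reproduces the final clustering
exactly, and undo pops the last entry.

## Analytics

Exact silhouettes cost O(n²) and n is ~50,000 in realistic data, so
`silhouette_by_cluster` subsamples uniformly without replacement (default
cap 2,000 bins, seeded) and computes silhouettes within the subsample;
a cap ≥ n reproduces the exact values to machine precision. Subsampled
singleton clusters score 0 by the usual convention; clusters absent from
the subsample report NaN rather than a fabricated value. Inter-cluster
distance defaults to the mean over all cross pairs of member bins
(subsampled per cluster) with a centroid-to-centroid option.

## Copy-state inference

The expected-signal closed forms are the standard normal-contamination
mixture: a fraction μ of cells carry (a, b) and 1 − μ are normal diploid
(1,1), with RDR normalized by the sample's average copy number
μρ + 2(1 − μ). They reproduce the canonical anchors — (2,1) at μ = 1 gives
BAF 1/3, (3,0) gives 0, (1,1) gives 0.5 at every μ. State (0,0) at μ = 1 has
no DNA and its BAF is a domain error; during grid search such states are
assigned infinite residual rather than raising.

State assignment enumerates all (a, b) with a ≥ b ≥ 0 and a + b ≤
max_total (default 6, bounding the grid while covering the common clonal
states) and minimizes the squared (RDR, BAF) residual summed over samples;
exact ties prefer the smaller total, then the larger minor count. The grid
scan scores each (μ, ρ) by the member-count-weighted minimized residual.
States become unidentifiable as μ → 0 (all expectations collapse toward
(1, 0.5)); round-trip tests document exact recovery of every state at
μ ≥ 0.6 with ploidy 2. All-diploid data make purity unidentifiable (score
≈ 0 everywhere); the scan warns in that case. Applying one (μ, ρ) to all
samples is the default; a per-sample mode scans one sample's centroid
columns alone, which is appropriate when purities differ across samples.
Gene classification votes per overlapping bin on total copies against the
fixed diploid baseline 2 — whole-genome-duplication-aware baselines are out
of scope — so copy-neutral LOH (2,0) counts as unaffected; mixed votes take
the bin-count majority, exact ties return "ambiguous".

## Evaluation

ARI, V-measure and exact silhouette are delegated to scikit-learn behind a
validating surface; the test suite checks them against brute-force pair
enumeration and hand-computed entropies. Bins are weighted equally, not by
genomic span. Zero-entropy V-measure conventions follow continuity
(single-cluster truth ⇒ homogeneity 1, and symmetrically).

## Simulator

The generator emulates multi-sample bulk sequencing of a clonal tumor. The
genome (default 2 chromosomes × 250 bins of 50 kb) is cut into contiguous
segments (default 20, never crossing chromosomes); each tumor clone gets an
integer state per segment, shared across clones with probability
`fraction_shared` (default 0.6) and clone-specific otherwise, drawn
uniformly from {(a, b) : a ≥ b ≥ 0, 1 ≤ a + b ≤ max_total} — (0,0) is
excluded so every clone retains DNA everywhere and noiseless expectations
are defined at purity 1. Each sample mixes the clones with normal cells at
its purity (defaults 0.6 and 0.8); the default clone proportions tilt
sample p toward clone p mod n_clones deterministically, so distinct clones
dominate distinct samples and the samples are jointly informative. Clone
ploidy is the clone's own bin-weighted mean total, keeping RDR
normalization internally consistent.

Expected signals generalize the state closed forms to multiple clones by
DNA-mass averaging. Observed RDR adds Gaussian noise (sd 0.05, truncated at
0); observed BAF is Binomial(coverage, E[BAF])/coverage with default 500
SNP reads per bin, respecting the [0, 0.5] support and coverage dependence,
then mirrored. Ground-truth cluster labels are the tuple of clone states at
a bin's segment, so segments with identical tuples share a label — exactly
the premise of global segmentation.

What the simulator does **not** model: whole-genome duplication, clone
phylogenies deeper than a star, GC/mappability bias, replication-timing
waves, and read-level artifacts. Passing recovery tests therefore shows the
algorithms are correct under clean clonal mixtures, not that they are robust
to every systematic bias of real sequencing.

## Problem sizes and seeds

Default test and acceptance problem sizes (500 bins × 2 samples, 200
metric replicates at n = 1000) were chosen as the smallest instances at
which the studied effects are comfortably resolvable on a laptop; all
stochastic paths take explicit seeds and identical configurations produce
byte-identical outputs.

## Known limitations

- Sample identity without a `SAMPLE` column rests on within-position row
  order; files that reorder samples between positions are misread silently.
- The HMM transition stickiness is a single global τ; no distance-dependent
  or learned transitions.
- State calling fits one clonal state per cluster; subclonal (fractional)
  mixtures within a cluster are not decomposed.
- The silhouette subsample is uniform, so very small clusters may be missed
  at aggressive caps (reported as NaN, never imputed).
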