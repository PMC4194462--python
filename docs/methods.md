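# Methods notes

This note records the model choices, numerical conventions and known
limitations behind the package, in the order of the workflow.

## Similarity measures

All three measures map a pair of expression profiles to [0, 1] over their
pairwise-complete observations (cells missing in either profile are
dropped per pair). Any pair with fewer than 3 complete observations — or a
constant profile — yields similarity 0 with a warning rather than an
exception, so that full-matrix computation never aborts on sparse rows.

**APCC** is |Pearson r|; it is invariant under affine transforms with
non-zero slope and sees only linear dependence.

**NCMI** estimates the mutual information Î of the pair from an equal-width
B × B histogram and maps it to [0, 1] by the global correlation coefficient
λ = √(1 − e^(−2Î)), the exact Pearson-|r| analogue for bivariate Gaussian
dependence. Two estimator choices matter:

* *Bin count.* `bins="auto"` uses B = max(2, ⌊√(n/5)⌋), i.e. about five
  observations per joint cell. One-dimensional rules (Sturges and kin)
  overbin a two-dimensional histogram: at n = 100 samples, B = 8 gives a
  plug-in bias of ≈ (B−1)²/2n ≈ 0.25 nats, which alone inflates λ to ≈ 0.6
  for independent profiles. With the square-root rule, independent pairs
  average λ ≈ 0.1.
* *Debiasing.* The plug-in estimate is corrected by the Miller–Madow term
  (K_xy − K_x − K_y + 1)/2n (occupied-cell counts) and floored at zero.
  The floor means λ = 0 exactly for many truly independent pairs, which is
  the desired reading of "no dependence".

Fewer than 2B complete observations reduce B with a warning. NCMI is
invariant under strictly monotone transforms of either profile only up to
binning error; the tests check this with a loose tolerance.

**NMRS** range-normalises each profile to [0, 1] over the common positions
(x̂ = (x − min)/(max − min)) and returns 1 − mean|x̂ − ŷ|. It is exactly
invariant to additive shifts and positive scalings, which is what makes it
sensitive to shifted co-expression patterns; a zero-range profile yields 0
with a warning.

## Threshold selection

The grid is fixed at 0.01 … 0.99, step 0.01, with no adaptive refinement:
the selection semantics ("first grid value whose |C − C_r| strictly exceeds
the next one's") are only reproducible on a fixed grid. Boundary
conventions: C := 0 when no node has degree > 1, and C_r := 0 when the
graph has no connected node, so |C − C_r| is defined at every grid point
(including empty and near-empty graphs at high τ). The strict inequality
means plateaus are skipped; on a monotone non-decreasing curve the global
argmax is returned with a warning. An all-zero curve raises an error
("degenerate similarity matrix"), which a single isolated high-similarity
pair can trigger: a one-edge graph has C = C_r = 0.

C_r uses connected nodes (k ≥ 1) only, in the degree mean, the squared
degree mean and N. For a k-regular graph the formula collapses to
(k−1)²/(kN), which the tests verify to 1e−12.

The scan is computed sparsely: the upper-triangle similarities ≥ 0.01 are
sorted once, and each grid point rebuilds a CSR adjacency and counts
triangles via (A·A)∘A. This is fast for the embedded validation matrices
(which are sparse by construction) and for thresholded expression data of a
few thousand genes.

Taking the *absolute* difference |C − C_r| rather than C − C_r is the one
methodological modification to the classical clustering-coefficient rule:
highly heterogeneous networks (degree CV ≈ 3) sit in a C < C_r regime over
the whole scan, where the unsigned rule has no signal. The recovery
experiments below exercise exactly this regime.

## Simulated networks and the embedded-threshold validation

`simulate_network` draws a deterministic degree sequence by inverse-CDF at
mid-point quantiles of a discrete truncated power law P(k) ∝ k^(−γ)
(γ = 2 by default), with the truncation point tuned by scan so the
sequence's CV(k) matches the target. The sequence is realized *exactly* by
Havel–Hakimi construction and then randomized by degree-preserving double
edge swaps; clustering is subsequently tuned toward the target C by greedy
degree-preserving swaps with incremental triangle bookkeeping (default cap
20,000 proposals, tolerance 0.005). Because every step preserves degrees,
the realized CV equals the tuned sequence's CV; targets missed by more
than 15 % (CV) or 0.05 (C) produce a warning with the realized values.
A configuration-model construction was rejected: erasing its multi-edges
truncates hubs and loses up to 15 % of the target CV at n ≤ 1000.

`embed_similarity` builds a similarity matrix whose thresholded network at
a planted τ_true is exactly a given graph G (this holds by construction and
is tested bitwise). The non-trivial part is what happens *below* τ_true.
An iid similarity band below the threshold produces a dense, unstructured
graph at low τ whose |C − C_r| ≈ 3p/n *decreases* along the scan, so the
first-local-maximum rule would fire at τ = 0.01 regardless of the planted
threshold. Real similarity matrices do not behave like that: similarity is
transitive (if i~j and j~k are strong, i~k tends to be), which keeps C well
above C_r while the graph thins, producing the characteristic monotone
growth of the contrast up to the true threshold. The embedding therefore
plants that qualitative shape explicitly:

* edge pairs receive uniform order statistics on [τ_true, 1], assigned so
  that hub-hub edges carry the smallest values — thinning above τ_true then
  reduces degree heterogeneity first, so the contrast declines after the
  plateau;
* a bounded set of non-edge pairs receives similarities on 12 evenly spaced
  levels below τ_true − δ (δ = 0.02 by default). These "noise" pairs form a
  matching over the lowest-degree nodes with no shared neighbours (so they
  create no triangles and their removal is smooth), levels are assigned
  round-robin over the degree-sorted pairs (so each removal batch has the
  same composition), and the total mass is capped — by direct evaluation —
  so that |C − C_r| keeps the sign it has on G and stays below its value on
  G throughout the sub-threshold scan;
* all remaining pairs get similarity 0.

Within each level the curve is exactly constant, so the strict
first-local-maximum scan walks through the floor without firing and
triggers on the first decline past the plateau at τ_true. The recovery
error η = mean|τ̂ − τ_true| is ≈ 0–0.001 across the three validation groups
(CV(k) = 2.86, 1.00, 3.10 at C = 0.02, spanning both the C < C_r and the
C > C_r regime), and grows gracefully as the gap δ shrinks.

The validation uses networks of 1000 nodes and 50 replicates per planted
threshold — large enough that the clustering statistics are stable, small
enough that the full three-group experiment runs in about three minutes on
one CPU.

What this validation does and does not show: it demonstrates that the
selection rule finds a planted threshold when the similarity matrix has
the growth-then-decline contrast shape; it does not model microarray noise
(probe effects, batch structure), and on small matrices (≲ 100 genes) with
many unstructured background pairs the early scan is noise-dominated and
the rule can fire at a very low τ. The method's intended regime is
matrices of hundreds to thousands of genes with genuine co-expression
structure.

## Planted expression modules

Each module derives from one latent N(0, 1) sample profile z. `linear`
genes are positive scalings of z; `inverted` genes alternate sign so
within-module pairs are strongly anti-correlated (|r| ≈ 1, detected by
APCC); `quadratic` genes alternate between a·z and a·(z² − 1), so
linear-vs-quadratic pairs have Pearson ≈ 0 (corr(z, z²) = 0 for symmetric
z) while mutual information remains high — the fixture behind the
non-linear-detection contract; `shifted` genes are z plus a per-gene
additive offset, the pattern NMRS is built for. Gaussian noise (default
sd 0.1 on a unit-variance signal) and a baseline of 8 (log2-like scale)
are added; genes outside modules are independent noise.

## Graph variables

* **Centralization** is Freeman centralization of pair-normalised
  betweenness, Σ(b'_max − b'_i)/(N − 1): 1 for a star, 0 for any
  vertex-transitive graph. Disconnected input is reduced to its largest
  component with a warning.
* **Assortativity** (AsG/AsP) is Newman's nominal coefficient on one
  categorical label per node. Set-valued GO/PFAM annotations are reduced to
  the node's most frequent term within the network (ties lexicographic);
  unannotated nodes share a common "none" label. A single label across the
  network leaves the coefficient undefined → 0 with a warning.
* **Attack tolerance** removes the ⌈0.05·N⌉ highest-degree nodes in one
  batch (ties by lexicographic node id, so the attack is deterministic) and
  returns L(G)/L(G′) over largest components; 0 if no connected pair
  survives. Single-batch removal (not iterative recomputation) is the
  simplest faithful version of the targeted-attack protocol.
* **KI** is the point-biserial (= Pearson) correlation between degree and a
  user-supplied boolean domain flag; undefined cases (single class, zero
  degree variance) give 0 with a warning.

A note on size dependence: the intensive variables (CC, Het, KI) are stable
across network sizes at fixed generative parameters, and the test suite
guards this. Den, Cen and Tol are *mechanically* size-coupled when the
degree distribution is held fixed (e.g. Den ≈ k̄/(n−1)); in a heterogeneous
collection of real networks this coupling is diluted by between-network
variation, but it should be kept in mind when interpreting the PCA of a
collection with a wide size range.

## PCA and clustering

PCA is computed on the correlation matrix (columns z-scored with sample
sd), since the eight variables have incommensurate scales; zero-variance
columns are dropped with a warning. Component signs are fixed by making the
largest-magnitude loading positive, so results are deterministic. The
variable–component correlations (correlation circle) are
eigenvector·√eigenvalue, clipped to [−1, 1].

K-means uses squared Euclidean distance with k-means++ seeding, best of
`n_starts` (default 100) runs per k, all seeded through one
`random_state`. BIC(k) = n ln(W_k/n) + k ln n. The default selector is the
elbow (largest second difference of the BIC curve); plain BIC minimisation
is exposed as an alternative but is not useful for k-means: W_k shrinks
like k^(−2/d) on unclustered data, so the likelihood term always outruns
the k ln n penalty and the minimum sits at k_max. Three retained components
are the default for single-experiment collections, two for merged-network
collections (configurable).

## Expression-matrix preparation

Probe collapsing drops probes mapping to more than one gene, then takes the
element-wise per-sample maximum over a gene's probes (missing ignored;
all-missing stays missing). A "max-mean" mode (keep the probe with the
highest mean) is available, since "maximum expression" is ambiguous; the
element-wise reading is the default. The missing-data filter removes, in
this order, samples covering < 50 % of the common gene list, then genes
observed in < 75 % of the remaining samples. Merging aligns experiments on
the intersection of their gene sets by default (a union mode exists) and
tags sample ids with experiment labels; values are never re-normalised —
inputs are expected to be already normalised, log2-scale matrices.

## Limitations

* Exact NCMI/NMRS variant definitions differ across the literature; the
  implementations here follow the definitions above and are validated
  against their stated contracts, not against any external reference
  implementation.
* The embedded-similarity validation plants the curve shape the selection
  rule assumes; it validates the selector, not the similarity step.
* The pipeline consumes preprocessed matrices; normalisation, background
  correction and differential-expression screening are upstream concerns.
* Attack tolerance and centralization are O(N·E); for networks beyond
  ~10⁴ nodes the characterization step dominates runtime.
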