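# Methods

This note describes the models and numerical choices behind `schic`, what
the synthetic-data generator does and does not emulate, and the known
limitations of each method.

## Data model

A container holds one genome binning (ordered chromosomes, fixed bin size,
0-based half-open bins; the last bin of a chromosome may be short) and an
ordered collection of per-cell sparse upper-triangular pixel tables
`(bin1_id, bin2_id, count)` with `bin1_id <= bin2_id`. A cell's
`total_reads` is the plain sum of stored pixel counts — diagonal pixels are
not halved and off-diagonal pixels are not doubled — which makes QC
thresholds unambiguous and additive under pooling. The on-disk twin is the
scool HDF5 layout (cooler v3 field names; one root `chroms`/`bins` table,
`cells/<id>/pixels` + `indexes` per cell, exactly one resolution per file).
Writes are deterministic: no timestamps, pixels in canonical order, cells in
container order (HDF5 link-order tracking preserves it).

## Quality control

Sparsity is the fraction of *possible intra-chromosomal* upper-triangle
pixels (diagonal included) that are non-zero. Inter-chromosomal pixels are
excluded from the denominator because trans signal in scHi-C at coarse
resolution is dominated by noise and every downstream method here operates
per chromosome. A cell passes if `total_reads >= min_reads` (default
100 000, strictly-below cells discarded so the boundary cell survives) and
`sparsity >= min_density`. There is no defensible universal sparsity
cutoff, so `min_density` defaults to 0 (disabled) and must be opted into.
A cell failing both checks reports `low_reads`: coverage is checked first
because a low-coverage cell's sparsity is not interpretable.

## Normalization and balancing

Depth normalization multiplies each cell by (minimum total / own total); it
is idempotent and order-independent. Range normalization divides one matrix
by its maximum; scale normalization multiplies by a user factor.

Both balancers seek per-bin factors *b* with corrected values
`A'_ij = A_ij / (b_i b_j)`. Bins whose entire row is zero are masked and
carry NaN bias. ICE is the plain row-sum iteration: each pass divides rows
and columns by their row sum over its mean, until the coefficient of
variation of unmasked row sums drops below `tol` (default 1e-5, max 1000
iterations; non-convergence is reported, not raised). The bias vector is
gauge-fixed to geometric mean 1. No coverage-percentile (MAD) pre-filtering
is applied; masking is purely the all-zero-row rule.

KR balancing targets unmasked row sums of exactly 1 (a doubly stochastic
corrected matrix). It is solved by the damped symmetric fixed point
`y <- sqrt(y / (A y))` (corrected matrix `diag(y) A diag(y)`), iterated
until `max |y * (Ay) - 1| < tol` (default 1e-6). The fixed point converges
whenever the matrix has total support; non-convergence raises an error that
reports the connected components of the support, since a missing diagonal
block is the usual cause. Note that a *disconnected* support is not by
itself unbalanceable — each component balances independently — so
convergence, not connectivity, is the criterion. Because both balancers
satisfy the same balance condition, on an irreducible matrix their
corrected outputs agree up to one global scalar; the tests assert maximum
relative deviation below 1e-4 on random positive 50×50 matrices.

## Dimension reduction

**Raw / PCA.** The raw embedding flattens each cell's upper triangle
(diagonal included) in row-major order: `n_bins(n_bins+1)/2` features,
stored sparsely. PCA mean-centers and takes a deterministic SVD; component
signs are fixed so each component's largest-magnitude loading is positive.
The default component count is `n_bins`, capped at
`min(n_cells, n_features)`.

**Exact kNN.** Euclidean distances, edge weight `1/(1 + dist)`, each row's
k nearest kept (ties broken toward the lower cell index via stable sort),
symmetrized by element-wise maximum, zero diagonal.

**MinHash kNN.** Each cell is reduced to the *set* of its non-zero pixel
indices; count magnitudes are ignored, which makes the similarity robust to
coverage differences. Signatures are minima of
`h_i(x) = (a_i * mix(x) + b_i) mod p` with `p = 2^31 - 1` and `(a_i, b_i)`
from a seeded RNG; the fraction of matching signature slots estimates the
Jaccard similarity (per-slot collision probability = Jaccard). `mix` is a
fixed bijective 64-bit scrambler (the splitmix64 finalizer): without it,
affine mod-p hashes are measurably biased on arithmetically structured sets
(translated sets such as {1,2,3}/{2,3,4} collide too rarely, an ~0.09 bias
that 2000 hashes cannot average away). The default of 800 hashes gives a
per-pair standard error of about `sqrt(J(1-J)/800)` ≈ 0.018 at J = 0.5.
Estimates are used directly to pick each cell's top-k neighbors; no exact
re-ranking of candidates is performed.

**SVL.** Per cell and chromosome, the ratio of short-range
(0 < distance ≤ threshold) to long-range (distance > threshold) contact
sums, diagonal excluded. The default threshold of 2 Mb separates sub-TAD
from long-range scales and is exposed as a parameter. A cell with no
long-range contacts on a chromosome receives a sentinel value (1e12,
flagged in the embedding's params); a chromosome too short to contain any
long-range pixel is flagged degenerate.

**Compartments.** Per chromosome: observed/expected matrix (expected at
distance d = mean over *all* pixels of that diagonal, zeros included;
entries with zero expected stay 0), Pearson correlation of its columns
(zero-variance columns masked to 0), leading eigenvector of the
correlation matrix. The track's sign is oriented so its dot product with
the reference track — the same procedure applied to the pooled bulk matrix
(or a user-supplied reference) — is non-negative. Using the pooled bulk as
reference keeps the tool annotation-free (no GC/gene-density input); it
fixes the A/B orientation only *consistently across cells*, not
biologically. Chromosomes with fewer than 3 unmasked bins yield a
zero-filled, flagged segment.

## Clustering

k-means is Lloyd's algorithm with k-means++ seeding (best of `n_init = 10`
runs under one seeded RNG), stopping when the center shift falls below
`tol`. The per-iteration inertia trajectory of the winning run is recorded;
it is non-increasing, which the tests assert. Empty clusters are re-seeded
at the worst-fit point. A neighbor graph given to k-means is clustered on
its weight rows as features.

Spectral clustering builds `L = I - D^{-1/2} W D^{-1/2}` (isolated vertices
are an error naming the cell), takes the eigenvectors of the K smallest
eigenvalues with a dense symmetric eigensolver — deterministic, no
iterative-solver tolerance needed at these sizes — fixes each eigenvector's
sign (largest-magnitude entry positive), unit-normalizes rows and runs the
seeded k-means above. On a graph with exactly K connected components the
0-eigenspace makes rows constant within components, so the split is exact
for any seed. Labels from both methods are relabeled in first-occurrence
order, making outputs independent of internal label permutations. K is
always user input; no automatic model selection is attempted.

## Summaries

Consensus matrices are pixel-wise sums per cluster, then every consensus is
scaled to the *smallest* cluster total (mirroring depth normalization; the
target is otherwise arbitrary). Decay profiles count contacts per bin
offset d = 0..max_distance/bin_size (50 Mb default, inclusive, diagonal
included) summed over chromosomes, normalized *per cell* to sum 1 — the
profile compares shapes, so per-cell relative frequencies stop coverage
differences from dominating; per-cluster normalization was the alternative
and is intentionally not used. Cells are ordered by cluster label, then
input order. Rendering always writes the numeric table (TSV) beside the
image so every plotted number is inspectable.

## Synthetic populations

The generator emulates the two coarse-scale signals that distinguish scHi-C
populations: contact-decay and compartmentalization. For a cell of cluster
κ, intra-chromosomal pixel (i, j) has sampling weight

    w_ij = (1 + |i - j|)^(-α_κ) * clip(1 ± ε_κ, 0)

(+ for same-compartment pairs, − across), where compartments are
alternating blocks of `compartment_block_size` whose grid is *shifted* per
cluster by `compartment_phase` bins. (Flipping A/B labels instead would
change nothing: a 2-coloring flip leaves every pair's same/different status
invariant, so distinct cluster patterns require shifted grids.) The cell's
reads are placed by one multinomial draw over the normalized weights, so
totals are exact and the container is bit-reproducible given the seed.

Defaults describe the reference simulation used by the tests and the
acceptance script: a 100 Mb genome (60 + 40 Mb chromosomes) at 1 Mb bins,
three clusters × 50 cells, 50 000 reads per cell, α = (0.8, 1.2, 1.6). The
positive condition adds compartment contrast ε = 0.5 — i.e. 1.5×/0.5×
same/cross modulation, the order of polarization real observed/expected
maps show — with grids shifted by (0, 5, 3) bins; the negative control uses
equal α and ε = 0. The estimator-validation fixture (50 cells for the
MinHash oracle) instead uses 5 clusters × 10 cells with widely spread α and
strong, distinctly shifted compartments, so each cell has exactly 9
clearly-similar neighbors and recall@10 measures estimator ranking rather
than biological near-ties.

What the generator does **not** emulate: read-level artifacts (dangling
ends, duplicates), per-bin mappability/GC bias (so balancing on simulated
data is exercised, not stressed), inter-chromosomal contacts, TADs and
loops, allele-level count ceilings, and doublets. Passing tests therefore
validate the pipeline's algebra and its ability to recover decay- and
compartment-level structure, not robustness to every artifact of real data.

## Known limitations

* **Set saturation degrades the MinHash-graph route on small simulated
  genomes.** At 50 000 reads over a 100-bin genome (≈2650 intra pixels) the
  average pixel receives ~19 reads, so cells occupy 75–99% of the pixel
  universe. Binarized Jaccard then suffers a set-inclusion pathology: a
  flat-decay cell's set nearly contains every other cell's set, and
  cross-population similarity can *exceed* within-population similarity
  (measured J(0,1) = 0.91 vs J(1,1) = 0.88 on the reference simulation).
  The kNN graph then wires populations together and no seed or k recovers
  them through the normalized cut (ARI ≈ 0.2) — even though k-means on the
  same similarity *rows* separates them perfectly, confirming the signal
  exists. Real 1 Mb scHi-C sits in the opposite regime (millions of pixels,
  ≪1 read per pixel), where set membership is informative. The acceptance
  script reports the measured ARI as-is.
* ICE and KR are implemented densely per chromosome-scale matrix; they are
  meant for desk-scale and consensus matrices, not 10 kb whole-genome
  balancing.
* The compartment track is a first eigenvector with bulk-referenced sign;
  without an external annotation the global A/B identity (which sign is
  "active") is undetermined.
* `exact_jaccard` is quadratic in cells and linear in set size; it is a
  validation oracle, not the production path (that is what MinHash is for).
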