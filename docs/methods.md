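# Methods

This note records the models, defaults, and numerical conventions behind
`cytoverbs`, and what the synthetic benchmarks do and do not demonstrate.

## Data model

A `CytoTable` is a `pandas.DataFrame` subclass with one row per cell.
Whether a column is a measurement *channel* or an *annotation* is decided
solely by the attached `Panel` (channel name, antigen name, marker vs
technical class): a column is a channel iff the panel lists it. This
avoids name-convention heuristics and makes the panel the single source of
truth; it survives every verb unchanged unless a verb adds or removes
channels. Augmenting verbs append columns with fixed dotted names
(`.cluster`, `.pc1`, `.tsne1`, `.umap1`, ...) and never mutate, drop, or
reorder existing columns; on a name collision the new column gets a
deterministic numeric suffix (`.cluster.1`). Row order is never
semantically meaningful, except that downsampling preserves the original
relative order of the surviving cells.

## FCS dialect

Reading supports FCS 3.0/3.1, list mode (`$MODE L`), `$DATATYPE` F/D/I,
little- and big-endian `$BYTEORD`, and doubled-delimiter escaping in the
TEXT segment. Column names prefer `$PnS` (antigen) over `$PnN` (channel);
both are kept in the panel, and `$PnN` values in a small known set (Time,
Event_length, DNA, Gaussian residual channels, ...) are classed technical.
Integer data with a log-amplification `$PnE` is rejected explicitly rather
than silently linearized — that encoding is legacy fluorescence and silent
rescaling risks wrong science. Float data is never rescaled by `$PnE`.
Writing emits one canonical dialect — FCS 3.1, float32, little-endian,
`$PnB 32`, `$PnE 0,0` — so write→read round trips are bit-exact at 32-bit
precision. `$SPILLOVER` is carried in the keyword map but never applied;
FCS 2.0 and the ANALYSIS segment are out of scope.

## Preprocessing

Mass-cytometry acquisition software adds uniform sub-integer
"randomization" noise to integer ion counts; `undo_randomization`
restores counts by round-half-up then clamping at zero (idempotent on
integer data). The variance-stabilizing transform is x → asinh(x/c) with
cofactor c = 5, the mass-cytometry convention (c = 150 is customary for
fluorescence). The default pipeline order is fixed and logged:
de-randomize, then arcsinh. `scale_channels` standardizes with the n−1
denominator and leaves zero-variance channels centered but unscaled, with
a warning, rather than dividing by zero.

## Density-dependent downsampling

The density verb is the SPADE-style scheme. Per group: local density
dᵢ = number of cells (self included) within Euclidean radius r of cell i,
counted exactly with a k-d tree; with r = "auto", r is the median distance
to the 15th nearest neighbor. OD and TD are the outlier (default 0.01) and
target (default 0.10) quantiles of the density distribution; cells with
dᵢ < OD are dropped as outliers, cells with dᵢ ≤ TD are kept, and denser
cells survive independently with probability TD/dᵢ. Quantiles use the
inverse empirical CDF: densities are discrete counts, and when the density
distribution is multimodal (well-separated populations) linear
interpolation would place the target between observed density values,
breaking the equalization this scheme exists for. Each group draws from
its own random stream derived from the global seed and a stable hash of
the group key, so group order cannot change results.

The equalization benchmark uses two far-apart blobs of 1000 and 9000
points placed uniformly on circles. Uniform-on-a-ring blobs have spatially
constant expected density and no boundary effects, which is what makes the
closed-form prediction (both blobs retain ≈ TD·Σ 1/dᵢ cells, hence nearly
equal counts) exact enough to test at a 20% tolerance; Gaussian blobs have
order-of-magnitude internal density gradients, and equalizing them is a
different, weaker statement.

## Clustering

The SOM is trained online: the codebook (default 10×10 grid) is
initialized by sampling distinct cells, then for `rlen` = 10 passes over
freshly seeded permutations of the cells, the best-matching node (BMU;
Euclidean, ties to the lowest node id) and all nodes within the current
bubble neighborhood are moved toward the presented cell by the current
learning rate. Learning rate and radius decay linearly per step, 0.05 → 0.01
and grid-diagonal/2 → 0.5 (grid units). Metaclustering is deterministic
average-linkage hierarchical clustering of the codebook vectors cut at k
groups (default k = 20), rather than consensus clustering with
subsampling: the workflow only requires a FlowSOM-style SOM+metacluster
pipeline, and determinism makes verification exact.
Metacluster ids are relabeled 1..k by descending node count (ties broken
by the lower minimum node id), so labels are reproducible but carry no
meaning beyond identity. The k-means backend is scikit-learn's Lloyd
iteration with seeded k-means++ initialization, ≤300 iterations, relative
tolerance 1e-4.

Cells must already be variance-stabilized before clustering; the verb
deliberately does not transform.

## Embeddings

PCA is computed in-package via SVD of the centered data (numerically
equivalent to eigendecomposition of the (n−1)-denominator covariance, but
stabler), centering without rescaling by default because post-arcsinh
channels are already variance-stabilized; a `scale` flag standardizes
first. The sign convention fixes each loading so its largest-magnitude
entry is positive. tSNE (Barnes-Hut, scikit-learn) and UMAP (umap-learn)
are delegated to established implementations behind the same augment
contract — re-implementing stochastic neighbor embeddings would be out of
proportion to this package's purpose. Both are seeded; tSNE is run
single-threaded so a fixed seed reproduces the embedding exactly.

## Sample-level features

Feature columns follow the parseable scheme
`<type>@<cluster>[@<marker>[@<condition>]]`. Abundances are exact
per-sample proportions over every cluster observed anywhere (absent
cluster → exact 0, so rows sum to 1 to machine precision). Central
tendencies of an empty (sample, cluster) stratum are missing values, never
zeros — zero abundance and "expression unobserved" are different facts.
The percent-positive threshold defaults to asinh(10/5) ≈ 1.4436, i.e. ten
raw counts on the transformed scale.

EMD/JSD compare a stimulation condition against a basal condition within
each (sample, cluster, marker). Both distributions are histogrammed on a
shared grid of 100 points spanning their pooled range *inclusive*
(spacing = range/99, values assigned to the nearest grid point); EMD is
the L1 distance between the empirical CDFs times the spacing, and JSD uses
natural logarithms with 0·log 0 ≡ 0, hence lies in [0, ln 2]. Anchoring
grid points at the range endpoints makes point-mass distances exact
(δ₀ vs δ₃ gives exactly 3), where interval-midpoint binning would
understate them by one bin width.

## Differential analysis

Abundance: proportions are clipped to [1e-6, 1−1e-6], logit-transformed,
and compared with a Welch two-sample t-test (or a paired t-test on
within-pair differences when a pairing column is given). Expression: the
same test per (cluster, marker) central tendency, skipping units missing
in more than half the samples of either group (skipped units are
reported). Zero-variance degenerate cases are defined explicitly: equal
constant groups give t = 0, p = 1; distinct constants give ±∞, p → 0.
Benjamini-Hochberg adjustment is applied within each call, with m equal
to the number of units actually tested, never across calls. The
logit-t approach was chosen over GLMM/empirical-Bayes machinery because it
is transparent, closed-form testable, and appropriate at cohort scales of
tens of samples; it is not a replacement for mixed models when samples are
structured.

## Synthetic cohorts

The generator emulates a two-arm case/control CyTOF study: cluster
signatures drawn once from uniform[0, 4] on the arcsinh scale, spherical
within-cluster s.d. 0.3, per-sample composition Dirichlet(50 × base
proportions), and defaults of 10 samples/arm, 8 clusters, 10 markers, and
1000 cells/sample. Raw instrument counts are produced by the inverse
transform (5·sinh) plus uniform(−0.5, 0.5) randomization noise clamped at
zero, so the package's own preprocessing recovers the asinh-scale values
up to count discretization. A planted effect shifts one cluster's
proportion (rescaling the rest) or one marker's mean in arm B only. The
uniform[0,4]/s.d.-0.3 geometry makes cluster recovery decisively solvable
without being trivial (nearby signature pairs do occur).

What this does *not* emulate: spillover, bead/sensitivity drift, doublets,
batch effects, acquisition-time artifacts, or heavy-tailed expression.
Passing benchmarks therefore demonstrate correctness of the algorithms
under the stated statistical model, not robustness to instrument
pathology.

## Verification sizes and determinism

The verification suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to finish in seconds to a few minutes on one CPU: 100 random
FCS round trips, 50-seed density equalization on 10k-point constructions,
10-seed cluster recovery on 2000-cell mixtures, 200-replicate null
calibration and 100-replicate power at 10 samples/arm, and 10 seeded
end-to-end pipeline runs at the generator defaults (20k cells per run).
All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning; per-stage and per-group streams are derived from (seed, stage
index) and (seed, group-key hash) respectively, so results are independent
of stage or group ordering and bit-identical across processes. The EMD
oracle is a sparse optimal-transport linear program; the PCA oracle an
independent covariance eigendecomposition; the FCS oracle a struct-based
reader written directly from the byte layout.
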