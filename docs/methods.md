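# Methods

This note records the models, conventions and numerical choices behind
`cspshape`, and what the synthetic test bed does and does not show.

## Geometry of the occupied set

A binary mask is interpreted on a continuous plane: pixel (row r,
col c) occupies the **closed** unit square [c, c+1] × [r, r+1], x
rightward, y downward, centre (c+½, r+½). The occupied region Ω is the
union of these closed squares, so points on shared edges and corners —
including the single corner shared by two diagonally adjacent occupied
pixels — count as inside. The boundary ∂Ω is the set of occupied
pixels with at least one unoccupied or off-grid **4-neighbour**; with
8-neighbour exteriors a 3×3 filled square would still have 8 boundary
pixels, but diagonal-touching shapes would differ. Disconnected
occupied components are retained (with a logged warning), and colonies
touching the raster border are accepted; chords are truncated at the
border.

The colony centroid is the unweighted mean of occupied pixel centres
and R is the maximum centre-to-centroid distance. Both are in pixel
units; physical conversion multiplies lengths by √resolution, since
the resolution is an *area* per pixel (µm²·px⁻¹). This linear factor
is applied to every physical quantity in the package.

## Chord measurement

The chord at boundary pixel p and angle φ is the maximal connected
segment of the line through p's centre at angle φ that contains the
centre and lies in Ω. It is measured **continuously**, by exact
ray–grid traversal: from the centre, the line is marched through
successive cell-boundary crossings in each direction, accumulating
parameter length until it first enters an unoccupied or off-grid cell.
A crossing exactly through a lattice corner steps diagonally, because
the open interval beyond the corner lies in the diagonal cell while
the corner point itself is in the closure of all four adjacent cells.
Comparisons of candidate crossings use a 10⁻¹² tolerance; chords are
therefore exact up to ~10⁻⁹ px. A pixel-count model cannot reproduce
the irrational chord set {√2, 2√2, 3√2} of the 3×3 square, which is
why the continuous model is the right reading. Only the maximal
segment containing p's centre is measured; for concave shapes the same
line may re-enter Ω elsewhere and those disjoint runs are ignored.
Every chord is ≥ 1 px (the shortest chord through a unit-square centre)
and ≤ the raster diagonal. The traversal is JIT-compiled (numba) so a
512² colony with a few thousand boundary pixels is measured in
milliseconds.

The test suite cross-checks the traversal against an independent
dense-sampling oracle (points every 0.01 px, membership in the closed
union), with agreement required to 0.05 px.

## CSP vocabulary

Clustering uses k-means per group on the physical-unit (µm) primitive
vectors — physical units are what make images at different resolutions
comparable. Details the descriptor leaves open are fixed as:
k-means++ initialization, 10 restarts, tolerance 10⁻⁶, ≤ 300
iterations (scikit-learn's `KMeans`), seeded per group so refits are
bit-identical. Centres are concatenated in group order, so centre
(g−1)K + k is the k-th CSP of group g. Nearest-centre assignment uses
Euclidean distance with ties broken toward the smallest centre index.
CSPs are always fitted on **training images only**; test images are
labelled against the trained centres. (Pooling train and test before
clustering would leak information into the features; this choice can
make reported accuracies slightly more conservative than a pooled
protocol.)

The augmented feature vector appends I_r/M, I_θ/M, I_Θ/M to the
M-histogram; the 1/M factor puts the indices on the scale of histogram
proportions, whose entries average 1/M.

## Spatial indices

The three indices are reconstructions built so that each vanishes
under complete spatial randomness; their published sketch fixes the
functional form of I_r, the bin counts (178 radial, 200 angular, 200
pair-correlation) and the 1000-pixel subsample, but not every
normalization, so absolute values may differ from other
implementations even where qualitative behaviour matches. All occupied
pixels (not only ∂Ω) contribute.

* **Radial index.** The disc of radius R about the centroid is cut
  into 178 equal-width annuli; each annulus' density is its occupied
  count divided by its continuous area, and the CSR reference is
  N/(πR²). R_CSR is the outer edge of the outermost annulus whose
  density still reaches the reference (colonies are dense centrally
  and rarefy outward); if no annulus falls below the reference,
  R_CSR = R and I_r = 0. I_r = 1 − R_CSR/R is clamped to [0, 1]; a
  single-pixel colony returns 0 by convention. On lattice discs the
  outermost annulus is slightly diluted by pixelation, so I_r ≈ 0.01
  rather than exactly 0.
* **Angular index.** Angles of occupied pixel centres about the
  centroid, binned into 200 equal bins over [0, 2π), each count
  divided by N/200; I_θ is the population variance of the normalized
  counts. Zero iff the angular occupancy is exactly uniform. Lattice
  pixelation leaves a small floor (≈ 0.04 for a radius-40 disc,
  < 0.01 from radius ≈ 100).
* **Pair-correlation index.** min(1000, N) occupied pixels sampled
  without replacement (seeded); all pairwise angular separations about
  the centroid folded onto [0, π] via min(Δ, 2π−Δ), binned into 200
  equal bins. Under independent uniform angles the folded separation
  is exactly uniform on [0, π], so each bin is normalized by
  n_pairs/200; F_Θ is the normalized profile and I_Θ is the excess of
  its **first bin** over 1 (the alternative reading "value at unit
  separation" was considered and not adopted).

CSR calibration (in the tests and acceptance script): on
uniform-random discs with N = 5000 the mean absolute indices are
≈ 0.02 / 0.04 / 0.01 over 20 replicates.

## Classification

A one-dimensional, equal-variance, uniform-prior Gaussian linear
discriminant is fitted per feature coordinate; with those assumptions
prediction reduces to nearest class mean (the pooled variance is
stored but cannot change the argmax), which also handles the
zero-variance degenerate case; if all class means coincide the first
class in encounter order is predicted.

Feature selection evaluates every coordinate of the augmented vector
and keeps the best by **training** accuracy (a switch allows selection
by test score, which is how a per-feature train-and-test sweep is
sometimes reported, but it is optimistically biased and not the
default). On training sets of ~10 images many features saturate at
perfect training accuracy, so accuracy ties are broken by the
**standardized training margin** — the gap between the closest pair of
class means divided by the pooled within-class standard deviation —
with the smallest index as the final resort. A plain smallest-index
rule turned out to select effectively arbitrary k-means coordinates
among ~15 tied features, several of which generalize poorly; the
margin rule keeps selection training-only (so chance-level null
behaviour is preserved) while preferring the most stable of the tied
features. The *set* of accuracy-tied features is still reported, and a
spatial index is counted as "chosen" whenever it is in that tied set.

Protocols:

* **Repeated train/test** (default n = 30): group-stratified random
  even split; odd group sizes put the extra image in training (9 →
  5 + 4). Each run refits CSPs on its training images with a fresh
  seed. Reported: mean, sample (n−1) standard deviation, per-run best
  feature, spatial-index tie counts.
* **LOOCV**: S folds; CSP refit **and** feature selection are redone
  on every fold of S − 1 images, so the held-out image never touches
  the centres. Accuracy is the fraction of the S held-out
  classifications that are correct.
* **Feature analysis**: one split, every feature scored on the test
  set; all features achieving the maximum are reported, with the
  centre vectors of CSP features attached for visualization (bar plot
  of chord length per angle).

Determinism: every protocol consumes one integer seed from which all
split, k-means and subsample seeds derive; identical seeds give
bit-identical results.

## Synthetic colonies

The generator emulates the geometry of pseudohyphal colonies — a dense
disc core with radial filamentous protrusions — not their biophysics.
Filaments are thick rasterized segments (width 3 px by default)
anchored inside the core; directions are evenly spaced with Gaussian
jitter (jitter 0 = regular spacing; increasing jitter makes angular
coverage less uniform); lengths follow a normal truncated to
[0, mean + 3 sd]; an optional single-level branch of half length
appears with probability `branching_prob`. Parameters are validated so
the colony fits the raster with a 2 px margin. Masks are deterministic
given the seed and always form one connected component.

The three presets mirror a three-condition laboratory design
(10 + 9 + 10 images at resolutions 1.52/1.55/1.53 µm²·px⁻¹, 512² px,
core radius 40 px) and differ in filament-length regime with pairwise
**disjoint** truncated supports — long sparse (120 ± 15 px, support
[75, 165]), intermediate (45 ± 8, [21, 69]) and short dense fringe
(12 ± 3, [3, 21]) — plus different filament counts and jitter. Default
image sizes were chosen so a full 30-repeat experiment on two presets
runs in well under a minute on one CPU; the miniature 160² colonies
used in some tests exercise the identical code paths at smaller n.

What passing the synthetic suite shows: the pipeline separates groups
whose boundary chord statistics genuinely differ, at the sample sizes
of a typical plate assay, and does not separate groups drawn from one
distribution. What it does not show: robustness to segmentation noise,
ragged cell-scale boundary texture, uneven illumination artefacts or
within-group biological variability beyond the filament statistics —
real masks carry all of these, and accuracies on them need not match
the synthetic ones.

## Known limitations

* The spatial-index normalizations are reconstructions (see above);
  only their CSR-null behaviour and qualitative ordering are
  guaranteed by tests.
* Boundary connectivity is fixed at 4-neighbour exteriors; shapes
  dominated by diagonal single-pixel chains will report more boundary
  pixels than an 8-neighbour convention would.
* Feature selection on very small image sets remains high-variance
  even with the margin tie-break; LOOCV is the more robust protocol,
  and the feature-analysis mode is descriptive, not inferential.
* The generator draws filament lengths i.i.d. per filament; it cannot
  emulate spatially correlated filament fields or time-resolved
  growth.
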