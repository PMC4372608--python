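# Methods

This note documents the models, conventions and numerical choices behind
`otoshape`, and what the synthetic fixtures do and do not emulate.

## Outline extraction

Images are converted to grayscale with Rec.709 luminance weights; the
otolith/background contrast in dissection-microscope imagery is high, so
the exact weights are non-critical. A pixel is foreground iff its
intensity **strictly exceeds** the threshold (default 0.2; ties at the
exact threshold are measure-zero in practice). An empty foreground is an
error suggesting a lower threshold; foreground touching the image border
triggers a clipping warning.

Connected components use 8-connectivity. The target component is the one
containing (or, for the default image-center seed, nearest to) the seed;
an explicit seed with no foreground within a radius of a quarter of the
image's short side is an error, while the default seed falls back to the
largest component, since the otolith dominates the frame. Interior holes
(e.g. compression pinholes) are filled before tracing; interior structure
is out of scope. From an interior pixel the scan proceeds along +x to the
last foreground pixel, which starts a clockwise Moore-neighbor trace. The
stopping rule generalizes Jacob's criterion: the trace stops as soon as a
(pixel, backtrack) state repeats, i.e. on the first re-entry of a boundary
pixel from the same direction. Components with fewer than 10 boundary
pixels are rejected as noise specks.

Coordinates are raster (origin top-left, y down) up to and including the
stored outline; normalization flips to mathematical orientation (y up)
before any angle is computed, so 0° points right and angles increase
counter-clockwise everywhere downstream.

## Smoothing

Each pass replaces `p_i` by `(p_{i−1} + 2p_i + p_{i+1})/4` cyclically.
The (1, 2, 1)/4 kernel preserves straight segments exactly, never
increases total absolute curvature, and contracts circular harmonic k by
`((1 + cos(2πk/n))/2)` per pass — bounded shrinkage concentrated at pixel
scales. The default 100 iterations attenuates wavelengths of a few pixels
essentially to zero while leaving the gross shape intact. Measurements
and coefficients are computed on the smoothed outline when smoothing was
applied: the measured object is the analyzed object.

## Normalization and radial profile

The centroid is the mean of the outline coordinates. The longest axis is
the direction of the maximum pairwise point distance (computed on the
convex hull; ties broken toward the smaller angle in [0, π)); after
rotating it horizontal, the 180° ambiguity is resolved by placing the
longer extent from the centroid on the positive-x side — with the imaging
convention of rostrum-left inputs this keeps orientation consistent
across fish, and users must follow that convention. Area is set to 1 by
the shoelace formula.

Radial profiles sample r(θ) at n = 2¹⁰ equidistant angles (matching ten
dyadic wavelet levels). Each radius is the exact ray–segment intersection,
interpolated along the crossing segment rather than snapped to a vertex.
Otoliths are assumed near star-shaped about the centroid; if a ray crosses
several segments the farthest crossing is used (preserving the outer
silhouette) with a warning, and a ray with no crossing (centroid outside
the outline) is an error naming the fish.

## Wavelet descriptor

Full dyadic DWT of the 1024-sample profile with the Daubechies
least-asymmetric filter with 8 vanishing moments (`sym8`) and periodic
boundary handling — the natural boundary rule for a signal that is
periodic in angle by construction, and the one that keeps the transform
orthogonal (Parseval holds to machine precision, and inversion is exact).
The filter order within the least-asymmetric family is a package choice;
coefficient values are therefore comparable across studies in structure,
not bitwise. Detail levels are numbered coarse-to-fine, level L holding
2^L coefficients whose nominal center angles are 360°(k + ½)/2^L. The
retained descriptor is the scaling coefficient plus levels 0–5
(1 + 63 = 64 values); levels 6–9 are pixel-scale noise and are discarded.
Reconstruction at "level L" inverts with detail levels < L; from the
64-vector, L ≤ 6.

## Elliptic Fourier descriptor

Kuhl–Giardina expansion of (x(t), y(t)) parameterized by **cumulative
chord length**, which is robust to the uneven vertex spacing contour
tracing produces. (Under arc-length parameterization an ellipse is not a
single-harmonic curve; closed-form single-harmonic identities hold only
for circles.) Normalization: the starting point is moved to the
first-harmonic ellipse's major axis (of the two candidate semi-axes the
longer is chosen), the shape rotated so that axis lies on +x, traversal
made counter-clockwise by requiring d1 > 0, and all coefficients divided
by the semi-major length, fixing a1 = 1, b1 = c1 = 0, which are dropped.
The residual 180° start/rotation symmetry flips the sign of every even
harmonic; it is resolved by a deterministic lexicographic rule (first
coefficient pair differing by more than 1e−8 decides). The result is
invariant to position, size, rotation, starting point and traversal
direction to ~1e−6 on analytic shapes. With 12 harmonics the descriptor
has 45 values ordered (d1, a2, b2, c2, d2, …).

## Length standardization

Per coefficient, a partial F-test compares `c ~ length × pop` against
`c ~ length + pop`. A significant interaction (α = 0.05; α/K under
Bonferroni, K the coefficient count of that transform) means no common
allometric slope exists, and the coefficient is omitted. Kept
coefficients are adjusted with the **pooled** common slope from the
additive model, centered at the grand mean length; per-group slopes are
deliberately not used (they would absorb group differences into the
correction). After adjustment the additive-model length slope of every
kept coefficient is zero by least-squares algebra, and omission decisions
are invariant to affine rescaling of the length units. Groups need ≥ 3
fish for estimable slopes.

## Measurements, mean shapes, ICC

Feret length is the maximum pairwise distance; width the maximal extent
perpendicular to that axis; perimeter and area come from the (smoothed)
polygon, scaled per fish by `cal` (px/mm): lengths as 1/cal, area as
1/cal². Mean shapes average the 64-vectors within a group and invert —
by linearity this equals reconstructing the group's mean profile. The ICC
at a wavelet level is a one-way random-effects variance decomposition per
coefficient, using the n₀ correction for unequal group sizes and
truncating negative among-group variance at zero, so ICC ∈ [0, 1]; both
the coefficient sd and its standard error are reported since either band
is a reasonable display.

## Ordination, permutation ANOVA, classification

With Euclidean distances on coefficient matrices, CAP reduces to
redundancy analysis: the centered matrix is projected onto the
group-indicator space and the fitted part decomposed by SVD; eigenvalues
are scaled by 1/(n−1) (matching vegan's convention) and at most
(groups − 1) constrained axes are kept. The precondition n > p is
enforced. The permutation ANOVA reports pseudo-F =
(SS_model/df_m)/(SS_residual/df_r) with the add-one p convention, so 1000
permutations can at best give p = 1/1001 ≈ 0.001. Cluster-plot summaries
use the population standard deviation for SE = sd/√n (exact SE/√2 halving
under sample duplication; SE = 0 for singleton groups). LDA errors: k-fold
CV (default 10; folds = n reproduces leave-one-out exactly) and
out-of-bag bootstrap (default 1000 replicates), with an optional
0.632-style blend; all resampling is driven by one seed.

## Reconstruction quality

Accuracy metrics are pluggable. The default is L1-relative agreement —
wavelet: `100(1 − Σ|r̂−r| / Σr)` on the radial profile; Fourier:
`100(1 − mean|p̂−p| / mean radius)` point-to-point at the original
chord-length parameters. Both are bounded above by 100, invariant to
uniform rescaling, and reach exactly 100 at the full wavelet level. The
L1 metric's per-fish curve can dip by ~1e−2 percentage points at coarse
levels (an L1 functional of an L2-orthogonal truncation is not exactly
monotone); the `"l2"` metric is provably monotone per fish and is
provided for that purpose. Mean curves under either metric rise
monotonically on the synthetic fixtures. The target-accuracy scan returns
the smallest level/harmonic count whose mean accuracy reaches the target
(e.g. 98.5%), or none.

## Synthetic fixtures

Blobs are star-shaped by construction, r(θ) = R(1 + Σ ε_k cos(kθ + φ_k)),
optionally plus localized angular Gaussian lobes; the default harmonic
content (elongation ε₂ = 0.15, a left-pointing rostrum lobe ε₁ = 0.08 at
180°, mild ε₃, ε₄) mimics gross otolith geometry at a realistic aspect
ratio. Defaults: 800×600 px frames, foreground 0.8 on background 0.05
with pixel noise sd 0.02 (a contrast far above the JPEG-quality-95
artifacts), calibration 90 px/mm, fish length ~ N(27.5, 2.5²) cm with
otolith radius 0.9 + 0.04·L mm, per-fish harmonic jitter sd 0.01, and the
study design of 65 + 65 + 30 fish in three groups. Planted group effects
(harmonic deltas or lobes), allometric harmonic slopes and interaction
slopes give every downstream test a known truth. What the generator does
**not** emulate: real otolith texture, annuli, sulcus structure,
non-star-shaped excisura notches, uneven illumination, focus gradients or
debris — so green tests certify the algorithms, not robustness to poor
imagery; QC overlays exist precisely because real images need eyeballing.

The coefficient-space generator draws Gaussian matrices with specified
group mean offsets, shared length slopes, per-group interaction slopes
and noise sd, for calibrating the standardization screen (type-I error at
α, ≥95% power at an interaction of ~6 slope standard errors) and the
classification regime (a Mahalanobis distance of ~1.6 between group means
puts LDA cross-validated accuracy in the 70–85% band).

## Problem sizes used in the test suite

Unit and property tests run on analytic shapes and rendered projects of
6–70 fish at 260×200–400×300 px; the calibration batteries use 200
simulation replicates; the end-to-end check runs the full study design
(160 fish at 800×600) through extraction, smoothing, both descriptor
sets, standardization and a 1000-permutation ANOVA, which completes in
well under a minute on a single CPU.

## Known limitations

- One global threshold per run; per-image thresholds only via remove +
  re-detect at a different threshold.
- The radial representation assumes star-shapedness about the centroid;
  deeply notched outlines degrade to their outer silhouette (with a
  warning) in the wavelet pathway, while the Fourier pathway handles them
  natively.
- No landmark or Procrustes support; no reflection invariance in the EFD
  (left/right otoliths should not be mixed without mirroring images
  first).
- Persistence archives store absolute project paths; move a project and
  reload from the CSV instead.
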