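# Methods

## The model in one paragraph

Peripheral vision is modeled as a lossy *summary-statistic* encoding.
An image, together with a fixation point and a pixels-per-degree scale,
is decomposed by a complex steerable pyramid (the "V1-like" stage:
oriented band-pass filters at dyadic scales, in quadrature pairs so each
band has a magnitude and a phase). The visual field is tiled by smooth,
overlapping pooling regions whose diameter grows linearly with
eccentricity, `D(e) = max(d0, g·e)`. Within each region, weighted by the
region's window, the encoder measures a fixed roster of statistics —
luminance moments, autocorrelations, and correlations of band
magnitudes and phases within and across scales and orientations. That
statistic field *is* the model's percept of the periphery: anything the
statistics do not pin down is invisible to it. "Mongrels" — images
synthesized to match a statistic field but otherwise random — visualize
exactly that equivalence class. On top of the encoding, visual tasks
are modeled as classification with an explicit complexity budget on the
decision boundary.

## Pyramid

Polar-separable filters defined in the frequency domain: raised-cosine
radial transitions on a log-frequency axis (so squared low- plus
high-pass responses sum to one at every level) and `cos^(O-1)` angular
profiles with the normalization that makes the squared orientation
responses sum to one. Oriented bands are made analytic by keeping a
single frequency half-plane (doubled, with the shared boundary split),
so the real part of each complex band equals the corresponding
real-pyramid band and reconstruction from real parts plus the two
residuals is exact to machine precision (~1e-15 max error; the stated
guarantee is 1e-4). Downsampling is dyadic by spectrum cropping, which
is alias-free because each level's lowpass is supported strictly inside
the next Nyquist square. Defaults S=4 scales, O=4 orientations; an
image must be divisible by 2^S in each axis and the builder reports the
maximum feasible S otherwise. Boundary handling is circular; pad
beforehand if wrap-around matters.

The transform is also exposed as a real-linear operator pair
(`forward` / `adjoint`); the adjoint is the exact transpose under the
real inner product (verified numerically in the tests) and is what
carries statistic-space gradients back to the image during synthesis.

## Pooling lattice

Regions must form a partition of unity (their weights sum to one at
every pixel) or synthesis and between-region comparisons inherit seam
artifacts. We build the lattice in a warped radial coordinate
`v = phi(e)` with `phi'(e) = 1/D(e)` — linear inside the foveal floor,
logarithmic beyond — so unit-spaced windows in `v` have half-power
width exactly `D(e)`. Windows are flat-top raised-cosine profiles whose
transitions are complementary, so each coordinate's windows sum to one
identically; region weights are products of a radial and an angular
window. The foveal disk and an outer catch-all ring absorb the two
complements, so coverage is total and the partition is exact (the 1%
audit tolerance is slack). Defaults: growth rate g = 0.5 (the
crowding-zone convention), foveal floor d0 = 1°, 50% cross-fade
overlap, and `ceil(2*pi/g)` angular sectors, which leaves rings
slightly elongated radially. None of these is prescribed by the
physiology beyond linear growth; all are config-exposed.

## Statistics

Per region and per scale the region's weight map is block-mean
downsampled and renormalized to sum one. Groups:

* `marginal` — weighted mean, variance, skewness, kurtosis, min, max of
  the pooled luminance;
* `highpass` — weighted variance of the highpass residual;
* `lowpass_energy` — weighted variance of the lowpass image at each of
  the S+1 levels;
* `band_energy` — weighted mean and variance of each band magnitude;
* `autocorr` — weighted Pearson correlation of each lowpass image with
  its circularly shifted copies over the central M×M neighborhood,
  deduplicated by point symmetry ((M²+1)/2 offsets);
* `mag_corr_orientation`, `mag_corr_position`, `mag_corr_scale` —
  weighted correlations of band magnitudes across orientations within a
  scale, across shifts within a band, and against the 2× upsampled
  magnitudes of the adjacent coarser scale;
* `phase_corr_scale` — weighted correlation of each band's real part
  with the real part of the phase-doubled (`z²/|z|`), upsampled coarser
  band.

The roster is the Portilla–Simoncelli texture family, pooled per region
with smooth weights instead of globally. The energy groups matter: with
only Pearson-normalized correlations the band variances are
unconstrained and the synthesis objective becomes ill-posed near zero
variance. Default M = 7; default count is 689 statistics per region
(closed form in `stat_count`, ceiling 1,000).

Numerical conventions: any correlation involving a signal of weighted
variance below 1e-8 (std below 1e-4 luminance units) is defined as 0 —
the degenerate-variance rule, which keeps vectors comparable across
regions and makes constant regions encode as all-zero correlations.
Magnitudes are smoothed as `sqrt(re² + im² + 1e-24)` for gradient
stability (value error ≤ 1e-12). Correlation-type statistics of a
region are flagged invalid at a scale where the region's *effective*
support (Kish size, `1/sum(w²)`) is below M² pixels: a 6-pixel corner
region has no meaningful 7×7 autocorrelation, and a raw nonzero-pixel
count would be fooled by wide near-zero window tails.

Every statistic has a hand-derived gradient with respect to the pyramid
maps, computed by the same code path as the value (one forward pass
fills values and, when a gradient sink is attached, accumulates
map-domain gradients which the pyramid adjoint pulls back to pixels).
The full chain is verified against finite differences.

## Mongrel synthesis

Synthesis minimizes `L(x) = Σ λ · (stat(x) − target)²` over pixels with
box constraints `x ∈ [0,1]`, by L-BFGS-B with the analytic gradients.
Per-statistic weights normalize each group by its natural scale
(correlations are unit-scale; dimensionful groups use the RMS of their
target values), so no group dominates by units. The run proceeds in
blocks; between blocks the weights of groups still above tolerance are
boosted by the squared ratio of their residual to the tolerance (a
penalty re-weighting that keeps one stubborn group from being starved).
Initialization is seeded white noise spectrally shaped to the target's
mass-weighted global band energies and matched in mean and variance.
Skewness/kurtosis targets of near-constant regions (target variance
< 1e-6) are excluded — they are undefined there, and kurtosis can never
reach the degenerate-rule value 0. Min/max marginals carry no gradient;
the box constraints and the moment matching control the range (matching
variance+skew+kurtosis of a binary texture forces a two-point
distribution by the Pearson inequality).

We deliberately deviate from projection-based synthesis: with many
overlapping, smoothly weighted pooling regions there is no consistent
per-region projection operator, whereas a single global objective is
well-defined, and its gradient is exact. Alternating blending was
prototyped along with Adam, multiscale preconditioning and staged
coarse-to-fine schedules; none beat the re-weighted L-BFGS-B run.

Residual convention (the convergence audit): per group, the RMS
deviation from the target — mass-weighted over regions, since a
six-pixel region's fourth-order statistics are sampling noise —
divided by the group's scale (1 for correlation groups, target RMS for
dimensionful ones). `converged` means every group is at or below `tol`
(default 0.05) at the end. One iteration of the public API is one block
round of `inner_steps` (default 8) quasi-Newton steps; defaults
`iters=50`.

Known limitations: sparse, high-kurtosis targets (glyph arrays — thin
dark strokes on a light field) converge markedly worse in the marginal
group, because matching an extreme pooled kurtosis requires
reconstructing near-exact sparse ink within each region; mongrels of
such displays are qualitatively informative but their marginal
residuals stay large at default budgets. On iid binary-noise targets
at 128×128 the worst groups (magnitude position correlations and lowpass autocorrelations at
the coarser scales) floor at roughly 0.06–0.07 rather than 0.05 within
the default budget — the remaining deviation is draw-specific
coarse-scale detail whose basin gradient descent does not reach; the
trace makes this visible rather than hiding it. Pixel RMS between
mongrels from different seeds on such targets is ~0.68, i.e. the
equivalence class is genuinely wide.

The fovea is "seen": `mongrelize` clamps pixels on the foveal plateau
(fovea weight > 1/2) to the source image by default; synthesis from a
bare statistic field treats the fovea as an ordinary region.

## Discriminability

Model-side discriminability is distance in statistic space. For field
comparisons, per-statistic z-scores come from a seeded ensemble of
phase-scrambled variants of the input (default 100 members; statistics
with zero ensemble variance are dropped and counted), and the distance
is Euclidean on the kept z-scores — a proper metric for encodings
sharing one normalization. Because humans define discriminability
behaviorally, everything here predicts orderings only.

The crowded-patch search proxy is a d′: present patches (target plus
four flankers with seed-varying rotations and a fixed 0.15° positional
jitter) and absent patches (distractor-centered) are encoded by a
single pooling window of diameter `max(d0, g·e)` at the patch's
eccentricity; the proxy is the separation of the class means divided by
the RMS within-class spread. Orientation pop-out separates the classes
two orders beyond flanker-induced spread; T-among-L barely separates at
all (the encoding pools away the position information that
distinguishes a T from an L). The spacing effect appears at the pooling
boundary: discriminability drops when flankers move from outside the
window into it. Within the deep-crowding regime (all flankers well
inside the window) the single-window proxy shows no reliable spacing
ordering — a limitation to keep in mind when comparing against
behavioral spacing curves.

Change visibility compares the statistic fields of an image pair at a
fixation, z-scored by a phase-scrambled ensemble of the first image;
the score is the maximum per-region distance. Approaching fixation
shrinks the regions covering the change, so the change stops being
averaged away and the score rises.

## Decision laboratory

Tasks are labeled seeded generators of feature vectors; composing two
tasks multiplies the class sets and concatenates features. Tracking k
of n items leaves `C(n,k) − 1` competing hypotheses.

Budget realizations: *k hyperplanes* — cells of an arrangement of at
most k linear separators, labeled by training majority; candidate
planes are axis-aligned stumps at feature quantiles, random directions
through data-pair midpoints, and class-mean differences on random
subsets, selected by beam search on training accuracy (pure greedy
fails on parity tasks like XOR, whose optimal planes are individually
uninformative; the second level searches all pairs over a pruned
subset). Shorter sets stay eligible, so training accuracy is
non-decreasing in k; held-out accuracy is monotone at the test set's
binomial resolution. *d dimensions* — univariate-F feature selection
followed by an unrestricted RBF-SVM. *curvature κ* — an RBF-SVM whose
kernel length-scale is floored at 1/κ (`gamma = κ²/2`), our
interpretation of a bound on boundary curvature. *unlimited* — the
better of LDA and an RBF-SVM on a validation split; on Gaussian toys
this sits within sampling error of the analytic Bayes accuracy.
Accuracies are reported with binomial standard errors.

The change-detection (VWM) experiment measures, per set size, the mean
encoder distance between colored-square arrays differing in one item's
color, against the mean distance between independent arrays. The
default encoder is the statistic encoder with skewness/kurtosis entries
squashed through `v/(1+|v|)` so the vector is intrinsically bounded and
Euclidean distance transfers across stimulus classes (an ensemble-z
alternative does not transfer: scales estimated on one class are
meaningless on another). Scene confusability thresholds the same
distances: probes within the one-item-change distance of each other are
reported as confusable — the generalized "what else would you not
notice" report. The measured direction of the one-item distance across
set sizes is reported, not asserted.

## Synthetic stimuli

All displays are generated internally and deterministically: letters
come from a built-in stroke-segment font rasterized with a 1-pixel
coverage ramp (bit-reproducible across platforms), search arrays
rejection-sample non-overlapping jittered positions, VWM arrays place
colored squares on an eccentricity ring against gray (palette: 9
maximally spaced hues), change pairs re-render with one item recolored,
and textures include iid binary noise, uniform noise, gratings and
constants. Ground-truth records are sufficient to re-render a display
exactly. What the generator does not emulate: natural-scene content,
photometric noise, or any spatial statistics of real environments — so
green tests certify the machinery and the model's internal directions
(pop-out vs. conjunction, near vs. far fixation), not quantitative
agreement with human thresholds on real images.

## Problem sizes

Default test and acceptance sizes: 128×128 at 32 ppd (4° field) for
texture synthesis, 128×128 at 16 ppd (8° field) for displays, 100-image
batches for the pyramid audit, 2,000 train/test samples per class for
classifier experiments, 10 seeds per discriminability condition, and
phase-scrambled ensembles of 30–100 members depending on the audit.
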