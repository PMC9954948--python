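# Methods

## Problem and pipeline

Ovarian follicles appear on B-mode ultrasound as hypoechoic (dark)
ellipse-like regions inside the brighter ovarian stroma. The package
segments them in a manually cropped ovary region of interest with two arms
sharing one enhancement chain, mirroring a two-method study design:

1. **Enhancement** (`preprocess`): linear contrast stretch between
   cumulative-histogram bounds → 5×5 median despeckling → 256-bin histogram
   equalization, in that order. Every stage maps 8-bit to 8-bit, preserves
   shape, and is monotone on pixel values.
2. **Classical arm** (`chanvese.segment(mode="classical")`): two-phase
   Chan–Vese level-set evolution from a rectangle inset 5% from the frame.
3. **Hybrid arm** (`mode="hybrid"`): exact multilevel Otsu thresholding
   (`otsu`) of the enhanced image; the darkest of k+1 classes becomes a
   binary seed mask whose signed distance initializes the same evolution.
4. **Evaluation** (`metrics`): pixel-based confusion counts → accuracy,
   Dice, Jaccard, sensitivity; aggregation with sample (n−1) standard
   deviation; paired two-sided comparison between arms.
5. **Phantoms** (`phantom`): synthetic scenes with known ground truth,
   since the clinical images behind the published comparison are not
   redistributable.

## Enhancement chain

*Contrast stretch.* The lower bound is the smallest gray level whose
cumulative histogram fraction exceeds `low_frac` (default 0.01), the upper
bound likewise at `high_frac` (default 0.99); pixels map affinely with
clipping. The published description names only "lower and upper bounds";
1% tail saturation is the conventional reading and both fractions are
configurable. A linear stretch (not gamma) is implemented.

*Median filter.* 5×5 window (the published choice), reflect padding so
follicles touching the frame are not darkened. Note one consequence used in
the tests: on a degradation-free render the median erodes convex follicle
boundaries by about half a pixel (a boundary pixel whose 25-window holds
fewer than 13 foreground pixels flips), so the clean-scene limit of the
full pipeline is Dice ≈ 0.99 per image, not exactly 1.

*Equalization.* Standard cdf map
`v ↦ round(255·(cdf(v) − cdf_min)/(1 − cdf_min))` over 256 bins, `cdf_min`
taken at the lowest occupied bin; constant images collapse to zero with a
warning.

## Multilevel Otsu

Thresholds `t1 < … < tk` (k = 4 by default, giving 5 classes) minimize the
total within-class variance of the 256-bin histogram, with classes
half-open, lower-inclusive: class j = [t_j, t_{j+1}). "Threshold level 4"
is read as four thresholds / five classes; k is configurable. The solver is
a dynamic program over cumulative zeroth/first/second moments — exact, so
tests can compare it against brute-force enumeration — with ties broken
toward the lexicographically smallest tuple (relevant only for degenerate
histograms with empty gaps). Heuristic optimizers are pointless at this
size: 255 levels × 4 thresholds solves in milliseconds. The darkest class
is the default seed foreground because follicles are hypoechoic;
`fg_classes` is configurable. When an image has fewer than k+1 occupied
gray levels (e.g. an already-binary image), the hybrid arm clamps k to
(occupied − 1) instead of failing.

## Chan–Vese evolution

Energy and update as in the README. Numerical choices:

* Smoothed Heaviside `H_ε(z) = ½(1 + (2/π)·arctan(z/ε))` with ε = 1 on the
  [0, 1] intensity scale; its derivative is the Dirac weight in the update.
  The arctan profile has global support, so distant pixels evolve (slowly)
  too — updates are not artificially restricted to a narrow band.
* Curvature `div(∇φ/|∇φ|)` by central differences, |∇φ| floored at 1e-8.
* Defaults μ = 0.2, ν = 0, λ1 = λ2 = 1, dt = 0.5 — canonical values for
  this functional on unit-scaled images; all exposed.
* Exactly `n_iter` = 500 fixed steps, no convergence exit by default (an
  `early_exit_tol` flag exists but is off), matching the fixed-iteration
  protocol of the study design.
* Signed distances (mask init and periodic reinitialization, every 50
  steps) via the exact Euclidean distance transform of the sign partition,
  offset half a pixel so `(φ > 0)` reproduces the mask exactly.
* Reinitialization restores the signed-distance profile and may *raise*
  the smoothed-Heaviside energy (it changes φ's profile, not its sign
  pattern); pure gradient descent (reinit disabled) is monotone
  non-increasing at dt = 0.5 on piecewise-constant scenes, and the descent
  test runs in that configuration.
* The printed form of the energy's outside integral reuses `c1`; the
  standard form with `c2` is implemented (the outside mean is otherwise
  unused — an evident typo in the source description).
* Output foreground is whichever phase has the darker mean, so "follicle"
  is stable under sign drift; a `fg_phase="brighter"` switch covers
  inverted-contrast material.
* Both arms run on the preprocessed image by default; `--raw-classical`
  ablates that for the classical arm.

## Evaluation

Undefined metrics (empty ground truth for sensitivity, both masks empty
for Dice/Jaccard) raise rather than contribute silent zeros; the pipeline
excludes such images from aggregates with a warning. The paired comparison
defaults to the t-test on per-image differences, with an exact Wilcoxon
signed-rank fallback when the differences have (numerically) zero variance,
and p = 1 with a degeneracy flag when they are all zero. The published
comparison never names its test; p-values are therefore reported as this
package's choice, not treated as reproducible targets. Published summary
arithmetic (`pipeline.reproduce_table1_arithmetic`) differences the
4-dp-rounded column means, which is how the published difference figures
(0.0325 / 0.1058 / 0.1289 / 0.2003) were evidently produced.

## Phantom generator

Each phantom renders background, an ovary ellipse of stroma, and
non-overlapping follicle ellipses, then degrades: Gaussian blur of
boundaries (`boundary_softness`, px), a smooth multiplicative bias field
(sum of three low-frequency cosines, zero-mean, amplitude-bounded by
`inhomogeneity_amp`), multiplicative gamma speckle (shape =
`speckle_looks`, mean 1 — the standard average-of-looks surrogate for
ultrasound speckle), clipping to [0, 1] and 8-bit quantization last. The
ground-truth mask is the exact pre-blur ellipse union. One seed feeds two
separated generator streams (placement vs noise), so masks depend only on
placement; `noise_seed` re-seeds just the noise stream to redraw texture
over a fixed layout.

Default scene parameters and why:

* `n_follicles = 12` (suite-jittered ±2): the study population is PCOS
  patients, for whom ≥ 12 follicles is part of the diagnostic criterion.
  Sizes 6–14 px, placed largest-first inside the ovary by rejection
  sampling.
* `background_level = 0.45` vs `stroma_level = 0.50`: a cropped ovary ROI
  is surrounded by echogenic pelvic tissue of near-stromal brightness, not
  by black. (A black far field would also make the two-phase
  piecewise-constant model's *global* optimum merge the far field with the
  follicles — a property of the model, not of any implementation.)
* `follicle_level = 0.10`: near-anechoic fluid.
* Presets: `dark_regime` (4-look speckle, ±20% bias, blur 1.5 px — the
  difficult, globally dark case), `light_regime` (8-look, ±15%, blur 1 px),
  `clean` (no degradation; exact three-level render).

What the phantoms do *not* emulate: point-spread anisotropy, rf-domain
scattering statistics, acoustic shadowing/enhancement, out-of-plane
follicles, operator-dependent cropping. Passing the phantom benchmark
therefore shows the pipeline handles multiplicative speckle, smooth bias
and faint boundaries at realistic follicle densities — not that clinical
performance figures transfer.

## Benchmark conditions and a known ceiling

The pinned benchmark (tests/test_acceptance.py) runs 20 dark-regime
phantoms at seed 0 with 500-step evolutions; it takes ~30 s on one core.
The hybrid arm beats the classical arm decisively (mean Dice ≈ 0.68 vs
≈ 0.25 at seed 0). An instructive limitation shows up here: after
histogram equalization the image histogram is nearly uniform, and the
two-phase partition settles at the midpoint of its phase means, which in
rank terms sits well inside the dark tissue tail. The contour therefore
carries a ~2 px outward halo and keeps bias-darkened tissue pockets, capping
mean Dice near 0.83 under these degradations even when the evolution is
started from the exact ground-truth mask (an independent implementation,
skimage's `chan_vese`, reproduces the same ceiling). Disabling equalization
(`preprocess.equalize = False`) lifts the clean-seeded figure above 0.99,
but equalization is part of the published chain and stays on by default.

## Determinism

Phantom generation is bit-reproducible from (spec, seed); segmentation is
deterministic; two pipeline runs with the same configuration produce
byte-identical masks and CSV. Tables round to 4 decimal places only at
serialization.
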