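# Methods

This note documents the models and procedures `hyperseed` implements, the
assumptions behind the synthetic scene generator, and the numerical and
design choices made where the underlying method description left the design
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Radiometric calibration

The chain is the standard bench-top push-broom procedure, per pixel (i, j)
and band:

    S   = S_raw − S_bg            (dark-current subtraction, clipped at 0)
    R   = (S_bright − S_bg)/L_ref (response from a bright panel scan)
    L   = S/(R · t_int)           (spectral radiance)
    ρ   = L / mean_panel(L) × ρ_panel   (reflectance, ρ_panel = 0.5)

Choices:

- Negative background-subtracted values are clipped to 0: sub-dark
  excursions are electronic noise, and carrying negatives into ratio
  features and masks does more harm than the bias the clip introduces.
- `L_ref` is interpreted as the panel's *radiant exposure* during the bright
  scan (radiance × integration time). This is the only reading under which
  the response and radiance equations compose to an exact inverse of the
  forward model `raw = dark + L·R·t_int`; the synthetic calibration
  fixtures adopt it and the round trip is exact to ~1e-13.
- The panel is summarized per band by the spatial mean over a declared
  region of interest. Pixels whose bright-minus-dark signal is not positive
  are flagged invalid and produce zero radiance rather than infinities.
- Downstream stages consume reflectance by default (the protein link and
  the segmentation rule are reflectance-scale statements); radiance mode
  remains available.

## Co-registration

The two sensors view the same flat scene, so their frames are related by a
planar projective transform H (here: anisotropic scale ≈ the resolution
ratio, plus a translation of a few coarse pixels). Tie points come from
fiducial markers visible in both ranges; automatic feature matching (SIFT
and similar) is unreliable across disjoint spectral ranges, which is why the
marker-based design exists at all.

- Estimation: 4 exact pairs are solved directly (normalized DLT via
  scikit-image); more pairs go through RANSAC with inlier threshold 7.0 px
  and at most 2000 trials, followed by a least-squares refit on the
  consensus set. The RANSAC seed is surfaced for determinism.
- Error reporting: when more than four markers exist, a 25% held-out subset
  is reserved and the reported RMSE is measured on it, so the number is not
  the (optimistic) fit residual.
- Warping maps the fine VNIR cube into the coarse SWIR frame (inverse
  mapping, shared coordinates across bands, bilinear sampling,
  out-of-frame → 0), keeping stacked cubes small. Stacking concatenates
  bands VNIR-then-SWIR; the ~40 nm sensor overlap is retained, so the
  stacked wavelength list is only piecewise increasing and is tagged as
  such.
- The naive baseline resamples by the dimension ratio alone
  (area-style interpolation: exact block means for integer factors). It is
  translation-blind by construction; on any scene with a ≥ 2 px shift the
  homography's held-out RMSE is smaller, and the comparison function
  measures exactly that.
- Coordinates are 0-based pixel centers, x = column, y = row.

## Segmentation

A pixel is seed iff all five conditions hold on reflectance at
410, 456, 553, 654, 852 nm (B1, B2, G, R, N):

1. B1 < B2
2. 0.7·B1 ≤ R ≤ 12.5·B1
3. 1.2·B1 ≤ N ≤ 15·B1
4. B2 < G
5. 1.2·B2 < G

The source description chains its inequalities ambiguously and lists a
redundant complementary background rule; here conditions 2 and 3 are read
as two-sided bounds and background is defined as the complement of 1–5,
which makes the predicate total. The rule lives behind one function so
alternative readings can be swapped in.

Cleanup: 3×3 morphological opening (idempotent; removes isolated
rule-passing background pixels), then hole repair — a one-pixel guard
border is added, the background is flood-filled 4-connected from (0, 0),
unreached interior zeros are relabeled seed, and the border is removed.
Hole repair never deletes an input seed pixel. Components are 8-connected
(seed cohesion vs conservative background spread; the method description is
silent on both) and strictly filtered to 250 < area < 1500 px, which drops
noise blobs and fused seed pairs alike. Grid identities cluster centroid y
into rows with tolerance = half the median component height, sort by x
within a row, and label column-letter + row-number. Crops are 32×32
windows centered on the centroid, zero-padded at frame edges, with
non-component pixels zeroed so a crop's sum equals its component's sum.

## Feature engineering and splits

Mean spectra are computed over nonzero-mask pixels only; smoothing is
Savitzky–Golay with window 7 and polyorder 3 (exact on cubics). Band
ratios are all pairs `X_j/X_k, j<k` in lexicographic order (C(C−1)/2
features; denominators below 1e-8 yield 0 rather than dropping the column,
keeping matrix shape stable). Ratios are computed on raw reflectance and
all columns are normalized jointly afterwards; min-max statistics come from
the training partition only, constant columns map to 0, and out-of-range
test values are deliberately not clipped.

The split rule is: `n_test = round_half_up(n/4)`,
`n_val = round_half_up((n − n_test)/5)`, train = remainder. Half-up
rounding is the only convention that reproduces both published cohort
triples (5057 → 3034/1264/759 and 4746 → 2847/1187/712); floor fails the
second, ceiling the first. Protein classes are low < 10%,
10% ≤ medium ≤ 14% (both boundaries inclusive), high > 14%. Summary
quartiles use linear interpolation (type-7); the published table's
convention is unstated, so its variance/skewness values are not asserted
anywhere.

## Feature models

Random forest (500 trees, unlimited depth) and RBF-kernel SVR (C = 10,
ε = 0.1); no hyperparameters were published, these are ordinary field
defaults and fully exposed. Permutation importance scores the R² drop on a
held-out fold over 10 column shuffles; the top-100 wavelengths seed dataset
variant 2 (100 bands + their 4950 ratios). Importance is computed on the
training partition only to avoid selection leakage. Variant 3 (all bands +
all ratios) is ~219k columns at 662 bands and is memory-heavy by nature;
the builder accepts any band subset for desk-scale runs.

## The CNN

Input is an (N, 32, 32, D, 1) patch tensor, with D either the raw 662
bands or K principal components of pixel space (PCA preserves the spatial
layout; K defaults to 30 and is configurable — the source work chose K
empirically without stating it). The stack is three valid-mode 3-D
convolutions (kernel sets (3,3,7)/(3,3,5)/(3,3,3), (3,3,11)/(3,3,9)/(3,3,7),
(5,5,15)/(5,5,11)/(5,5,9), plus a compact all-(3,3,3) set for shallow
depths such as K = 8), batch normalization and ReLU after each convolution,
optional global channel attention (pool over H, W **and** D — the stated
1×1×1×C attention-map shape forces depth pooling — then a C → C/2 → C
bottleneck with sigmoid gate), depth folded into channels, one 3×3 2-D
convolution with 64 filters, optional squeeze-and-excitation
(reduction 2), and dense layers 256/128 into a linear or 3-way softmax
head. Filter counts and dense widths follow the cited hybrid-network
lineage; none were published.

Training uses Adam (lr 1e-3) with mini-batches; regression targets are
standardized internally and predictions mapped back, a pure conditioning
choice. Dropout is omitted: it was never mentioned in the method
description and determinism is simpler without it. All layers are numpy
with hand-written backward passes, verified in the test suite by
finite-difference gradient checks, a triple-loop convolution oracle, and
analytic anchors (zero gate weights ⇒ every attentive block scales its
input by exactly sigmoid(0) = 0.5). Determinism is guaranteed for
single-device CPU execution with fixed seeds.

## The synthetic scene generator

The simulator emulates what the pipeline assumes about real scans, not
seed optics:

- **Layout**: a dark tray (flat reflectance 0.06), a 50% panel strip, 24
  seeds as filled ellipses (default 40×20 px in the fine frame,
  area ≈ 630 px — inside the 250–1500 component window) on a 4-wide ×
  6-long grid, and ≥ 4 fiducial disks (radius 5 px, reflectance 0.9) on a
  half-cell lattice between the seeds. Both sensors render the same vector
  scene through the true transform, so marker centroids are geometrically
  consistent across frames up to grid quantization.
- **Protein link**:
  `ρ(λ, p) = base(λ) · (1 − 0.35·t) · (1 − d(p)·dips(λ))` with
  `t = (p − 7.69)/11.96`, Gaussian dips at 1450 and 1950 nm
  (σ = 45/55 nm) and `d(p) = 0.30·(1 − 0.5·t)`. Reflectance decreases
  strictly with protein at every band, and the moisture dips are deepest
  for low-protein (higher-moisture) seeds; with these constants the fade
  of the dips never overturns the monotone ordering. The base curve is a
  monotone spline through seed-like control points: dark blue rising
  steeply through the visible (the rule conditions need a real B1 → B2 → G
  gradient to have margin against pixel noise), a NIR plateau, and a
  gently declining SWIR envelope. The link is qualitative domain structure
  with exposed parameters, not a fitted physical model.
- **Noise** is i.i.d. Gaussian per pixel and band (default studies use
  sd 0.01), clipped at zero. Real seed spectra have correlated texture,
  specular crease effects, and orientation differences the simulator does
  not model (an `orientation_contrast` knob exists but defaults to 0
  because no quantitative ventral/dorsal difference was published).
  Passing tests therefore demonstrate the correctness of the chain under
  the stated generative assumptions, not field-level accuracy: published
  real-data scores (R² ≈ 0.7–0.77) are far below the near-perfect recovery
  the clean synthetic link permits, and the package makes no attempt to
  imitate them.
- **Calibration fixtures**: per-pixel response drawn uniform in
  [0.8, 1.2], dark frames uniform in [3, 8] DN, flat illumination; the
  bright frame is a full-frame panel scan under the same forward model, so
  the calibration chain inverts it exactly.

## Scaled-down study sizes

The recovery experiments run 400 seeds (16×16 patches, K = 8, compact
kernel set, 30 epochs, batch 32) for the CNN and 400 mean spectra for the
random forest, with a 240/100/60 train/test/validation split — sizes chosen
so a full from-scratch run of every stage completes in minutes on a single
CPU while still giving the models a few hundred training examples. The
full-size architecture (32×32×662 input, kernel sets 1–3) is exercised for
shape correctness and forward passes in the unit tests.

## Known limitations

- The ENVI reader loads cubes fully into memory; no memory-mapped partial
  reads.
- Rotation-rich or non-planar registration is out of scope (the bench-top
  geometry is scale + translation).
- Touching seeds are dropped by the area filter, not split by watershed.
- Variant-3 feature matrices at full band count require tens of GB for
  cohort-scale sample counts; use band striding for desk machines.
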