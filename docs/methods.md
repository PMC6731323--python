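# Methods

## The problem

Scoring Ki67 in breast cancer requires knowing where the tumour is.
Ki67-stained (DAB, brown) sections carry no pan-tumour marker: the tumour
contains both Ki67-positive and Ki67-negative nuclei, and Ki67-positive
nuclei occur outside the tumour as well. `ki67net` implements a complete
patch-classification pipeline for this problem: a small convolutional
network labels 64×64 px tiles of the slide as tumour or non-tumour, a
second model of identical architecture flags lymphocytic infiltrate (dense
immune-cell fields that otherwise confound the tumour classifier), and a
hotspot stage localises regions of high Ki67 density inside the predicted
tumour. All stages are exercised end-to-end on synthetic pseudo-slides
with exact ground truth.

## The classifier

Architecture (fixed, "4-layer"): two valid 5×5 convolutions (32 then 64
filters, stride 1, ReLU), one 2×2/stride-2 max-pool, two fully connected
layers (1024 and 512 units, ReLU), dropout 0.5 after the second FC layer,
and a 2-way softmax head. On a 64×64×3 input the spatial trace is
64 → 60 → 56 → 28 under the standard valid-convolution size rule
`(W + 2·pad − M)/stride + 1`; the parameter count is 51,960,770, dominated
by the first FC layer (28·28·64 → 1024).

Training: plain SGD with momentum on the softmax cross-entropy.
Defaults — learning rate 0.001, momentum 0.9, 15 epochs, batch size 25,
dropout 0.5 — are the pipeline's published operating point and are not
tuned per run. There is no schedule, early stopping or checkpointing.
Inputs are 8-bit RGB patches scaled to [0, 1] and mean-normalised per
channel with means estimated on the training set and stored with the
model. (Normalising on the [0, 1] scale rather than raw 8-bit values
keeps the fixed learning rate stable with He initialisation; this is the
package's convention for "mean-normalised input".) ReLU is applied after
each convolution and after each hidden FC layer but not at the output;
dropout is active only during training, so inference is deterministic.

The compute core is pure NumPy over BLAS: convolutions are im2col + GEMM
in float32, and the momentum update is fused into the weight-gradient GEMM
(`v ← momentum·v − lr·AᵀB` as one `sgemm(alpha=−lr, beta=momentum)` call),
which avoids materialising the 205 MB FC1 gradient each batch. One SGD
batch costs ≈0.7 s on a single CPU core; the standard 1,600-patch,
15-epoch fit takes ≈11 minutes.

The infiltrate classifier (INFI-NET role) is the same estimator trained
with `infiltrate` / `non-infiltrate` labels — there is no separate code
path. Because the infiltrate-vs-everything task on these images is much
easier (dense small dark-blue nuclei against everything else), it is
trained by default on fewer patches (600) for fewer epochs (4).

## The pipeline

* **Tissue rule.** A tile is tissue iff its mean intensity (MI) over all
  pixels and channels is < 235; brighter tiles are glass and skipped.
* **Patch labelling.** Tiles on a stride lattice become training patches
  when ≥ 90 % of their pixels (the `purity` parameter) carry one
  annotation label; boundary-straddling tiles are dropped. The default
  training stride equals the patch size; the evaluation harvests use
  stride 32 to collect enough tumour tiles from one slide.
* **Probability map.** At inference, overlapping 64×64 tiles (default
  stride 32, i.e. 50 % overlap) are scored and their tumour probabilities
  averaged per stride-lattice cell. Cells never covered by a tissue tile
  are background, which is distinct from probability 0.
* **Infiltrate exclusion.** Cells whose infiltrate probability ≥ 0.5 are
  forced to non-tumour and flagged; the operation is idempotent.
* **Binarisation.** Tumour mask = covered cells with p > 0.55, the lower
  edge of the lowest tumour colour bin (yellow 0.55–0.65, orange
  0.65–0.75, red > 0.75; bin edges belong to the lower bin so that red is
  strictly p > 0.75).
* **Hotspots.** Ruifrok–Johnston H-DAB deconvolution of the RGB image;
  DAB optical density > 0.15 (default), opening with a radius-1 disc,
  components < 20 px removed, intersected with the tumour mask. Connected
  components yield nucleus centroids; Chiu-style subtractive clustering
  (ra = 200 px, rb = 1.5·ra, accept 0.5, reject 0.15 — Chiu's
  conventions; the radii are on the scale of the 100 px circles) proposes
  centres; each centre gets a 100-px-diameter circle (≈50 µm at 0.5
  µm/px) whose Ki67 ratio is DAB area over circle area (clipped at the
  image border, the clipped area is the denominator). Ratio > 20 % calls
  a hotspot. Optional banding cut-offs map ratios to proliferation bands;
  a ratio equal to a cut-off goes to the upper band.
* **Validation.** Pixel confusion counts at the annotation downsample
  (default 8×, matching the ~×10 annotation magnification), evaluated over
  tissue pixels only by default — counting glass would inflate true
  negatives. Metrics: TPR, TNR, FPR, FNR, PPV, NPV, Dice; zero-denominator
  metrics are reported missing (never 0) and excluded from cohort means
  with a warning. Cohorts aggregate as unweighted mean ± sd over slides.

## The synthetic-data generator

The generator emulates a Ki67 IHC appearance just well enough that every
stage has real work to do: near-white glass (Gaussian noise σ = 2, clipped
at 240 so glass never trips the MI rule), pale stroma and epithelium
fields whose mean intensity sits below the 235 cut-off, and nuclei as
filled ellipses with jittered size, orientation and colour. Haematoxylin
nuclei are blue (70, 80, 160), DAB nuclei brown (110, 70, 30) — colours
chosen so that H-DAB deconvolution separates them with margin (DAB OD
≈ 0.20 vs ≈ 0.00) while remaining in the visual range of real stains.

Per-class nuclear densities (per 1000 px²) and semi-axis ranges:
stroma 0.4 / 2–4 px, benign epithelium 1.2 / 3–5 px, tumour 11 / 5.5–7.5
px, infiltrate 12 / 2–3 px. Tumour nests are deliberately nucleus-dense
(≈60 % nuclear area), as in carcinoma; this also means a tumour region
with Ki67 fraction f has DAB area ratio ≈ 0.6·f, so the planted-hotspot
scenario (fraction 0.5 over ambient 0.05) produces circle ratios of
≈ 0.3 vs ≈ 0.03 around the 20 % decision line. Ki67 positivity is
assigned per nucleus by exact allocation (`round(f·n)` positives chosen
at random), so the realised fraction matches the requested one to within
half a nucleus.

Ground truth is exact by construction: the label mask is rasterised from
the same polygons that form the annotation set (pixel-centre coverage,
priority infiltrate > tumour > non-tumour), and nuclei are clipped to the
tissue footprint as seen at the mask downsample so the full-resolution
DAB mask never leaks outside the label mask. `plant_hotspot` flips
nucleus labels inside a disc to reach a requested Ki67 fraction,
re-renders the flipped nuclei and rebuilds the DAB mask from the nucleus
table.

What the generator does **not** model: chromatin texture, stain
variability between laboratories, out-of-focus regions, tissue folds,
nuclear pleomorphism, or touching-cell boundaries. Passing tests on these
slides demonstrates that the pipeline's machinery is correct and that the
classifier can learn colour/density-separable tissue classes; it does not
demonstrate real-slide accuracy, which in the source setting is
substantially lower (Dice ≈ 0.74 on real cohorts vs ≥ 0.85 required here
on synthetic scenes).

## Numerical and design choices

* The feature-map size rule includes the conventional "+1"; a printed
  variant of the formula without it is arithmetically inconsistent with
  the 64 → 60 → 56 → 28 trace and the "pooling halves the map" statement,
  so the standard convention is used. Valid (pad 0) convolutions
  throughout.
* The loss is cross-entropy over the softmax — the natural pairing for a
  softmax classifier; no other loss is supported.
* Weight initialisation is seeded He (fan-in scaled normal); biases start
  at zero. All randomness (init, shuffling, dropout) derives from one
  `random_state` through named `SeedSequence` spawns, so fits are exactly
  reproducible.
* Softmax is stabilised by max-subtraction and is shift-invariant by
  construction; NaN logits raise.
* Rasterisation labels a pixel by its centre; overlapping polygons
  resolve by fixed priority (infiltrate > tumour > non-tumour), which
  makes overlap behaviour deterministic where annotation semantics are
  silent.
* Probability bins are half-open with the upper edge in the lower bin
  (red means strictly p > 0.75).
* Subtractive clustering stops at Chiu's reject threshold; grey-zone
  candidates use the distance criterion `d_min/ra + P/P₁ ≥ 1`, and a
  rejected grey-zone candidate has its potential zeroed rather than ending
  the search.
* Circle scoring uses the strict-interior disc convention
  (distance² < r²), matching the rasterised discs it is tested against.
* Degenerate inputs: empty point sets cluster to nothing; a single point
  is its own centre; an empty tumour mask yields an empty DAB mask with a
  warning; zero-coverage probability cells are background, not p = 0.

## Problem sizes used in the checks

The standard benchmark harvests 2,000 class-balanced patches (stride 32,
purity 0.9) from one 2048² training slide, fits on 1,600 with 400 held
out, and evaluates segmentation on an independently seeded 2048² slide at
inference stride 32. The label-shuffled no-leakage control runs at
reduced size (800 patches, 5 epochs): chance-level held-out accuracy on
shuffled labels is equally conclusive at any training length, and the
reduced control keeps the full suite's runtime proportionate. The
hotspot benchmark plants one fraction-0.5 hotspot (radius 160 px) in a
1024² tumour field with ambient fraction 0.05.

## Known limitations

* The CNN core is CPU-only NumPy/BLAS; it is fast enough for the
  benchmark sizes but not for gigapixel production scans.
* Only the fixed two-conv/two-FC topology is supported; filter counts and
  FC widths are configurable, kernel stride/padding are not.
* The pseudo-slide reader handles PNG/TIFF rasters; pyramidal vendor WSI
  formats are out of scope (the `PseudoSlide` duck type is the extension
  point).
* Proliferation band cut-offs (low/medium/high) are configuration — no
  canonical numeric values are asserted.
* Cohort statistics are descriptive (mean ± sd); no significance testing.
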