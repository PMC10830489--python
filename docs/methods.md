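# Methods

`gauzeloss` re-implements an automated pipeline for estimating
intraoperative blood loss (EBL) from laparoscopic images of surgical gauze:
frames are tiled and classified to find the gauze, the crumpledness of the
gauze surface is summarized by a texture statistic, and a multi-input
regression network maps the masked gauze image plus crumple features to
absorbed blood mass in grams. Because the clinical image corpora behind the
original study are not public, the package ships a synthetic scene
generator that carries the statistical structure the method assumes, with
exact ground truth at every stage; all quantitative claims made by the test
suite refer to that synthetic setting.

## The estimation problem

A used surgical gauze absorbs between roughly 0.1 and 10 g of blood. Summed
over a procedure, per-gauze masses give the gauze component of EBL, a
quantity that is otherwise obtained by manually weighing each gauze.
Two image cues carry mass information: the extent/darkness of red staining,
and the crumpled state of the gauze — a crumpled, folded gauze packs more
absorbent surface per projected pixel, so the same stained area can hold
more blood. The pipeline therefore fuses appearance (a CNN feature of the
masked gauze image) with an explicit crumple statistic.

## Crumple texture: LBP and the crumpled-state value

The local binary pattern of a center pixel c thresholds P neighbors on a
circle of radius r against the center:

    LBP_{P,R}(c) = Σ_{p=0}^{P-1} s(g_p − g_c) · 2^p,  s(x) = 1 iff x ≥ 0

with defaults P = 8, r = 3. Conventions fixed by this implementation:

* neighbor p sits at angle 2πp/P counterclockwise from the +column axis,
  i.e. offset (Δrow, Δcol) = (−r sin θ, +r cos θ);
* non-integer positions are bilinearly interpolated (a nearest-pixel mode
  exists for exact-integer oracles); interpolated values within 1e-6 of an
  integer are snapped before comparison so integer images behave exactly
  (s(0) = 1 makes constant regions code 255);
* pixels whose sampling circle leaves the image are marked invalid and are
  excluded from both the numerator and denominator of any region statistic.
  Edge replication was rejected because it biases codes at the mask
  boundary.

The crumpled-state value (CSV) is the mean LBP code over the detected gauze
region — the region-sum of codes divided by the count of gauze pixels with
valid codes, a scalar in [0, 255]. Codes are computed on the luminance
grayscale (0.299 R + 0.587 G + 0.114 B) of the *original* frame and only the
summation is restricted by the mask, so masking artifacts do not perturb
boundary codes.

The patch-wise variant computes one CSV per gauze patch (a detection tile
with ≥ 50% gauze coverage) and weights it by that patch's blood-evidence
score — the stained+soaked probability from the tile classifier. Per-patch
blood mass is not observable at inference time; the classifier probability
is the only inference-time signal consistent with the premise that blood
and crumple co-locate, so it is the default weighting. Two further modes
exist: `uniform` (ablation) and `ground_truth_mass` (synthetic scenes only,
to validate the proxy). The weighted CSVs are sorted descending, truncated
or zero-padded to a fixed length N = 16, and fed to the fusion MLP; the
fixed length decouples the network from the variable patch count.

## Synthetic scenes

The generator renders 256×256 RGB frames (size configurable) containing:

* a connected, star-shaped gauze blob whose area is a requested fraction of
  the frame (default draw U[0.28, 0.42]) on a tissue-like or dark-cavity
  background;
* a periodic two-direction weave (period 8 px) with fiber noise;
* a crumple field: band-limited multi-scale noise (Gaussian-filtered white
  noise at σ = 4 and 10 px), min–max normalized and scaled by the crumple
  intensity (per-scene draw U[0.25, 2.25]). It is rendered as a smooth
  displacement warp of the weave (nearest-neighbor resampling, amplitude
  1.6 px per intensity unit) plus multiplicative shading (±18% per unit,
  plus a fine σ = 2 px component at 4%). Shading alone is locally a
  monotone intensity map that LBP ignores; the warp is what makes crumple
  visible to the texture operator. Nearest-neighbor resampling avoids the
  low-pass smoothing of bilinear warps, keeping windowed contrast monotone
  in the fold amplitude;
* blood staining: pixels are stained in decreasing order of a score that
  mixes the crumple field with smooth noise (the `stain_spread` parameter
  sets the mixing weight), so blood pools in folds. Each pixel has an
  absorption capacity ρ0·(1 + 0.8·crumple), where ρ0 is a flat-gauze
  whole-mask capacity of 12 g divided by the mask pixel count; pixels are
  filled until cumulative capacity reaches the target mass, and the
  per-pixel mass map is scaled to sum to the label exactly. Stain color is
  a semi-transparent dark red (α = 0.72) modulated by the weave, so the
  crumple signature survives inside the stain while the rendered color
  encodes extent rather than density.

The capacity model is the deliberate confound: stained *extent* alone
under-determines mass (two gauzes with equal stained area but different
crumple hold different masses, by up to a factor ≈ 2.6 across the intensity
range), which is exactly why the CS and P-W CS variants should beat the
image-only baseline, and the patch-wise variant should beat the global one
when crumple varies spatially within a scene.

Per-gauze mass labels are drawn from a scaled Beta(2, 2.88) on
[0.13, 9.98] g with mean 4.17 g, emulating the reported intraoperative
per-gauze range. Synthetic patients group 1–10 consecutive gauzes.
Train/val/test splits are 3:1:1, dealt block-wise over the mass-sorted
samples so every split spans the weight range.

What the generator does **not** emulate: specular highlights, smoke, motion
blur, partial occlusion by instruments, camera color calibration, or the
true mapping from stain appearance to grams on woven cotton (no public
calibration exists, so the mass→appearance function is a stated modeling
choice). Passing tests therefore demonstrate pipeline correctness and
qualitative signal recovery under the assumed structure, not clinical
accuracy on real surgical video.

## Gauze detection

Tiles (default 64 px, stride = tile size) are classified into four states —
background tissue, clean, stained, soaked gauze — by a small CNN: three
conv(3×3)/ReLU/max-pool blocks of widths 8/16/24 on 24 px inputs, global
average pooling, and a softmax head. VGG-, GoogLeNet- and EfficientNet-style
backbones (stacked 3×3 pairs, parallel 1×1/3×3/5×5 branches,
depthwise-separable blocks with Swish) are available as desk-scale
architectural sketches of those families; none are pretrained. The whole
numeric core (convolutions, Adam, losses) is a compact in-package
implementation on NHWC numpy arrays, deterministic under a fixed seed and
verified against finite differences.

A pixel is gauze iff the mean gauze probability (clean+stained+soaked) of
all tiles covering it is ≥ 0.5; uncovered remainder strips are background;
a 5 px binary closing (optional, default on) removes grid artifacts. Hard
labels break probability ties toward the lower class index in the fixed
order. For pixel-accurate masks the pipeline defaults to a finer inference
grid (32 px tiles, stride 16), which raised pixel-level mask
sensitivity/specificity well above the 64 px masking grid in development;
the coarse grid remains the default for patch extraction, where one tile =
one patch is the point.

## Regression

All variants share the image path: masked gauze image → tight bounding-box
crop → centered square pad → resize to `input_side` (default 64 px, chosen
so CPU-only training stays in minutes while stain extent and weave remain
resolvable) → per-channel standardization by training-split statistics →
small-CNN backbone → global average pooling. CSV features are standardized
by training-split mean/sd (constants stored with the model); the feature
MLP has ReLU hidden layers of widths [32, 16]. Image feature and MLP output
are concatenated and a fully connected head with linear (default) or ReLU
activation emits grams. Training uses MAE loss (MSE available), Adam with
learning rate 5e-3, batch size 32, best-validation-epoch weight selection,
and per-epoch loss logging; the recorded batch loss is exactly the stated
formula on that batch. Predictions are clamped at 0 g.

## Evaluation protocol

MAE (g), MAPE (%) and MSE (g²) are computed per gauze and stratified by
true mass (≤ 3 g, 3–5 g, > 5 g). The overall row pools all samples; an
unweighted stratum-mean row can be emitted alongside because the two differ
on imbalanced strata. MAPE refuses true values below 0.01 g (below the
smallest mass the protocol emulates) instead of emitting exploding
percentages. Per-patient evaluation sums each patient's predicted and true
totals before computing errors, and agreement is summarized by the
Bland–Altman bias (predicted − true) with 1.96·sd limits. Cross-validation
folds group by patient (no leakage across folds) and deal mass-ranked
patients round-robin into k folds, so fold sizes differ by at most one
patient. Relative improvements are 100·(ref − new)/ref, reported to two
decimals.

## Reference experiment sizes

The packaged experiments (`gauzeloss.experiments`) run at desk scale, the
package's standard conditions: the tile classifier trains on ~1000–2500
tiles harvested from 30 scenes at both applied tile scales (8 epochs); the
variant-ordering comparison uses 300 scenes split 3:1:1, 25 epochs per
variant, averaged over 3 seeds;
the bookkeeping check runs the full pipeline over 20 frames including two
gauze-free frames. A single global seed fans out to per-stage seeds via a
CRC-32 hash of the stage name, so every stage is independently
reproducible.

## Known limitations

* The numeric core is CPU-bound pure numpy; it is not meant for 1920×1080
  inputs or EfficientNet-scale capacity, and the named backbone styles are
  sketches, not reproductions of the original architectures or weights.
* Blood-evidence patch weighting inherits any classifier miscalibration;
  the `ground_truth_mass` mode quantifies the gap on synthetic data only.
* The synthetic mass→appearance mapping is a modeling choice; absolute
  error levels on synthetic scenes do not transfer to surgical video.
* Masks come from tile voting, not per-pixel segmentation; very thin gauze
  protrusions below tile size are missed by construction.
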