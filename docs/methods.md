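# Methods

## Problem and scope

The package predicts the binary vesicoureteral-reflux (VUR) status of a
paediatric patient from a posterior static renal DMSA scintigram, using
per-side VCUG grades (0–5) as reference standard. The clinical cohort the
protocol was designed around is private, so the package ships a synthetic
phantom generator as a first-class module; every end-to-end claim made by
the test suite is a property of the method measured on phantoms, not a
reproduction of clinical performance.

## Phantom image formation

A scan is rendered on a 256×512 8-bit canvas (large enough that the
bounding-rectangle crop is non-trivial) as

    I(x) = B + (C − B) · Σ_side f_side(x) · Π_k h_k(x),

with background level `B = 28`, cortical level `C = 185`, `f_side` an
elliptical uptake profile (semi-axes 72×44 px, cosine-tapered rim whose
fractional width is `edge_softness = 0.18`), and `h_k` multiplicative
Gaussian-profile photopenic holes planted on a mid-cortical ring. The
number, fractional depth and radius of holes are non-decreasing lookup
tables of the planted grade, so expected within-kidney uptake is
monotonically non-increasing in grade — the one property the classifier
must exploit. Poisson noise is applied last (2 counts per intensity unit,
i.e. σ ≈ √(I/2) grey levels) and the image is clipped and quantised to
[0, 255]. Grade-0/0 patients are exactly mirror-symmetric before noise.

Cohorts fix the positive fraction exactly (`round(n·prevalence)`); the
more affected side of a positive draws its grade from a distribution over
1–5 (mass 0.14/0.20/0.26/0.24/0.16), the other side is 0 with probability
0.65, else a grade up to the primary's — reflecting the predominance of
unilateral reflux. A `strong_effect_config` variant (deeper/larger
defects, positives at grade ≥ 3) defines the scaled-down learning study;
it exists so a small network can separate classes from ~50 training scans.

What the phantom does **not** model: attenuation, scatter, collimator
blur, patient motion, anatomy beyond two kidneys (liver/spleen uptake),
acquisition-parameter drift. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the architecture can learn
uptake-defect phenotypes — not that clinical-grade accuracy transfers to
real scans.

## Preprocessing

1. **Background correction** — Otsu's threshold (256-bin histogram)
   detects the kidney foreground; one rectangular background ROI of 25%
   of each kidney's bounding-box area is placed at a 5-px diagonal offset
   above-left of the left kidney and above-right of the right; the pooled
   mean over both ROIs is subtracted per pixel, clipping at 0. Pooling
   (rather than per-kidney correction) keeps left/right intensities
   comparable for the severe-side rule; this is one consistent reading of
   "integral background subtraction" where several exist.
2. **Delineation and crop** — Otsu on the corrected image; components
   smaller than 200 px are ignored. The midline is the mean
   column-centroid of the two largest components, computed once per scan
   and kept fixed. If only one kidney is detected its mask is mirrored
   across the canvas centre column to complete the bilateral outline. The
   crop is the minimum bounding rectangle of the mask union with ≥ 10-px
   margins (clamped at borders), widened so the midline sits at the crop
   centre, padded to a 2:1 aspect with the background median (padding
   never discards kidney pixels), and bilinearly resized to 224×448.
   Splitting at the midline yields two 224×224 per-kidney inputs; the
   per-side mean intensity is taken over the kidney mask (tracking tracer
   uptake), not the full half-image.
3. **Augmentation** (training only, fully seeded) — horizontal flip
   (p = 0.5), rotation uniform in ±15°, random resized crop (area
   0.8–1.0), brightness ±15% of 255 and contrast ±15%.
4. **Normalisation** — `x/255`, then standardisation with mean 0.5 and
   std 0.25. The constants are fixed package defaults (phantoms are not
   ImageNet images; any fixed affine map is equivalent for training).

Coordinates are row-major, 0-based, with half-open boxes throughout.

## Severe-side selection

Grades differ → the higher-grade kidney; equal positive grades → the
lower mean-uptake kidney (exact ties resolve to the left, a fixed
deterministic rule); both grades 0 → a pseudo-random side keyed on
(global seed, SHA-256 of patient id), so the choice is reproducible and
invariant to dataset ordering. The rule is label-informed by design and
is used for training inputs only; evaluation also covers the bilateral
setting, where both kidneys are scored and a patient is positive iff
either side is (logical OR).

## Classifier

A four-stage hierarchical windowed-attention backbone (patch embedding,
window attention with relative position bias, shifted windows on
alternate blocks, patch merging between stages) produces features
`F_i ∈ R^{C_i×H_i×W_i}`. All stages are unified to a common grid by
bilinear interpolation — downsampling to the stage-4 grid by default; an
upsampling variant aligns at the stage-1 grid — implemented as two
constant interpolation-matrix products (half-pixel-centre convention), so
constants are preserved exactly. Each stage is projected to the stage-4
channel width by a 1×1 convolution (the stages have different widths and
the weighted sum requires a common shape), and fused as
`F_fused = Σ α_i · proj(F̃_i)` with `α = softmax(g)`, `g ∈ R⁴` learnable
and initialised to zero (an unbiased uniform mix). CBAM then recalibrates
the fused map — channel gate: sigmoid of a shared bottleneck MLP
(reduction ratio 16) applied to the global average- and max-pooled
descriptors; spatial gate: sigmoid of a 7×7 convolution over the
channel-wise average/max maps — followed by a 1×1 convolution, global
average pooling and a linear head to two logits. CBAM precedes the 1×1
convolution; average pooling is used for the global pool. Ablation flags
reconstruct the incremental variants: backbone-only, up-/down-sampling
fusion, +CBAM, +gating, full model.

Two scales are configured: `paper_scale` mirrors the standard Swin-T
layout (embed 96, depths 2/2/6/2, heads 3/6/12/24, MLP ratio 4);
the desk-scale default uses embed 24, depths 2/2/2/2, window 7, MLP
ratio 2, no pretrained weights. Scaled-down experiments additionally
reduce the input to 128×128 with window 4 (stage grids 32/16/8/4), which
cuts the stage-1 token count ~3× and keeps a training run under a minute
on one CPU.

The network and optimiser run on `scintivur.nn`, a reverse-mode autodiff
engine over numpy written for this package (the pre-installed stack has
no deep-learning framework, and the architecture cannot be expressed in
scikit-learn). The op set is minimal; every op and the composed blocks
are checked against central finite differences at float64. Training uses
float32 (a `default_dtype` context), which roughly halves CPU time.

## Training protocol

Patient-level splits: 10% of patients (rounded) form an independent test
cohort; the rest are partitioned into k approximately equal folds (k = 10
at full scale; fold sizes differ by ≤ 1; a 346-patient manifest yields
311 development / 35 test with folds of 31–32). Each fold trains on the
other folds' severe-side inputs with augmentation — AdamW, lr 1e-4,
weight decay 0.01, cross-entropy, batch 3 — and validates each epoch
under both settings. Early stopping halts after 20 consecutive epochs
without improvement of severe-side validation accuracy (ties broken by
lower validation loss — the monitored quantity is otherwise coarse on
small folds); the best epoch's weights are kept. `max_epochs` caps runs
at 300. The per-fold seed is `global seed + fold index`, so folds are
reproducible independently of training order. Test patients can never
contribute a gradient: the split plan rejects any overlap at
construction and `train_fold` re-audits the id sets.

Test metrics are reported two ways, both emitted: per-fold metrics
aggregated as mean ± t-based 95% CI (`mean ± t_{0.975,k−1}·sd/√k`), and
metrics of the element-wise fold-averaged confusion matrix (which may be
fractional — all metric formulas are evaluated on reals, and rounding to
3 decimals happens only at report time). Cohen's kappa is omitted for
fold-averaged model matrices, where per-case agreement is undefined.
Probability 0.5 on the positive-class softmax converts scores to labels;
AUC is threshold-free (Mann–Whitney form with half-credit for ties).

## QC battery

Eight per-image metrics: mean and standard deviation of grey level,
p95−p05 dynamic range (linear-interpolation percentiles, pinned for bit
stability), sharpness as the variance of the 3×3 Laplacian response
([[0,1,0],[1,−4,1],[0,1,0]], edge-repeating reflection padding), base-2
Shannon entropy of the 256-bin histogram, fractions of pixels ≤ 5 and
≥ 250, and file size in KB. Mann–Whitney U and two-sample KS compare
train vs test per metric: exact methods for tie-free samples of size ≤ 8,
asymptotic otherwise (with tie correction for MWU), matching mainstream
stats-package behaviour and letting small-sample p-values agree with
brute-force enumeration. A metric is flagged when either p < α (default
0.05, per metric). Identical constant groups are degenerate; p is
reported as 1 with a warning. Two-sided tests are used throughout.

Note on the battery's family-wise behaviour: with per-metric flagging at
α = 0.05 and several effectively varying metrics, the probability that a
random split of a homogeneous cohort raises *some* flag is roughly
13–20%, even though each individual metric flags at its nominal 3–6%
rate. A battery-level "no shift anywhere" statement therefore holds in
most, but not ≥ 95%, of random splits; users wanting a family-wise
guarantee should divide α by the number of tests.

## Scaled-down studies and problem sizes

`scintivur.experiments` fixes the study the tests and the acceptance
script share: a 60-patient, 50%-prevalence strong-effect cohort; 5 folds
(validation folds of ~11 patients keep both classes present); the
128×128/window-4 network; 12 epochs with patience 12 at the protocol
learning rate (the strong effect separates by epoch ~8–10). The QC
non-shift study re-splits one 60-patient homogeneous cohort 100 times at
the protocol's 9:1 ratio. These sizes are the package's chosen desk-scale
conditions; the full-scale configuration (224×224, window 7, 10 folds,
patience 20) remains the default elsewhere.

## Known limitations

The phantom omits most physics of SPECT acquisition, so no claim about
clinical accuracy follows from the tests. The severe-side rule uses
reference labels and is a research setting, not a deployable reader. The
engine is CPU-bound and sized for small cohorts. Pretrained backbone
weights are not bundled; the `paper_scale` configuration trains from
random initialisation only. Calibration assessment, decision-curve
analysis and saliency visualisation are out of scope.
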