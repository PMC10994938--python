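# Methods

This note records the models, conventions and design choices behind
`mrisr`, in the order data flows through the package.

## K-space degradation

Low-resolution inputs are synthesized from high-resolution magnitude
images by truncating the spectrum: orthonormal FFT, centre shift with DC
at 0-based index `(H//2, W//2)` (even and odd sizes alike), crop of the
central `(H/f, W/f)` block with the half-open window
`[N//2 − M//2, N//2 + (M+1)//2)` per axis, inverse transform, magnitude.
The cropped coefficients are multiplied by `sqrt(Mh·Mw/(Nh·Nw))` so that
a constant image maps to the same constant; low- and high-resolution
images therefore live on one intensity scale, which keeps the
mean-shift normalisation of the network well posed. Taking the
magnitude of the inverse transform guarantees the nonnegativity
invariant of `GrayImage`. Pixel spacing grows by the truncation factor,
so `shape × spacing` (the field of view) is invariant through every
degradation and up-sampling operator — a property the tests assert.

Intensity pre-processing before metrics follows the evaluation recipe:
clip above the 99.9th percentile (linear-interpolation quantile on the
sorted flattened image — one explicit rule so the clip is reproducible),
min-max scale to 0–4096, and clamp at 4096. A constant image cannot be
min-max scaled; the operator warns and returns the lower bound.

## Network

The super-resolution network is a residual CNN in the EDSR family:
head conv (1→F), `B` residual blocks (conv F→F, ReLU, conv F→F, output
scaled by 0.1 and added back; no batch normalisation), tail conv with a
global skip from the head output, then one `conv F→4F` + 2× pixel
shuffle stage per doubling (two stages at scale 4), and a final conv to
one channel. All kernels are 3×3, stride 1, zero padding. The
per-image mean is subtracted before the head and added to the output;
with all weights zero the network is therefore the identity on constant
images, a contract the tests check exactly.

The baseline-large configuration `B = 32`, `F = 256` is fixed by its
parameter budget: the closed-form count `Σ (9·C_in + 1)·C_out` gives
43,080,705 ≈ 43 M trainable parameters at scale 4 with one channel, and
the automatic per-tensor count must agree exactly. Desk-scale work
(training, examples, tests) uses tiny configurations (`B ≤ 2`,
`F ≤ 8`); the full-size model is only ever built and counted.

Forward, backward and Adam live in `mrisr.nn` as a small NumPy layer
library (im2col convolutions; exact adjoints, verified against central
finite differences in the tests). Weight init is Kaiming-uniform with a
recorded seed. 2×→4× parameter transfer copies every non-upsampler
tensor bitwise and freshly initializes the pixel-shuffle stages, which
do not exist at the same shape in the 2× model.

Model bundles serialize architecture + weights + provenance into one
file: a magic header, a version, a length-prefixed JSON block and raw
little-endian float64 weights in sorted name order. The format is
deterministic (two saves are byte-identical) and validates on load.

## Training

Pairs are built inline per batch: a uniformly random HR crop of the
label (default 192, divisible by the scale) and its k-space-truncated
counterpart. The loss is `mean|ŷ−y| + λ·mean|E(ŷ)−E(y)|` with `E` the
3×3 Sobel gradient magnitude under symmetric boundary padding and
`λ = 1` by default; the Sobel operator is the simplest choice matching
an edge-sensitive objective and is exposed in `TrainConfig` so a
different operator or weight can be swapped in. The loss gradient uses
the exact adjoint of pad-then-correlate (boundary contributions folded
back) with an ε-smoothed magnitude.

Optimisation is Adam (default moments) under a one-cycle schedule:
cosine warm-up from `max_lr/25` to `max_lr` over the first 30% of
steps, cosine anneal to `max_lr/10⁴`. The per-stage peak learning
rates default to 1e-5 (2× base stage), 5e-5 (4× transfer stage) and
1e-6 (fine-tune stage). Data are split 90/10 by image with the run
seed; validation uses fixed centre crops so tracked metrics (edge-L1,
NRMSE, SSIM, PSNR) are comparable across epochs. The returned bundle
is the epoch of **minimum validation edge-L1**, not the last epoch.
Non-finite losses abort with a diagnostic. Runs are bitwise
reproducible under a fixed seed.

For the desk-scale learning demonstration (tiny model, 200 phantoms,
30 epochs) the open hyperparameters are `max_lr = 1e-3`, batch 8, crop
64: values a practitioner would default to for a 2-block, 8-feature
model, where the full-scale stage rates above would barely move the
weights in 30 epochs.

## Evaluation

Metric dialects are normative for this package because the names alone
underdetermine them:

* NRMSE = RMSE / (max(ref) − min(ref)); undefined for a constant
  reference (error).
* SSIM: 11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03, data
  range = reference range, population (not sample) moments; the
  unmasked value averages the local map over the edge-cropped interior,
  the masked value averages the full local map over the mask. An
  independent sliding-window implementation in the tests agrees to
  1e-8.
* PSNR = 10·log10(range²/MSE), capped at 100 dB on identical images to
  avoid infinities in logs.

The reference-derived mask is Otsu threshold → binary closing
(radius-2 disk) → hole fill → largest connected component, applied
jointly to every method's image so no method is advantaged. Rigid
registration (when enabled) maximises normalised cross-correlation by a
coarse rotation sweep (phase correlation supplying the translation per
candidate angle) followed by Nelder-Mead refinement of
`(θ, dy, dx)`, with bilinear resampling; it returns the identity with a
warning flag if it cannot beat the identity score. Paired method
comparisons use the classical paired t test with two-sided p values and
no family-wise correction (comparisons are reported per metric/method
pair); zero-variance differences degenerate to `t = 0, p = 1` (zero
mean) or a flagged infinite statistic.

## Tracking simulation

The phantom is a sphere of radius 30 mm (cross-section rendered with a
one-pixel linear partial-volume ramp, which is translation-equivariant
and puts the half-intensity contour exactly at the radius) in a 400 mm
field of view, moving along the column axis — 1-D motion with 2-D
rendering, matching a one-dimensional motion stage. Frames are
rendered at the 256 HR matrix, truncated to the tracking matrix
(default 64), optionally up-sampled, and localised by normalised
cross-correlation against a template cut from the zero-displacement
reference frame, with optional sub-pixel refinement by a parabolic fit
to the 3×3 correlation neighbourhood. A peak correlation below 0.5
signals a lost target; the chain then holds the last displacement (the
safest deterministic policy).

Timing follows a mid-exposure convention: frame k represents the target
at `t_k = k·T_frame` and its displacement command is issued at
`t_k + (recon + SR + tracking + MLC delays)`. Commands are held until
the next frame's command, and that zero-order hold contributes exactly
`T_frame/2` of group delay for sinusoid phase fits — so the injected
end-to-end latency is `T_frame/2 + Σ stage delays` without double
counting. `frame_period = 0` selects an idealized continuous-imaging
limit (the trace itself is the frame stream; zero imaging latency),
which is the only regime where a perfect-localiser, infinite-velocity
chain reproduces the target identically. The MLC is modelled as a
single aperture centroid moving toward the latest command at most
`v_max·dt` per control tick (default 25 mm/s — a typical leaf-speed
order of magnitude — at 100 Hz); per-leaf geometry, dose and
out-of-plane motion are out of scope. A settle window (stage delays
plus two frame periods) is trimmed from the returned traces so the
start-up transient does not bias the analysis; both traces are then
sampled at the 3.6 Hz portal-imager rate.

Latency estimation fits `a·sin(2πft) + b·cos(2πft) + c` to the target
trace with `f` refined from a periodogram initialisation (fine grid
scan + bounded polish — the residual valley in `f` is narrow), then
fits the aperture with `f` held fixed; the latency is the wrapped phase
difference over `2πf`, and a target residual above 50% of variance is
rejected as non-sinusoidal. Geometric error linearly resamples the
aperture onto the target timestamps; the latency-corrected error first
advances the aperture timestamps by the measured latency. For a
pure-delay aperture the corrected error vanishes to interpolation
precision, and the uncorrected error follows the identity
`A·√2·|sin(πfτ)|` — both are asserted numerically.

The breathing-trace generator is a statistical surrogate (per-cycle
period/amplitude jitter around a 4 s / 10 mm cycle plus two slow
random-phase drift sinusoids); with zero jitter and drift it reduces
exactly to the sinusoid generator. Because it is a surrogate rather
than a measured patient trace, absolute RMSE magnitudes from the
simulated experiment are not comparable to hardware measurements — only
orderings and decompositions are meaningful, and those are what the
tests assert.

## Synthetic phantoms

Anatomy-like labels are nested anti-aliased ellipse composites (outer
ring, inner compartment, paired ventricle analogues, random internal
ellipses), thin sinuous curves splatted with bilinear weights (fine
edge content for the edge loss), and mild smoothed texture, emitted in
three contrast profiles (T1-, T2- and FLAIR-like intensity orderings)
mixed uniformly so multi-sequence training is exercised. Intensities
span [0, 4096]; generation is pure given the recipe. These phantoms
deliberately trade anatomical realism for analytic ground truth (masks,
centroids, determinism): passing tests show the pipeline's operators
and learning machinery work, not that a tiny model generalises to
clinical MRI, where noise, coil profiles and sequence-dependent
contrast are absent here. The degradation → bicubic NRMSE on these
labels is strictly positive, so a learned model has genuine headroom.

## Problem sizes

Desk-scale sizes keep every run on one CPU: phantoms at 128–256
matrices, tiny networks (≤ 2 blocks, ≤ 8 features), 30-epoch training
on 200 labels (~half a minute), tracking runs of 30–40 s simulated time
at 4 Hz, and brute-force DFT oracles at sizes ≤ 32. The full-size
network is instantiated only to count parameters.
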