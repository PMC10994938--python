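# mrisr

Super-resolution for real-time MRI guidance, end to end and in silico:
k-space-truncation degradation for paired training data, a residual
pixel-shuffle super-resolution network trained with an edge-weighted L1
loss, masked full-reference evaluation against interpolation baselines,
and a simulated multi-leaf-collimator (MLC) beam-tracking experiment
that measures end-to-end latency and latency-corrected geometric error.

## The problem

Real-time MRI trades spatial against temporal resolution: at the ~4 Hz
frame rates needed to track a moving tumour on an MRI-linac, only a
coarse matrix (e.g. 64 × 64 over a 400 mm field of view, 6.25 mm
pixels) can be acquired per frame. Single-image super-resolution can
restore a 256 × 256 matrix (1.56 mm pixels) from each low-resolution
frame in milliseconds, so the targeting system sees fine-grained
anatomy without paying the acquisition-time cost of a native
high-resolution scan. This package implements that pipeline for
researchers in MRI-guided radiotherapy and real-time MR imaging, with a
synthetic phantom generator so every component runs and is tested with
no external data.

## The model

Low-resolution inputs are synthesized from high-resolution labels by
**k-space truncation**: with an orthonormal centred 2-D Fourier
transform `F`, the degradation is

    x_LR = | F⁻¹[ crop_{N/f}( F x_HR ) · √(M/N) ] |

— the central block of the spectrum (low spatial frequencies) is
retained, rescaled so a constant image keeps its value, and inverse
transformed. This is how a fast coarse acquisition relates to a slow
fine one on the scanner.

The learned up-sampler is an **EDSR-style residual CNN**: a head
convolution, `B` residual blocks (conv–ReLU–conv with residual scaling
0.1 and no batch normalisation), a tail convolution with a global skip,
one conv + pixel-shuffle stage per resolution doubling, and a final
convolution to one channel. The per-image mean is subtracted on entry
and added back on exit. At the baseline-large configuration
(`B = 32`, `F = 256`, scale 4, single channel) the network has
43,080,705 ≈ 43 M trainable parameters. Training minimises

    L = mean|ŷ − y| + λ · mean| E(ŷ) − E(y) |,   E = Sobel gradient magnitude

with Adam and a one-cycle learning-rate schedule; the kept checkpoint is
the epoch of minimum validation edge-L1. The forward pass, backprop and
optimiser are implemented in NumPy (`mrisr.nn`), which is ample for the
desk-scale configurations this package trains.

The tracking testbed moves a ~30 mm-radius spherical target on
sinusoidal or breathing-like 1-D traces, renders 4 Hz cine frames,
degrades them in k-space, optionally up-samples, localises the target by
normalised cross-correlation template matching, and drives a
velocity-limited MLC aperture after the imaging-chain delays.
End-to-end **latency** is the phase shift between sinusoid fits to the
target and aperture traces; the **latency-corrected RMSE** re-aligns the
aperture trace by that latency, isolating tracking error from delay
error.

## Worked example

`examples/02_train_tiny_model.py` trains a 2-block, 8-feature 4× model
on 200 synthetic phantoms (about half a minute on one CPU) and compares
it with bicubic interpolation on 20 held-out phantoms:

```
 epoch  train_loss  val_edge_l1  val_nrmse  val_ssim
     0 1775.020339  1566.657678   0.176645  0.274732
     9 1074.655048   981.291437   0.060922  0.711264
    19 1043.606625   970.880486   0.060091  0.717996
    29 1057.279949   968.623193   0.059669  0.719739
best checkpoint: epoch 25
edsr     held-out NRMSE 0.0505  SSIM 0.7935
bicubic  held-out NRMSE 0.0838  SSIM 0.6325
```

The validation edge-L1 falls as the network learns to restore the high
spatial frequencies that k-space truncation removed; on held-out
phantoms the learned model reaches lower NRMSE and higher SSIM than
bicubic interpolation. `examples/04_tracking_latency.py` runs the
in-silico latency experiment (triplicate, like a phantom session):

```
           method  latency_s  latency_sd  rmse_mm  rmse_sd  rmse_corrected_mm  rmse_corrected_sd  n_repeats
     none (64x64)       0.18         0.0    2.059    0.076              0.425               0.01          3
bicubic (256x256)       0.18         0.0    2.055    0.079              0.416               0.01          3
```

Up-sampling leaves the latency unchanged (the imaging chain dominates)
while the corrected RMSE — the part of the error the images are
responsible for — improves with the finer tracking grid.

The other examples cover degradation and baselines (`01`), masked
evaluation with paired statistics (`03`), and the per-frame streaming
contract (`05`). A thin CLI (`mrisr degrade|train|infer|evaluate|track-sim|report`)
wraps the same entry points for shell use with NIfTI volumes.

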