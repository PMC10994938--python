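"""Build a paired low/high-resolution image by k-space truncation and
compare up-sampling baselines.

A synthetic brain-like phantom serves as the high-resolution label; its
spectrum centre is cropped 4x (64x64 from 256x256), which is how a fast
low-resolution MR acquisition relates to a slow high-resolution one.
Nearest and bicubic interpolation then restore the matrix size and are
scored against the label.
"""

import numpy as np

from mrisr import (PhantomRecipe, gen_anatomy_phantom, kspace_downsample,
                   nrmse, psnr, ssim, upsample_bicubic, upsample_nearest)

label = gen_anatomy_phantom(PhantomRecipe(seed=0, matrix=256))
print(f"label: {label.shape} at {label.spacing[0]:.4f} mm pixels "
      f"(FOV {label.fov[0]:.0f} mm)")

lr = kspace_downsample(label, 4)
print(f"input: {lr.shape} at {lr.spacing[0]:.2f} mm pixels "
      f"(same FOV {lr.fov[0]:.0f} mm)")

for name, up in [("nearest", upsample_nearest(lr, 4)),
                 ("bicubic", upsample_bicubic(lr, 4))]:
    print(f"{name:8s} NRMSE {nrmse(up, label):.4f}  "
          f"SSIM {ssim(up, label):.4f}  PSNR {psnr(up, label):.1f} dB")

# The NRMSE is strictly positive: truncating k-space destroys high
# spatial frequencies, which is the information a learned model tries
# to restore (see 02_train_tiny_model.py).
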