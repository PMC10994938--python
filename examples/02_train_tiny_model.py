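"""Train a tiny residual super-resolution network on synthetic phantoms.

A desk-scale configuration (2 residual blocks, 8 feature maps; the
full-size model uses 32 blocks and 256 features, ~43 M parameters)
trains in about half a minute on one CPU with the edge-weighted L1 loss,
Adam and a one-cycle learning-rate schedule.  The checkpoint kept is the
epoch with minimum validation edge-L1.  The trained model is then
compared with bicubic interpolation on held-out phantoms.
"""

import numpy as np

from mrisr import (EDSRConfig, TrainConfig, build_edsr, forward_sr,
                   gen_label_set, kspace_downsample, nrmse, ssim,
                   train_stage, upsample_bicubic)

labels = gen_label_set(200, seed=42, matrix=128)
cfg = TrainConfig(stage="scale4_transfer", max_lr=1e-3, label_crop=64,
                  batch=8, epochs=30, seed=0)
model = build_edsr(EDSRConfig(scale=4, n_resblocks=2, n_feats=8), seed=0)
bundle, log = train_stage(model, labels, cfg)

df = log.to_dataframe()
print(df[["epoch", "train_loss", "val_edge_l1", "val_nrmse", "val_ssim"]]
      .iloc[[0, 9, 19, 29]].to_string(index=False))
print(f"best checkpoint: epoch {bundle.metadata['best_epoch']}")

held_out = gen_label_set(20, seed=777, matrix=128)
best = bundle.build()
nr = {"edsr": [], "bicubic": []}
ss = {"edsr": [], "bicubic": []}
for lab in held_out:
    lr = kspace_downsample(lab, 4)
    for name, up in [("edsr", forward_sr(best, lr)),
                     ("bicubic", upsample_bicubic(lr, 4))]:
        nr[name].append(nrmse(up, lab))
        ss[name].append(ssim(up, lab))
for name in ("edsr", "bicubic"):
    print(f"{name:8s} held-out NRMSE {np.mean(nr[name]):.4f}  "
          f"SSIM {np.mean(ss[name]):.4f}")
# Lower NRMSE / higher SSIM for the learned model means it restored
# edge detail that interpolation cannot recover from the truncated
# spectrum.
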