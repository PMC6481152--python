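"""Train detector + segmentator on phantoms and segment a held-out image.

A deliberately small run (a few minutes on one CPU core): both networks
share the 6-conv architecture (patch side 29, same padding, small filter
banks) and train with Adam on balanced minibatches.  The two-stage
pipeline then screens overlapped 29x29 tiles with the detector and
classifies every foreground pixel of the flagged tiles with the
segmentator.
"""

from dataclasses import replace

import numpy as np

from mcseg import (
    NetworkConfig,
    PhantomConfig,
    TrainSchedule,
    generate_phantom,
    lesionwise_recall,
    otsu_foreground,
    pixel_metrics,
    run_pipeline,
    train,
)
from mcseg.patches import PatchDatabase
from mcseg.nn import make_eval_set

phantom = PhantomConfig(image_height=128, image_width=128, n_mcs=8, mc_diameter_range=(2, 11))

db = PatchDatabase(patch_side=29)
for i in range(8):
    cfg = replace(phantom, seed=i)
    image, mask = generate_phantom(cfg)
    split = "val" if i >= 6 else "train"
    db.add_image(f"ph_{i}", image, mask, otsu_foreground(image).pixels, split=split)

net_cfg = NetworkConfig(patch_side=29, padding_mode="same", conv_filters=(8, 8, 16, 16, 16, 16))
rng = np.random.default_rng(0)
models = {}
for role, steps in (("detector", 150), ("segmentator", 180)):
    schedule = TrainSchedule(batch_size=128, max_steps=steps, seed=1)
    val = make_eval_set(db, role, 256, rng, split="val")
    models[role] = train(net_cfg, db, role, schedule, val)
    print(f"{role}: best val loss {min(models[role].history['val_loss']):.4f} "
          f"at step {models[role].stopping_step}")

test_image, test_mask = generate_phantom(replace(phantom, seed=99))
pred, grid, fg = run_pipeline(models["detector"], models["segmentator"], test_image)
m = pixel_metrics(pred, test_mask, fg.pixels)["all"]
print(f"held-out phantom: {grid.stats['n_flagged']}/{grid.stats['n_tiles']} tiles flagged, "
      f"pixel accuracy {m.accuracy_pct:.2f}%, FPR {m.fpr_pct:.3f}%, "
      f"lesionwise recall {lesionwise_recall(pred, test_mask):.2f}")
# recall counts a lesion as found when any of its pixels is predicted;
# FPR is the fraction of truly-negative pixels predicted positive
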