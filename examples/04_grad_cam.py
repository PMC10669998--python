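"""Grad-CAM heatmaps from a trained miniature model.

Trains a small network briefly on synthetic scans, then renders Grad-CAM
panels for one test image per class.  The heatmap weights the deepest
attention block's channels by the class logit's spatially averaged gradient;
bright regions are the areas the classifier used for its decision.
"""

import numpy as np

from octattn.explain import grad_cam, save_panel
from octattn.io import load_images
from octattn.network import NetworkConfig, StageConfig, build_network
from octattn.synthetic import SyntheticConfig, default_bands, fixed_split, generate_dataset
from octattn.training import TrainConfig, predict, train

syn = SyntheticConfig(
    image_side=96, bands=default_bands(96 / 224), foveal_dip_depth=4.0,
    surface_curve_amp=2.5, counts={"bipolar": 16, "control": 16}, seed=1,
)
manifest = generate_dataset(syn, "example_gradcam_data")
manifest = fixed_split(
    manifest,
    {(c, k): 12 for c in ("left_to_right", "top_to_bottom")
     for k in ("bipolar", "control")},
    seed=1,
)
train_df = manifest.subset(case="left_to_right", split="train")
test_df = manifest.subset(case="left_to_right", split="test")
Xtr, ytr, classes = load_images(train_df, side=96)
Xte, yte, _ = load_images(test_df, side=96, class_names=classes)

net = build_network(
    NetworkConfig(input_side=96, stem_filters=16,
                  stages=(StageConfig(16, repeats=2),
                          StageConfig(32, repeats=2, followed_by_downsample=False))),
    seed=1,
)
train(net, (Xtr, ytr), None, TrainConfig(epochs=6, mini_batch=12, seed=1))
pred, probs = predict(net, Xte)
print(f"test accuracy: {100 * (pred == yte).mean():.0f}%")

for cls_index, cls_name in enumerate(classes):
    i = int(np.flatnonzero(yte == cls_index)[0])
    hm = grad_cam(net, Xte[i])
    out = f"example_gradcam_{cls_name}.png"
    save_panel(out, Xte[i], hm)
    print(f"{cls_name}: predicted {classes[hm.target_class]} "
          f"(p={probs[i, hm.target_class]:.2f}); panel -> {out}")
print("Each panel shows original | heatmap | overlay; heatmap values are")
print("normalized to [0, 1] per image, so compare locations, not magnitudes.")
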