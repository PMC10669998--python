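"""Render synthetic OCT B-scans and verify the class effect by measurement.

Generates a small two-class dataset, writes the PNGs, and measures the RNFL
band thickness of each scan with the threshold oracle.  The bipolar class is
rendered with a 40% thinner RNFL band, so its measured thickness should sit
around 0.6x the control value — that gap is what the classifier learns.
"""

import numpy as np
from PIL import Image

from octattn.synthetic import (
    SyntheticConfig,
    generate_dataset,
    measure_rnfl_thickness,
)

config = SyntheticConfig(counts={"bipolar": 5, "control": 5}, seed=0)
manifest = generate_dataset(config, "example_scans")
print(f"wrote {len(manifest.records)} scans under example_scans/")
print(manifest.records.groupby(["case", "class"]).size(), "\n")

for cls in ("control", "bipolar"):
    sub = manifest.records[(manifest.records["class"] == cls)
                           & (manifest.records["case"] == "left_to_right")]
    vals = []
    for _, row in sub.iterrows():
        img = np.asarray(Image.open(row["path"]), dtype=np.float64) / 255.0
        vals.append(measure_rnfl_thickness(img, row["case"]))
    print(f"{cls:8s} RNFL thickness (px): {vals}  mean {np.mean(vals):.1f}")

print("\nA ~14 px control band vs a ~8.4 px bipolar band: the 40% thinning")
print("is directly measurable, which is what makes the dataset separable.")
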