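"""Detect nuclei, build the cell tessellation and extract features.

Cells are the bounded expansion (4.5 µm = 7 px at 0.65 µm/px) of each
nucleus; neighbouring cells meet at the equidistance midpoint.  Channel
intensities are background-corrected (10×-downsized 7×7 median background)
before per-cell means/totals are measured.
"""

import numpy as np

import mplexquant as mq

cfg = mq.TissuePhantomConfig(image_size_px=(512, 512), n_cells=150, seed=42,
                             islet_specs=[((150.0, 150.0), 45.0)])
image, truth = mq.generate_tissue(cfg)

nuclei = mq.detect_nuclei(image.nuclei, smooth_sigma=1.0)
cells = mq.expand_cells(nuclei, expansion_px=7)
print(f"nuclei detected: {nuclei.max()} (planted: {truth.nucleus_labels.max()})")

corrected = {}
for name, chan in image.channels.items():
    bg = mq.estimate_background(chan, window_px=7, downsize=10)
    corrected[name] = mq.subtract_background(chan, bg)
table = mq.extract_features(nuclei, cells, image.with_channels(corrected))

print(f"feature table: {len(table)} cells x {len(table.columns)} columns")
print("nucleus morphology of the first cells:")
cols = ["cell_id", "nucleus_area_um2", "aspect_ratio", "circularity",
        "equivalent_radius_px"]
print(table[cols].head().round(3).to_string(index=False))
print("per-channel intensity summaries, e.g. P16 over the cell region "
      "(cytosolic stain) vs P53 over the nucleus:")
print(table[["P16_cell_mean", "P53_nuc_mean"]].describe().round(2).to_string())
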