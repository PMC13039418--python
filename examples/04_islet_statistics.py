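"""Segment islets and compute islet-level association statistics.

Islets are regions positive for insulin OR glucagon, refined by
closing/opening and hole filling; regions under 400 µm² are excluded.
Islet-level Pearson correlations are the statistic used to relate marker
expression to islet morphology; here the planted population correlation
between islet area and a marker is recovered from 10,000 synthetic islets.
"""

import numpy as np

import mplexquant as mq

cfg = mq.TissuePhantomConfig(image_size_px=(512, 512), n_cells=150, seed=42,
                             islet_specs=[((150.0, 150.0), 45.0),
                                          ((360.0, 360.0), 55.0)])
image, truth = mq.generate_tissue(cfg)

# background-correct the endocrine channels before thresholding
corrected = {}
for name in ("Insulin", "Glucagon"):
    bg = mq.estimate_background(image.channels[name])
    corrected[name] = mq.subtract_background(image.channels[name], bg)
islets = mq.segment_islets(
    corrected["Insulin"], corrected["Glucagon"],
    thresholds=(6.0, 6.0), min_area_um2=400.0, pixel_size_um=0.65,
)
corrected_image = mq.MultiplexImage("r1", corrected, image.pixel_size_um,
                                    nuclei_channel="Insulin")
table = mq.islet_features(islets, corrected_image)
print(f"islets retained (>= 400 um^2): {len(table)}")
print(table[["islet_id", "area_um2", "circularity", "Insulin_mean"]]
      .round(2).to_string(index=False))

# planted islet-level correlation: population r = 0.4 between area and P16
pop = mq.planted_islet_population(10_000, r_target=0.4, seed=1)
r, p = mq.islet_correlation_matrix(pop, ["area_um2", "P16_mean"])
print(f"recovered Pearson r(area, P16) = {r.loc['area_um2', 'P16_mean']:.3f} "
      f"(planted population r = 0.40)")

# occurrence vs islet size: a fraction planted proportional to area
rng = np.random.default_rng(2)
import pandas as pd
area = rng.uniform(500, 10_000, 500)
demo = pd.DataFrame({"area_um2": area,
                     "P16_pos_frac": area / area.max()
                     + rng.normal(0, 0.02, 500)})
summary, r_occ, _ = mq.occurrence_vs_size(demo, "P16_pos_frac", n_bins=5)
print("P16+ occurrence rises with islet area "
      f"(r = {r_occ:.2f} on the planted monotone trend):")
print(summary.round(3).to_string(index=False))
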