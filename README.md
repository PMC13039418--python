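# mplexquant

Quantification of whole-slide multiplexed immunofluorescence images —
built for studies that image a panel of protein markers (for example
senescence markers P16, P21, P53, 53BP1, HMGB1, Lamin B1 alongside
endocrine markers insulin, glucagon, somatostatin-28) over several staining
and imaging rounds of the same tissue section, and then ask single-cell and
tissue-compartment questions: which expression subtypes exist, where do
they sit, and how do marker levels relate to structures such as the islets
of Langerhans.

The package covers the full image-to-statistics path:

1. **Registration** — rounds are aligned on their nuclei (DAPI) channels:
   a global rigid transform `A(x) = R(θ)(x − c) + c + t` estimated by
   normalized cross-correlation on down-sampled images, followed by local
   deformable registration on a coarse grid (default spacing 500 px) whose
   node displacements are estimated at full resolution by windowed phase
   correlation; the dense field is the bilinear interpolation of the nodes.
2. **Segmentation and tessellation** — nuclei from a classical
   detector (pluggable; any external detector producing a label map works),
   then cells as the bounded label expansion of each nucleus: a pixel joins
   its nearest nucleus (Euclidean distance to the nearest nucleus pixel) if
   that distance is at most 4.5 µm (7 px at 0.65 µm/px); equidistant pixels
   between neighbours form the midpoint boundary.
3. **Background-corrected features** — per channel, the background is a
   7×7 median filter applied to the 10×-downsized image, rescaled back;
   features are nucleus morphology (area, aspect ratio, circularity
   `4πA/P²`, equivalent radius `√(A/π)`) and per-channel mean/total
   intensity over nucleus and cell regions after `max(0, I − bg)`.
4. **Islet analysis** — islets are regions positive for insulin OR
   glucagon, refined by morphological closing/opening and hole filling;
   regions under 400 µm² are excluded. Islet tables carry morphology,
   intensity summaries and per-subtype cell censuses; statistics include
   pairwise two-tailed Pearson correlation matrices and subtype occurrence
   as a function of islet size.
5. **Expression landscape** — the cells × markers matrix (nuclear mean by
   default, cell-region mean for cytosolic markers such as P16) is
   restricted to non-overlapping 2000 px ROIs, z-scored per marker,
   projected onto the principal axes capturing 95 % of the variance, and
   clustered with K-means (k = 20 by default). Marker positivity (manual,
   quantile or automatic bimodal threshold) drives the endocrine subtype
   partition (Insulin+ / Glucagon+ / SST28+ / negative) and co-occurrence
   statistics with Wilson confidence intervals.

Because real whole-slide data is not practical for testing, the package
ships a first-class **synthetic tissue-phantom generator** with complete
ground truth — label maps, per-cell drawn intensities, planted cluster
structure, planted islet-level correlations and planted misalignments — so
every stage can be scored against a known answer.

## Worked example

```python
import numpy as np
import mplexquant as mq
from mplexquant.registration import normalize_decomposition
from mplexquant.synthetic import ClusterProfile

cfg = mq.TissuePhantomConfig(
    image_size_px=(1250, 1250), n_cells=900, seed=7,
    islet_specs=[], islet_profiles=[], islet_base_intensity={},
    cluster_profiles=[ClusterProfile("uniform", 1.0, {"M": 3.0}, {"M": 0.5})],
    noise_sd=0.5,
)
true = mq.RigidTransform(theta_rad=np.deg2rad(3.0), ty_px=12.0, tx_px=-7.0)
fixed, moving, truth = mq.generate_round_pair(cfg, true, deform_amplitude_px=4.0)

est = mq.estimate_rigid(fixed.nuclei, moving.nuclei)
aligned = mq.apply_transform(moving, rigid=est)
grid = mq.estimate_deformation(fixed.nuclei, aligned.nuclei, step_px=500)
est, grid = normalize_decomposition(est, grid)
```

Running this (`python examples/02_registration.py`) prints:

```
true rigid: theta=3.00 deg, t=(12.0, -7.0) px
estimated : theta=2.90 deg, t=(11.88, -6.90) px
deformation node error, interior: 0.70 px (sub-pixel recovery of the planted smooth warp)
```

i.e. a planted 3° rotation with a (12, −7) px offset plus a smooth ±4 px
deformation field is recovered to about a tenth of a degree, ~0.1 px of
translation and sub-pixel accuracy at the interior grid nodes.

The other example scripts cover the remaining capabilities —
`01_simulate_phantom.py` (ground-truth phantom), `03_segment_and_features.py`
(tessellation + background-corrected features),
`04_islet_statistics.py` (islet segmentation, planted correlation r = 0.40
recovered as 0.428 at n = 10⁴ islets, occurrence-vs-size trends), and
`05_expression_landscape.py` (z-score → PCA → K-means; six planted
exclusive-marker clusters plus a diffuse mass recovered with ARI 0.97).

A thin CLI mirrors the stages
(`mplexquant simulate|register|segment|features|islets|landscape|all`);
the Python API is the primary surface.

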