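"""Recover a planted misalignment between two imaging rounds.

A moving round is generated from the fixed round with a known rigid offset
plus a smooth deformation field on a 500 px grid; the two-stage
registration (global rigid, then grid deformable on the nuclei channel)
must recover both.
"""

import numpy as np

import mplexquant as mq
from mplexquant.registration import normalize_decomposition
from mplexquant.synthetic import ClusterProfile

cfg = mq.TissuePhantomConfig(
    image_size_px=(1250, 1250),
    n_cells=900,
    seed=7,
    islet_specs=[],
    islet_profiles=[],
    islet_base_intensity={},
    cluster_profiles=[ClusterProfile("uniform", 1.0, {"M": 3.0}, {"M": 0.5})],
    noise_sd=0.5,
)
true = mq.RigidTransform(theta_rad=np.deg2rad(3.0), ty_px=12.0, tx_px=-7.0)
fixed, moving, truth = mq.generate_round_pair(cfg, true, deform_amplitude_px=4.0)

est = mq.estimate_rigid(fixed.nuclei, moving.nuclei)
aligned = mq.apply_transform(moving, rigid=est)
grid = mq.estimate_deformation(fixed.nuclei, aligned.nuclei, step_px=500)
est, grid = normalize_decomposition(est, grid)

print(f"true rigid: theta={np.rad2deg(true.theta_rad):.2f} deg, "
      f"t=({true.ty_px:.1f}, {true.tx_px:.1f}) px")
print(f"estimated : theta={np.rad2deg(est.theta_rad):.2f} deg, "
      f"t=({est.ty_px:.2f}, {est.tx_px:.2f}) px")
node_err = np.abs(grid.displacements - truth.deformation.displacements)
print(f"deformation node error, interior: {node_err[1:-1, 1:-1].max():.2f} px "
      "(sub-pixel recovery of the planted smooth warp)")
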