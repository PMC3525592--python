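"""Straight-bundle phantom -> tensor fit -> tractography -> connectome.

Builds a noiseless two-label bundle phantom, reconstructs the diffusion
tensor and its scalar maps, tracks streamlines along the ODF maxima and
assembles the weighted connectivity matrices.
"""

import numpy as np

from tractkit import connectome as cxn
from tractkit import recon, tracking
from tractkit.phantom import default_scheme, make_phantom, straight_bundle_spec

scheme = default_scheme(30)          # 1 b0 + 30 directions at b = 1000 s/mm^2
spec = straight_bundle_spec()        # 20^3 voxels at 2 mm, caps labelled 1 / 2
dwi, wm_mask, labels, truth = make_phantom(spec, scheme)

tensors = recon.fit_tensor(dwi, scheme, wm_mask)
maps = recon.tensor_scalars(tensors)
bundle_fa = maps["FA"].data[wm_mask.data.astype(bool)]
print(f"bundle voxels: {int(wm_mask.data.sum())}, FA inside bundle: {bundle_fa.mean():.4f}")

directions = recon.extract_maxima(recon.tensor_to_odf(tensors))
params = tracking.default_params(wm_mask, seeds_per_voxel=4)
tract = tracking.track_whole_brain(directions, wm_mask, params)
tract = tracking.filter_by_length(tract, params.min_length, params.max_length)
print(f"retained streamlines: {len(tract)}, mean length {tract.lengths().mean():.1f} mm")

assignment = cxn.assign_endpoints(tract, labels, wm_mask)
surfaces = cxn.node_surfaces(labels, wm_mask)
c = cxn.build_connectome(assignment, tract, {"FA": maps["FA"]}, surfaces=surfaces)
print("fibre count matrix:\n", c.matrix("fibre_count"))
print("mean FA along the bundle:", np.round(c.matrix("mean_FA")[0, 1], 4))
print("connection density:", np.round(c.matrix("density")[0, 1], 4))
# Expected: every retained streamline links cap 1 to cap 2 (one off-diagonal
# cell), the FA edge weight equals the single-tensor FA of the bundle, and
# density = 2/(S_1+S_2) * sum of inverse streamline lengths.
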