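"""Tracking through a 90-degree fibre crossing.

Crossing voxels carry two ODF lobes; maxima extraction returns both, and
the |dot|-based direction selection keeps each streamline on its own bundle
instead of turning onto the other one.
"""

import collections

import numpy as np

from tractkit import connectome as cxn
from tractkit import recon, tracking
from tractkit.phantom import crossing_spec, default_scheme, make_odf_field, make_phantom

spec = crossing_spec()  # bundle A along x (labels 1-2), bundle B along y (3-4)
scheme = default_scheme(30)
dwi, wm_mask, labels, truth = make_phantom(spec, scheme)

odf = make_odf_field(spec)  # ground-truth multi-compartment ODFs
directions = recon.extract_maxima(odf)

both = sorted(set(map(tuple, truth.bundle_voxels[0])) & set(map(tuple, truth.bundle_voxels[1])))
v = both[len(both) // 2]
d = directions.voxel_directions(v)
angle = np.degrees(np.arccos(np.clip(abs(d[0] @ d[1]), 0, 1)))
print(f"crossing voxels: {len(both)}; maxima in one of them: {len(d)}, {angle:.1f} deg apart")

params = tracking.default_params(wm_mask, seeds_per_voxel=2)
tract = tracking.track_whole_brain(directions, wm_mask, params)
tract = tracking.filter_by_length(tract, params.min_length, params.max_length)
assignment = cxn.assign_endpoints(tract, labels, wm_mask)
pairs = collections.Counter(tuple(sorted(p)) for p in assignment.pairs[assignment.assigned])
print("end-cap pairs:", dict(pairs))
# Expected: only (1, 2) and (3, 4) — no streamline hops between the bundles.
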