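"""Shared fixtures: small deterministic phantoms and schemes.

Everything is generated in memory at session scope; no data files.
"""

import numpy as np
import pytest

from tractkit import recon
from tractkit.phantom import (
    crossing_spec,
    curved_bundle_spec,
    default_scheme,
    make_phantom,
    straight_bundle_spec,
)


@pytest.fixture(scope="session")
def scheme30():
    return default_scheme(30)


@pytest.fixture(scope="session")
def scheme12():
    return default_scheme(12)


@pytest.fixture(scope="session")
def straight_phantom(scheme30):
    """Noiseless straight x-bundle, 20^3 at 2 mm, end caps labelled 1/2."""
    spec = straight_bundle_spec()
    dwi, wm, labels, truth = make_phantom(spec, scheme30)
    return {"spec": spec, "dwi": dwi, "wm": wm, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def straight_directions(straight_phantom, scheme30):
    tf = recon.fit_tensor(
        straight_phantom["dwi"], scheme30, straight_phantom["wm"]
    )
    odf = recon.tensor_to_odf(tf)
    return recon.extract_maxima(odf)


@pytest.fixture(scope="session")
def crossing_phantom(scheme30):
    """Two orthogonal bundles crossing at the grid centre (labels 1/2, 3/4)."""
    spec = crossing_spec()
    dwi, wm, labels, truth = make_phantom(spec, scheme30)
    return {"spec": spec, "dwi": dwi, "wm": wm, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def curved_phantom(scheme30):
    """Quarter-circle bundle, 20 mm radius of curvature."""
    spec = curved_bundle_spec()
    dwi, wm, labels, truth = make_phantom(spec, scheme30)
    return {"spec": spec, "dwi": dwi, "wm": wm, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def small_sphere():
    from tractkit.sphere import make_sphere

    return make_sphere(freq=2)  # 42 samples


def crossing_voxels(truth):
    a = set(map(tuple, truth.bundle_voxels[0]))
    b = set(map(tuple, truth.bundle_voxels[1]))
    return sorted(a & b)
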