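"""Synthetic diffusion phantoms with known ground truth.

Every downstream stage (reconstruction, tracking, connectome building) is
validated against phantoms whose fibre geometry is known by construction:
tubular bundles around polyline centrelines, each voxel carrying an axially
symmetric diffusion tensor aligned with the local tangent.  Crossing voxels
mix the compartments with equal weight; the background is isotropic.  The
signal model is the standard single/multi-tensor attenuation
``S = S0 * sum_c w_c exp(-b g^T D_c g)``, optionally corrupted by Rician
noise (magnitude of a complex Gaussian perturbation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .gradients import GradientScheme


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification."""


@dataclass
class Bundle:
    """A tubular fibre bundle around a 3D polyline centreline (world mm)."""

    centreline: np.ndarray  # (P, 3) world mm
    radius: float  # mm
    lambda_par: float = 1.7e-3  # mm^2/s, along the tangent
    lambda_perp: float = 0.3e-3  # mm^2/s, across
    end_labels: tuple = (1, 2)  # label ids of the two endpoint caps

    def __post_init__(self) -> None:
        self.centreline = np.asarray(self.centreline, dtype=float).reshape(-1, 3)
        if len(self.centreline) < 2:
            raise PhantomSpecError("centreline needs at least 2 points")
        if self.radius <= 0:
            raise PhantomSpecError("radius must be positive")
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise PhantomSpecError("need lambda_par >= lambda_perp > 0")


@dataclass
class PhantomSpec:
    """Grid geometry, bundle list and acquisition-noise settings."""

    shape: tuple = (20, 20, 20)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    bundles: list = field(default_factory=list)
    background_diffusivity: float = 0.7e-3  # mm^2/s, isotropic
    s0: float = 1000.0
    noise_sigma: float = 0.0  # Rician sigma, signal units
    cap_length: float | None = None  # mm of centreline forming each label cap
    rng_seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth: per-bundle voxel sets and endpoint label pairs."""

    bundle_voxels: list  # list of (N, 3) int arrays
    end_labels: list  # list of (label_a, label_b)
    centrelines: list  # list of (P, 3) world-mm arrays


def _segment_geometry(point: np.ndarray, line: np.ndarray):
    """Distance from ``point`` to the polyline, the local tangent, and the
    arc-length position of the closest point."""
    seg = line[1:] - line[:-1]
    seg_len = np.linalg.norm(seg, axis=1)
    seg_dir = seg / seg_len[:, None]
    rel = point - line[:-1]
    t = np.clip(np.einsum("ij,ij->i", rel, seg_dir), 0.0, seg_len)
    closest = line[:-1] + t[:, None] * seg_dir
    d = np.linalg.norm(point - closest, axis=1)
    i = int(np.argmin(d))
    arc = float(np.concatenate([[0.0], np.cumsum(seg_len)])[i] + t[i])
    return float(d[i]), seg_dir[i], arc


def _axial_tensor(tangent: np.ndarray, l_par: float, l_perp: float) -> np.ndarray:
    t = tangent / np.linalg.norm(tangent)
    return l_perp * np.eye(3) + (l_par - l_perp) * np.outer(t, t)


def make_phantom(spec: PhantomSpec, scheme: GradientScheme):
    """Simulate a DWI phantom.

    Returns ``(dwi, wm_mask, label_volume, truth)``.  A voxel belongs to a
    bundle iff its centre lies within the bundle radius of the centreline
    (no partial volume, keeping ground truth exact).  Endpoint caps are the
    bundle voxels whose closest centreline point lies within ``cap_length``
    of either end; caps of different labels must not overlap.
    Identical ``rng_seed`` reproduces the volumes bit-exactly.
    """
    shape = tuple(spec.shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    affine = np.diag(list(vs) + [1.0])
    nvol = scheme.n_volumes
    bvals = scheme.bvals
    bvecs = scheme.bvecs

    centres = np.indices(shape).reshape(3, -1).T * vs  # world mm, diagonal affine
    n_vox = len(centres)

    # per-voxel compartment lists: (tensor, bundle index)
    iso = spec.background_diffusivity * np.eye(3)
    signal = np.empty((n_vox, nvol))
    wm = np.zeros(n_vox, dtype=bool)
    labels = np.zeros(n_vox, dtype=np.int32)
    bundle_voxels = [[] for _ in spec.bundles]
    cap_len = spec.cap_length if spec.cap_length is not None else 1.5 * float(vs.max())

    # precompute attenuation for the isotropic background (same everywhere)
    att_iso = np.exp(-bvals * spec.background_diffusivity)

    arc_totals = []
    for b in spec.bundles:
        seg = b.centreline[1:] - b.centreline[:-1]
        arc_totals.append(float(np.linalg.norm(seg, axis=1).sum()))

    for v in range(n_vox):
        p = centres[v]
        comps = []
        for bi, b in enumerate(spec.bundles):
            d, tangent, arc = _segment_geometry(p, b.centreline)
            if d <= b.radius:
                comps.append((bi, tangent, arc))
        if not comps:
            signal[v] = spec.s0 * att_iso
            continue
        wm[v] = True
        att = np.zeros(nvol)
        for bi, tangent, arc in comps:
            b = spec.bundles[bi]
            D = _axial_tensor(tangent, b.lambda_par, b.lambda_perp)
            att += np.exp(-bvals * np.einsum("ij,jk,ik->i", bvecs, D, bvecs))
            bundle_voxels[bi].append(v)
            if arc <= cap_len:
                lab = b.end_labels[0]
            elif arc >= arc_totals[bi] - cap_len:
                lab = b.end_labels[1]
            else:
                lab = 0
            if lab:
                if labels[v] and labels[v] != lab:
                    raise PhantomSpecError(
                        f"endpoint label regions overlap at voxel {np.unravel_index(v, shape)}"
                    )
                labels[v] = lab
        signal[v] = spec.s0 * att / len(comps)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        re = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
        im = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt(re**2 + im**2)

    dwi = VolumeGrid(signal.reshape(shape + (nvol,)), affine, {"phantom": True})
    wm_mask = VolumeGrid(wm.reshape(shape).astype(np.uint8), affine)
    label_vol = VolumeGrid(labels.reshape(shape), affine)
    truth = PhantomTruth(
        bundle_voxels=[
            np.array(np.unravel_index(np.asarray(v, dtype=int), shape)).T
            for v in bundle_voxels
        ],
        end_labels=[b.end_labels for b in spec.bundles],
        centrelines=[b.centreline for b in spec.bundles],
    )
    return dwi, wm_mask, label_vol, truth


def make_odf_field(spec: PhantomSpec, sphere=None):
    """The phantom's true ODF field, one Gaussian diffusion ODF per compartment.

    Per compartment the orientation profile is the Gaussian diffusion ODF
    ``psi_c(u) = (u^T D_c^{-1} u)^{-3/2}``, which peaks sharply along the
    fibre tangent; compartments add with equal weight and the voxel profile
    is max-normalised.  A 90-degree crossing voxel therefore genuinely
    carries two distinct lobes — unlike the single-tensor bridge
    :func:`tractkit.recon.tensor_to_odf`, whose quadratic form cannot
    resolve crossings.
    """
    from .recon import OdfField
    from .sphere import make_sphere

    sphere = sphere or make_sphere()
    shape = tuple(spec.shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    affine = np.diag(list(vs) + [1.0])
    u = sphere.vertices
    psi = np.zeros(shape + (sphere.n,))
    valid = np.zeros(shape, dtype=bool)
    for ijk in np.ndindex(shape):
        p = np.asarray(ijk) * vs
        acc = None
        n_comp = 0
        for b in spec.bundles:
            d, tangent, _ = _segment_geometry(p, b.centreline)
            if d <= b.radius:
                D = _axial_tensor(tangent, b.lambda_par, b.lambda_perp)
                quad = np.einsum("ni,ij,nj->n", u, np.linalg.inv(D), u)
                lobe = quad ** -1.5
                acc = lobe if acc is None else acc + lobe
                n_comp += 1
        if acc is None:
            continue
        valid[ijk] = True
        psi[ijk] = acc / acc.max()
    grid = VolumeGrid(np.zeros(shape), affine)
    return OdfField(sphere, psi, valid, grid)


def straight_bundle_spec(
    shape=(20, 20, 20),
    voxel_size=(2.0, 2.0, 2.0),
    radius_mm: float = 4.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhantomSpec:
    """A single straight bundle along x through the grid centre."""
    vs = np.asarray(voxel_size, float)
    extent = np.asarray(shape) * vs
    yc, zc = extent[1] / 2, extent[2] / 2
    line = np.array([[0.0, yc, zc], [extent[0] - vs[0], yc, zc]])
    return PhantomSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        bundles=[Bundle(line, radius_mm, end_labels=(1, 2))],
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def crossing_spec(
    shape=(20, 20, 20),
    voxel_size=(2.0, 2.0, 2.0),
    radius_mm: float = 4.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Two straight bundles crossing at 90 degrees in the grid centre plane."""
    vs = np.asarray(voxel_size, float)
    extent = np.asarray(shape) * vs
    yc, zc = extent[1] / 2, extent[2] / 2
    xc = extent[0] / 2
    a = np.array([[0.0, yc, zc], [extent[0] - vs[0], yc, zc]])
    b = np.array([[xc, 0.0, zc], [xc, extent[1] - vs[1], zc]])
    return PhantomSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        bundles=[
            Bundle(a, radius_mm, end_labels=(1, 2)),
            Bundle(b, radius_mm, end_labels=(3, 4)),
        ],
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def curved_bundle_spec(
    radius_of_curvature_mm: float = 20.0,
    tube_radius_mm: float = 4.0,
    voxel_size=(2.0, 2.0, 2.0),
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhantomSpec:
    """A quarter-circle bundle (curvature stress test for tracking)."""
    vs = np.asarray(voxel_size, float)
    R = radius_of_curvature_mm
    margin = tube_radius_mm + 2 * float(vs.max())
    theta = np.linspace(0.0, np.pi / 2, 46)
    centre = np.array([margin, margin, 0.0])
    zc = margin
    line = np.column_stack([
        centre[0] + R * np.cos(theta),
        centre[1] + R * np.sin(theta),
        np.full_like(theta, zc),
    ])
    extent = np.array([margin + R + margin, margin + R + margin, 2 * margin])
    shape = tuple(np.ceil(extent / vs).astype(int))
    return PhantomSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        bundles=[Bundle(line, tube_radius_mm, end_labels=(1, 2))],
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def default_scheme(n_directions: int = 30, b: float = 1000.0, n_b0: int = 1) -> GradientScheme:
    """A deterministic single-shell scheme: Fibonacci-sphere directions."""
    i = np.arange(n_directions)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(1.0 - z**2)
    phi = golden * i
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals, bvecs)
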