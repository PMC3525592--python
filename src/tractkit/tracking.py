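"""Deterministic streamline tractography on a discrete direction field.

Streamlines are grown from random seed points in both directions along the
local ODF maxima with a fixed step, constrained to a white-matter mask.
Propagation halts on mask exit, on violation of the curvature constraint
(angle between consecutive steps above threshold), or when no direction is
available.  The direction at each point is the nearest voxel's maximum with
the largest absolute dot product to the incoming direction — no
interpolation of directions, which keeps the algorithm exactly reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .grid import VolumeGrid
from .recon import DirectionField


class SeedError(ValueError):
    """Seed point outside the tracking mask."""


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (lengths in mm, angles in degrees)."""

    step_size: float = 1.0
    angle_threshold: float = 60.0
    seeds_per_voxel: int = 32  # per ODF maximum
    min_length: float = 10.0
    max_length: float = 300.0
    max_steps: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not (0 < self.angle_threshold < 90):
            raise ValueError("angle_threshold must be in (0, 90) degrees")
        if not (self.min_length < self.max_length):
            raise ValueError("min_length must be below max_length")


def default_params(field_grid: VolumeGrid, **overrides) -> TrackingParams:
    """Defaults tied to the grid: step = 0.5 x smallest voxel edge."""
    p = TrackingParams(step_size=0.5 * float(field_grid.voxel_size.min()))
    return replace(p, **overrides) if overrides else p


@dataclass
class Streamline:
    """An ordered polyline in world mm with seed provenance."""

    points: np.ndarray  # (P, 3)
    seed_voxel: tuple = (0, 0, 0)
    seed_direction: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def length(self) -> float:
        """Arc length l(f) = sum of segment lengths, mm."""
        if self.n_points < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Tractogram:
    streamlines: list = field(default_factory=list)
    grid: VolumeGrid | None = None  # reference grid (for TRK headers)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([s.length() for s in self.streamlines])


def _mask_lookup(mask: VolumeGrid):
    m = mask.data.astype(bool)
    if m.ndim == 4:
        m = m[..., 0]
    inv = np.linalg.inv(mask.affine)
    shape = np.asarray(m.shape)

    def inside(p: np.ndarray):
        ijk = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            return False, None
        return bool(m[tuple(ijk)]), tuple(ijk)

    return inside


def seed_points(
    wm_mask: VolumeGrid,
    dirs: DirectionField,
    params: TrackingParams,
) -> list:
    """Random seed points per mask voxel, one batch per ODF maximum.

    Returns ``[(point_mm, initial_direction, voxel, dir_index), ...]``;
    ``seeds_per_voxel`` points are drawn uniformly inside each voxel cube
    for each of its maxima.  Deterministic for a fixed ``rng_seed``; voxels
    without maxima contribute no seeds.
    """
    m = wm_mask.data.astype(bool)
    if m.ndim == 4:
        m = m[..., 0]
    if not m.any():
        raise ValueError("empty white-matter mask")
    rng = np.random.default_rng(params.rng_seed)
    seeds = []
    for ijk in np.argwhere(m):
        vdirs = dirs.voxel_directions(ijk)
        if len(vdirs) == 0:
            continue
        # voxel cube spans index +/- 0.5 around the centre
        offs = rng.uniform(-0.5, 0.5, size=(len(vdirs) * params.seeds_per_voxel, 3))
        pts = wm_mask.voxel_to_world(ijk + offs)
        pts = np.atleast_2d(pts)
        for di in range(len(vdirs)):
            for k in range(params.seeds_per_voxel):
                seeds.append(
                    (pts[di * params.seeds_per_voxel + k], vdirs[di], tuple(ijk), di)
                )
    return seeds


def _half_track(
    point: np.ndarray,
    direction: np.ndarray,
    dirs: DirectionField,
    inside,
    params: TrackingParams,
) -> list:
    """Points reached from ``point`` marching along ``direction``."""
    cos_thresh = np.cos(np.radians(params.angle_threshold))
    pts = []
    p = point.copy()
    d = direction / np.linalg.norm(direction)
    for _ in range(params.max_steps):
        p_next = p + params.step_size * d
        ok, ijk = inside(p_next)
        if not ok:
            break
        vdirs = dirs.voxel_directions(ijk)
        pts.append(p_next)
        if len(vdirs) == 0:
            break
        dots = vdirs @ d
        best = int(np.argmax(np.abs(dots)))
        d_new = vdirs[best] if dots[best] >= 0 else -vdirs[best]
        if d_new @ d < cos_thresh:  # curvature constraint
            break
        p = p_next
        d = d_new
    return pts


def propagate(
    dirs: DirectionField,
    wm_mask: VolumeGrid,
    seed,
    params: TrackingParams,
) -> Streamline:
    """Grow one streamline from a seed in both directions.

    ``seed`` is ``(point_mm, initial_direction, voxel, dir_index)``.  The
    two half-tracks share the seed point; the backward half is reversed and
    concatenated so consecutive points are ``step_size`` apart throughout.
    """
    point, direction, voxel, di = seed
    inside = _mask_lookup(wm_mask)
    ok, _ = inside(point)
    if not ok:
        raise SeedError(f"seed {point} outside mask")
    fwd = _half_track(np.asarray(point, float), np.asarray(direction, float), dirs, inside, params)
    bwd = _half_track(np.asarray(point, float), -np.asarray(direction, float), dirs, inside, params)
    pts = bwd[::-1] + [np.asarray(point, float)] + fwd
    return Streamline(np.asarray(pts), voxel, di)


def track_whole_brain(
    dirs: DirectionField,
    wm_mask: VolumeGrid,
    params: TrackingParams,
) -> Tractogram:
    """Propagate every seed; discard streamlines with fewer than 3 points."""
    out = []
    for seed in seed_points(wm_mask, dirs, params):
        try:
            sl = propagate(dirs, wm_mask, seed, params)
        except SeedError:
            continue
        if sl.n_points >= 3:
            out.append(sl)
    return Tractogram(out, wm_mask)


def filter_by_length(t: Tractogram, min_length: float, max_length: float) -> Tractogram:
    """Keep streamlines with min <= l(f) <= max, preserving order."""
    if not min_length < max_length:
        raise ValueError("min_length must be below max_length")
    kept = [s for s in t.streamlines if min_length <= s.length() <= max_length]
    return Tractogram(kept, t.grid)


def _smooth_one(points: np.ndarray, spacing: float, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < 2 * spacing or len(points) < 8:
        return points
    n_int = max(0, int(total / spacing) - 1)
    interior = np.linspace(0, total, n_int + 2)[1:-1]
    knots = np.concatenate([[0.0] * 4, interior, [total] * 4])
    # Schoenberg-Whitney needs enough sites per span; fall back if violated
    try:
        spl = make_lsq_spline(arc, points, knots, k=3)
    except Exception:
        return points
    u = np.arange(0.0, total + step / 2, step)
    u[-1] = min(u[-1], total)
    return np.asarray(BSpline(spl.t, spl.c, 3)(u))


def smooth_spline(t: Tractogram, control_point_spacing: float, step_size: float | None = None) -> Tractogram:
    """Replace each streamline by a least-squares cubic B-spline fit.

    Control points sit every ``control_point_spacing`` mm of arc length;
    the fit is resampled at ``step_size`` (defaults to the input point
    spacing).  Straight lines lie in the spline space and pass through
    unchanged; streamlines shorter than two control spacings are passed
    through untouched.
    """
    out = []
    for s in t.streamlines:
        step = step_size
        if step is None:
            step = float(np.linalg.norm(s.points[1] - s.points[0])) if s.n_points > 1 else control_point_spacing
        if control_point_spacing < step:
            raise ValueError("control_point_spacing must be >= step size")
        pts = _smooth_one(s.points, control_point_spacing, step)
        out.append(Streamline(pts, s.seed_voxel, s.seed_direction))
    return Tractogram(out, t.grid)


def write_trk(t: Tractogram, path: str | os.PathLike, grid: VolumeGrid | None = None) -> None:
    """Write a tractogram as TrackVis TRK (points in world/RAS mm)."""
    grid = grid or t.grid
    if grid is None:
        raise ValueError("a reference grid is required for the TRK header")
    tg = nib.streamlines.Tractogram(
        [s.points for s in t.streamlines], affine_to_rasmm=np.eye(4)
    )
    hdr = {
        "voxel_sizes": tuple(grid.voxel_size),
        "dimensions": tuple(int(n) for n in grid.shape3),
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.trk.TrkFile(tg, hdr), str(path))


def read_trk(path: str | os.PathLike) -> Tractogram:
    """Read a TrackVis TRK file back into a :class:`Tractogram`."""
    trk = nib.streamlines.load(str(path))
    aff = np.asarray(trk.header["voxel_to_rasmm"], dtype=float)
    shape = tuple(int(n) for n in trk.header["dimensions"])
    grid = VolumeGrid(np.zeros(shape, dtype=np.uint8), aff)
    return Tractogram([Streamline(np.asarray(s)) for s in trk.streamlines], grid)
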