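"""Structural connectome construction from a tractogram and a parcellation.

Each streamline whose two endpoints land in (or rescue to) distinct grey
matter labels contributes to cell (i, j) of the connectivity matrix; since
diffusion carries no directionality, every matrix is kept symmetric.
Edges carry several measures: raw fibre count, mean streamline length,
the mean along-tract value of any scalar map (FA, GFA, ...), and the
surface-normalised connection density
``density[i, j] = 2 / (S_i + S_j) * sum_{f in F_ij} 1 / l(f)``,
where S_i is the interface surface of node i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .parcellation import MultiScaleAtlas
from .tracking import Tractogram

DEFAULT_SEARCH_RADIUS_MM = 2.0


class GridMismatchError(ValueError):
    """Volumes expected on a shared grid differ."""


@dataclass
class Assignment:
    """Per-streamline endpoint labels; ``(0, 0)`` rows are unassigned."""

    pairs: np.ndarray  # (N, 2) int; label ids, 0 = unresolved
    assigned: np.ndarray  # (N,) bool

    @property
    def n_assigned(self) -> int:
        return int(self.assigned.sum())


@dataclass
class Connectome:
    """Symmetric node x node matrices for one parcellation scale."""

    scale: int
    labels: list  # node label ids, row/column order
    node_table: dict  # label -> {"name", "region", "surface"}
    matrices: dict = field(default_factory=dict)  # measure -> (n, n) array
    edge_fibres: dict = field(default_factory=dict)  # (i_label, j_label) -> fibre indices

    def index_of(self, label) -> int:
        return self.labels.index(label)

    def matrix(self, measure: str) -> np.ndarray:
        return self.matrices[measure]


def _same_grid(a: VolumeGrid, b: VolumeGrid) -> bool:
    return a.shape3 == b.shape3 and np.allclose(a.affine, b.affine, atol=1e-6)


def _endpoint_label(point, terminal_dir, labels: VolumeGrid, search_radius: float) -> int:
    """Label at an endpoint, rescuing along the terminal direction if needed.

    Marches outward in quarter-voxel steps up to ``search_radius``; the
    first distance with a nonzero label wins, ties broken by lowest id.
    """
    data = labels.data
    shape = np.asarray(data.shape)

    def label_at(p):
        ijk = np.rint(labels.world_to_voxel(p)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            return 0
        return int(data[tuple(ijk)])

    lab = label_at(point)
    if lab:
        return lab
    step = float(labels.voxel_size.min()) / 4.0
    d = terminal_dir / np.linalg.norm(terminal_dir)
    t = step
    while t <= search_radius + 1e-9:
        lab = label_at(point + t * d)
        if lab:
            return lab
        t += step
    return 0


def assign_endpoints(
    t: Tractogram,
    label_volume: VolumeGrid,
    wm_mask: VolumeGrid,
    search_radius: float = DEFAULT_SEARCH_RADIUS_MM,
    allow_self: bool = False,
) -> Assignment:
    """Assign each streamline's endpoints to parcel labels.

    An endpoint takes the label of its containing voxel; endpoints in
    unlabelled tissue are rescued by searching up to ``search_radius`` mm
    along the streamline's terminal direction.  Streamlines with an
    unresolved endpoint — or with both endpoints in the same label, unless
    ``allow_self`` — are left unassigned.
    """
    if not _same_grid(label_volume, wm_mask):
        raise GridMismatchError("label volume and mask are on different grids")
    n = len(t)
    pairs = np.zeros((n, 2), dtype=np.int64)
    assigned = np.zeros(n, dtype=bool)
    for i, sl in enumerate(t.streamlines):
        p = sl.points
        if len(p) < 2:
            continue
        la = _endpoint_label(p[0], p[0] - p[1], label_volume, search_radius)
        lb = _endpoint_label(p[-1], p[-1] - p[-2], label_volume, search_radius)
        pairs[i] = (la, lb)
        if la and lb and (allow_self or la != lb):
            assigned[i] = True
    return Assignment(pairs, assigned)


def node_surfaces(label_volume: VolumeGrid, wm_mask: VolumeGrid) -> dict:
    """Interface surface S_i per label: label voxels face-adjacent to the mask.

    Measured in voxel-face units (count of labelled voxels touching white
    matter across a face), the discrete analogue of the white-grey
    interface area.
    """
    if not _same_grid(label_volume, wm_mask):
        raise GridMismatchError("label volume and mask are on different grids")
    lab = label_volume.data
    m = wm_mask.data.astype(bool)
    if m.ndim == 4:
        m = m[..., 0]
    touch = np.zeros_like(m)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(m, shift, axis=axis)
            # don't wrap around
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = False
            touch |= rolled
    out: dict = {}
    sel = (lab > 0) & touch
    vals, counts = np.unique(lab[sel], return_counts=True)
    for v, c in zip(vals, counts):
        out[int(v)] = float(c)
    for v in np.unique(lab[lab > 0]):
        out.setdefault(int(v), 0.0)
    return out


def _streamline_mean(sl, scalar: VolumeGrid) -> float:
    ijk = np.rint(scalar.world_to_voxel(sl.points)).astype(int)
    shape = np.asarray(scalar.data.shape[:3])
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not ok.any():
        return np.nan
    vals = scalar.data[tuple(ijk[ok].T)]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def build_connectome(
    assignment: Assignment,
    t: Tractogram,
    scalar_maps: dict | None = None,
    node_table: dict | None = None,
    surfaces: dict | None = None,
    scale: int = 1,
) -> Connectome:
    """Aggregate assigned streamlines into symmetric connectivity matrices.

    Produces ``fibre_count``, ``mean_length``, one ``mean_<name>`` matrix
    per scalar map (nearest-voxel sampling along each streamline, then
    averaged over the bundle), and — when node ``surfaces`` are supplied —
    the surface-normalised ``density``.
    """
    scalar_maps = scalar_maps or {}
    labels = sorted(
        set(node_table) if node_table else set(assignment.pairs[assignment.assigned].ravel()) - {0}
    )
    nt = {
        lab: (node_table or {}).get(lab, {"name": f"label_{lab}", "region": None})
        for lab in labels
    }
    if surfaces:
        for lab in labels:
            nt[lab] = {**nt[lab], "surface": surfaces.get(lab, 0.0)}
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    count = np.zeros((n, n))
    edge_fibres: dict = {}
    for fi in np.flatnonzero(assignment.assigned):
        la, lb = assignment.pairs[fi]
        if la not in idx or lb not in idx:
            continue
        i, j = idx[la], idx[lb]
        count[i, j] += 1
        if i != j:
            count[j, i] += 1
        key = (min(la, lb), max(la, lb))
        edge_fibres.setdefault(key, []).append(int(fi))

    matrices = {"fibre_count": count}
    mean_len = np.zeros((n, n))
    per_map = {name: np.zeros((n, n)) for name in scalar_maps}
    for (la, lb), fibres in edge_fibres.items():
        i, j = idx[la], idx[lb]
        lens = [t.streamlines[f].length() for f in fibres]
        mean_len[i, j] = mean_len[j, i] = float(np.mean(lens))
        for name, vol in scalar_maps.items():
            vals = [_streamline_mean(t.streamlines[f], vol) for f in fibres]
            vals = [v for v in vals if np.isfinite(v)]
            m = float(np.mean(vals)) if vals else 0.0
            per_map[name][i, j] = per_map[name][j, i] = m
    matrices["mean_length"] = mean_len
    for name, mat in per_map.items():
        matrices[f"mean_{name}"] = mat
    if surfaces is not None:
        matrices["density"] = weight_density(assignment, t, surfaces, labels)
    return Connectome(scale, labels, nt, matrices, edge_fibres)


def weight_density(
    assignment: Assignment,
    t: Tractogram,
    surfaces: dict,
    labels: list | None = None,
) -> np.ndarray:
    """Connection density: ``2/(S_i+S_j) * sum over fibres of 1/l(f)``.

    Normalising by the joint interface surface and by fibre length
    compensates the seeding bias towards large regions and long tracts.
    Zero-length streamlines are excluded with a warning.
    """
    import warnings

    if labels is None:
        labels = sorted(set(assignment.pairs[assignment.assigned].ravel()) - {0})
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dens = np.zeros((n, n))
    for fi in np.flatnonzero(assignment.assigned):
        la, lb = assignment.pairs[fi]
        if la not in idx or lb not in idx:
            continue
        length = t.streamlines[fi].length()
        if length <= 0:
            warnings.warn(f"zero-length streamline {fi} excluded from density")
            continue
        i, j = idx[la], idx[lb]
        dens[i, j] += 1.0 / length
        if i != j:
            dens[j, i] += 1.0 / length
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            si, sj = surfaces.get(la, 0.0), surfaces.get(lb, 0.0)
            if dens[i, j] and si + sj > 0:
                dens[i, j] *= 2.0 / (si + sj)
    return dens


def relabel_assignment(assignment: Assignment, parent_map: dict, allow_self: bool = False) -> Assignment:
    """Map endpoint labels through a parent map (finer -> coarser scale)."""
    pairs = np.zeros_like(assignment.pairs)
    assigned = np.zeros_like(assignment.assigned)
    for i, (la, lb) in enumerate(assignment.pairs):
        pa = parent_map.get(int(la), 0)
        pb = parent_map.get(int(lb), 0)
        pairs[i] = (pa, pb)
        if pa and pb and (allow_self or pa != pb):
            assigned[i] = True
    return Assignment(pairs, assigned)


def multi_scale_connectomes(
    assignment: Assignment,
    atlas: MultiScaleAtlas,
    t: Tractogram,
    scalar_maps: dict | None = None,
    surfaces: dict | None = None,
    allow_self: bool = False,
) -> dict:
    """One connectome per atlas scale from a single finest-scale assignment.

    Endpoints are relabelled through the parent maps and re-aggregated
    fibre-wise at each scale (mean weights are recomputed from the
    contributing streamlines, never averaged from the finer matrix).
    Fibres that collapse onto the diagonal at a coarse scale (both
    endpoints under one parent) become self-connections and are excluded
    under the default policy.
    """
    finest = atlas.finest()
    out = {}
    current = assignment
    cur_surfaces = surfaces
    for s in range(finest, 0, -1):
        node_table = {
            lab: {"name": p.name, "region": p.region}
            for lab, p in atlas.scales[s].items()
        }
        out[s] = build_connectome(
            current, t, scalar_maps, node_table, cur_surfaces, scale=s
        )
        if s > 1:
            pm = atlas.parent_map(s)
            current = relabel_assignment(current, pm, allow_self)
            if cur_surfaces is not None:
                agg: dict = {}
                for lab, surf in cur_surfaces.items():
                    parent = pm.get(lab)
                    if parent is not None:
                        agg[parent] = agg.get(parent, 0.0) + surf
                cur_surfaces = agg
    return out
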