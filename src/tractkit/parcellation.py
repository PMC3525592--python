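"""Multi-scale parcellation of an area-weighted region graph.

The connectome's nodes come from a nested hierarchy of grey-matter parcels:
anatomical regions at the coarsest scale, subdivided into approximately
equal-area connected parcels at the finest (target ~1.5 cm^2), with
intermediate scales obtained by merging neighbouring sibling parcels.
Surface meshes and voxel lattices both reduce to the same abstraction — a
graph of atomic units with areas, adjacency and an anatomical region id —
so the partitioning operates purely on that graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .grid import VolumeGrid

DEFAULT_TARGET_AREA_CM2 = 1.5


class RegionGraphError(ValueError):
    """Invalid region graph (e.g. a disconnected anatomical region)."""


class InfeasibleDepthError(ValueError):
    """Requested more scales than the parcel counts can support."""


@dataclass
class RegionInfo:
    name: str
    hemisphere: str = ""  # "lh" | "rh" | ""
    region_class: str = "cortical"  # cortical | subcortical | brainstem


@dataclass
class RegionGraph:
    """Atomic units with area (cm^2) and anatomical region id, plus adjacency.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes carry
    ``area`` (cm^2), ``region`` (region id) and optionally ``voxel``
    (an (i, j, k) tuple for volumetric graphs).
    """

    graph: nx.Graph
    region_table: dict  # region id -> RegionInfo

    def units_of_region(self, region_id) -> list:
        return sorted(
            u for u, d in self.graph.nodes(data=True) if d["region"] == region_id
        )

    def area(self, units) -> float:
        return float(sum(self.graph.nodes[u]["area"] for u in units))

    def validate(self) -> None:
        for rid in self.region_table:
            units = self.units_of_region(rid)
            if not units:
                continue
            sub = self.graph.subgraph(units)
            if not nx.is_connected(sub):
                raise RegionGraphError(
                    f"anatomical region {rid!r} ({self.region_table[rid].name}) is disconnected"
                )


@dataclass
class Parcel:
    label: int
    name: str
    region: object  # anatomical region id
    parent: int | None  # label at the next coarser scale
    units: frozenset


@dataclass
class MultiScaleAtlas:
    """Nested labellings over ``n_scales`` scales (1 = coarsest = regions).

    Every label at scale s+1 has exactly one parent at scale s; sibling
    member sets are disjoint and union to the parent's set.
    """

    scales: dict  # scale -> {label: Parcel}
    region_graph: RegionGraph | None = None
    label_volumes: dict = field(default_factory=dict)  # scale -> VolumeGrid

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def finest(self) -> int:
        return max(self.scales)

    def parent_map(self, scale: int) -> dict:
        """label at ``scale`` -> parent label at ``scale - 1``."""
        return {lab: p.parent for lab, p in self.scales[scale].items()}

    def label_counts(self):
        return atlas_label_counts(self)

    def check_invariants(self) -> None:
        for s in range(2, self.n_scales + 1):
            parents = self.scales[s - 1]
            child_units: dict = {}
            for lab, p in self.scales[s].items():
                if p.parent not in parents:
                    raise ValueError(f"scale {s} label {lab}: missing parent {p.parent}")
                acc = child_units.setdefault(p.parent, set())
                if acc & p.units:
                    raise ValueError(f"scale {s}: sibling unit sets overlap under {p.parent}")
                acc |= p.units
            for lab, p in parents.items():
                if child_units.get(lab, set()) != set(p.units):
                    raise ValueError(f"scale {s - 1} label {lab}: children do not tile parent")
        if self.region_graph is not None:
            g = self.region_graph.graph
            for s, parcels in self.scales.items():
                for lab, p in parcels.items():
                    if len(p.units) > 1 and not nx.is_connected(g.subgraph(p.units)):
                        raise ValueError(f"scale {s} label {lab} is disconnected")


def _farthest_point_seeds(sub: nx.Graph, k: int, rng: np.random.Generator) -> list:
    """k seeds spread by BFS hop distance; first seed drawn from the rng."""
    nodes = sorted(sub.nodes)
    first = nodes[int(rng.integers(len(nodes)))]
    seeds = [first]
    dist = dict(nx.single_source_shortest_path_length(sub, first))
    while len(seeds) < k:
        far = max(nodes, key=lambda u: (dist.get(u, -1), -nodes.index(u)))
        if far in seeds:
            far = next(u for u in nodes if u not in seeds)
        seeds.append(far)
        for u, d in nx.single_source_shortest_path_length(sub, far).items():
            if d < dist.get(u, np.inf):
                dist[u] = d
    return seeds


def _grow_parcels(sub: nx.Graph, seeds: list) -> dict:
    """Area-balanced greedy accretion from the seeds; returns unit -> parcel idx."""
    assign = {s: i for i, s in enumerate(seeds)}
    areas = [sub.nodes[s]["area"] for s in seeds]
    unassigned = set(sub.nodes) - set(seeds)
    while unassigned:
        # grow the currently smallest parcel that still has a free neighbour
        order = sorted(range(len(seeds)), key=lambda i: (areas[i], i))
        grown = False
        for i in order:
            frontier = sorted(
                v
                for u, a in assign.items()
                if a == i
                for v in sub.neighbors(u)
                if v in unassigned
            )
            if frontier:
                v = frontier[0]
                assign[v] = i
                areas[i] += sub.nodes[v]["area"]
                unassigned.discard(v)
                grown = True
                break
        if not grown:  # isolated leftovers: attach to the smallest adjacent parcel
            v = sorted(unassigned)[0]
            nb = sorted(
                (assign[u] for u in sub.neighbors(v) if u in assign),
                key=lambda i: (areas[i], i),
            )
            assign[v] = nb[0] if nb else 0
            areas[assign[v]] += sub.nodes[v]["area"]
            unassigned.discard(v)
    return assign


def _refine_boundaries(sub: nx.Graph, assign: dict, n_parcels: int, passes: int = 8) -> dict:
    """Move boundary units between parcels to reduce area variance, keeping
    every parcel connected and non-empty.

    Besides strictly variance-reducing moves, variance-neutral moves from a
    larger into a smaller parcel are accepted: they let area migrate along
    chains of parcels (a 2-parcel local move cannot change the area multiset,
    so without them an oversized parcel separated from an undersized one by
    average parcels is stuck).  Pass count is bounded, so the sweep always
    terminates."""
    areas = [0.0] * n_parcels
    for u, a in assign.items():
        areas[a] += sub.nodes[u]["area"]
    for _ in range(passes):
        moved = False
        for u in sorted(sub.nodes):
            a = assign[u]
            members = [v for v, x in assign.items() if x == a]
            if len(members) <= 1:
                continue
            rest = [v for v in members if v != u]
            if not nx.is_connected(sub.subgraph(rest)):
                continue
            ua = sub.nodes[u]["area"]
            best, best_gain = None, np.inf
            for v in sorted(sub.neighbors(u)):
                b = assign[v]
                if b == a:
                    continue
                # variance change of moving u from a to b
                gain = (areas[a] - ua) ** 2 + (areas[b] + ua) ** 2
                gain -= areas[a] ** 2 + areas[b] ** 2
                improving = gain < -1e-12
                flat_downhill = abs(gain) <= 1e-12 and areas[a] > areas[b] + 1e-12
                if (improving or flat_downhill) and gain < best_gain - 1e-12:
                    best, best_gain = b, gain
            if best is not None:
                areas[a] -= ua
                areas[best] += ua
                assign[u] = best
                moved = True
        if not moved:
            break
    return assign


def subdivide_regions(
    g: RegionGraph,
    target_area: float = DEFAULT_TARGET_AREA_CM2,
    rng_seed: int = 0,
) -> dict:
    """Split each cortical region into ~equal-area connected parcels.

    Region R is split into ``k = max(1, round(area(R)/target_area))``
    parcels by a two-phase heuristic: seeded greedy region growing from k
    farthest-point seeds, then boundary-swap refinement minimising area
    variance subject to connectivity.  Subcortical and brainstem regions
    are never split.  Deterministic for a fixed ``rng_seed``.

    Returns ``unit -> global parcel label`` (labels 1..P, ordered by region).
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    g.validate()
    rng = np.random.default_rng(rng_seed)
    labelling: dict = {}
    next_label = 1
    for rid in sorted(g.region_table, key=str):
        info = g.region_table[rid]
        units = g.units_of_region(rid)
        if not units:
            continue
        sub = g.graph.subgraph(units)
        area = g.area(units)
        k = 1
        if info.region_class == "cortical":
            k = max(1, round(area / target_area))
            k = min(k, len(units))
        if k == 1:
            for u in units:
                labelling[u] = next_label
            next_label += 1
            continue
        # a few seeded restarts; local boundary swaps alone cannot shift
        # area between non-adjacent parcels, so the start matters
        best, best_var = None, np.inf
        for _ in range(4):
            seeds = _farthest_point_seeds(sub, k, rng)
            assign = _grow_parcels(sub, seeds)
            assign = _refine_boundaries(sub, assign, k)
            pa = np.zeros(k)
            for u, a in assign.items():
                pa[a] += sub.nodes[u]["area"]
            var = float(np.var(pa))
            if var < best_var - 1e-12:
                best, best_var = assign, var
        assign = best
        for i in range(k):
            members = [u for u, a in assign.items() if a == i]
            for u in members:
                labelling[u] = next_label + i
        next_label += k
    return labelling


def build_scale_hierarchy(
    finest_labelling: dict,
    g: RegionGraph,
    n_scales: int = 5,
) -> MultiScaleAtlas:
    """Build the nested atlas by successive merging of adjacent sibling parcels.

    Scale ``n_scales`` is the input labelling; each coarser scale merges
    adjacent parcels within the same anatomical region so counts shrink
    roughly geometrically until scale 1 equals the anatomical regions.
    """
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    # group finest parcels per region
    parcels_by_region: dict = {}
    units_by_parcel: dict = {}
    for u, lab in finest_labelling.items():
        units_by_parcel.setdefault(lab, set()).add(u)
    for lab, units in units_by_parcel.items():
        rid = g.graph.nodes[next(iter(units))]["region"]
        parcels_by_region.setdefault(rid, []).append(lab)
    max_k = max(len(v) for v in parcels_by_region.values())
    limit = max(2, int(np.ceil(np.log2(max_k))) + 1)
    if n_scales > limit:
        raise InfeasibleDepthError(
            f"n_scales={n_scales} infeasible: max within-region parcel count {max_k} "
            f"supports at most {limit} scales"
        )

    # per-region parcel-count schedule, geometric from k down to 1
    def schedule(k: int) -> list:
        counts = [
            max(1, int(round(k ** ((s - 1) / (n_scales - 1)))))
            for s in range(1, n_scales + 1)
        ]
        counts[0], counts[-1] = 1, k
        for i in range(1, n_scales):  # enforce monotone non-decreasing
            counts[i] = max(counts[i], counts[i - 1])
            counts[i] = min(counts[i], k)
        return counts

    scales: dict = {}
    # finest scale: adopt the input labelling
    finest_parcels = {}
    for rid in sorted(parcels_by_region, key=str):
        for lab in sorted(parcels_by_region[rid]):
            name = f"{g.region_table[rid].name}_{lab}"
            finest_parcels[lab] = Parcel(lab, name, rid, None, frozenset(units_by_parcel[lab]))
    scales[n_scales] = finest_parcels

    current = {rid: sorted(parcels_by_region[rid]) for rid in parcels_by_region}
    cur_units = {lab: set(units_by_parcel[lab]) for lab in units_by_parcel}

    for s in range(n_scales - 1, 0, -1):
        new_parcels: dict = {}
        next_label = 1
        new_current: dict = {}
        for rid in sorted(current, key=str):
            labs = current[rid]
            k = len(labs)
            target = schedule(len(parcels_by_region[rid]))[s - 1]
            groups = _merge_adjacent(g, labs, cur_units, target)
            region_new = []
            for gi, group in enumerate(groups):
                lab = next_label
                next_label += 1
                units = frozenset().union(*(cur_units[c] for c in group))
                name = g.region_table[rid].name
                if len(groups) > 1:
                    name = f"{name}_s{s}_{gi + 1}"
                new_parcels[lab] = Parcel(lab, name, rid, None, units)
                for c in group:
                    scales[s + 1][c].parent = lab
                region_new.append(lab)
            new_current[rid] = region_new
        scales[s] = new_parcels
        current = new_current
        cur_units = {lab: set(p.units) for lab, p in new_parcels.items()}

    atlas = MultiScaleAtlas(scales, g)
    return atlas


def _merge_adjacent(g: RegionGraph, labs: list, cur_units: dict, target: int) -> list:
    """Merge adjacent parcels (given as unit sets) down to ``target`` groups.

    Greedy: repeatedly merge the smallest-area group with its smallest
    adjacent sibling.  Returns a list of lists of original labels.
    """
    groups = {lab: [lab] for lab in labs}
    units = {lab: set(cur_units[lab]) for lab in labs}
    areas = {lab: g.area(units[lab]) for lab in labs}

    def adjacent(a: int, b: int) -> bool:
        ua, ub = units[a], units[b]
        return any(v in ub for u in ua for v in g.graph.neighbors(u))

    while len(groups) > target:
        order = sorted(groups, key=lambda l: (areas[l], l))
        merged = False
        for a in order:
            partners = sorted(
                (b for b in groups if b != a and adjacent(a, b)),
                key=lambda l: (areas[l], l),
            )
            if partners:
                b = partners[0]
                groups[a].extend(groups[b])
                units[a] |= units[b]
                areas[a] += areas[b]
                del groups[b], units[b], areas[b]
                merged = True
                break
        if not merged:  # no adjacency information links them; force-merge smallest two
            a, b = order[0], order[1]
            groups[a].extend(groups[b])
            units[a] |= units[b]
            areas[a] += areas[b]
            del groups[b], units[b], areas[b]
    return [sorted(groups[l]) for l in sorted(groups)]


def atlas_label_counts(atlas: MultiScaleAtlas) -> tuple:
    """Label counts per scale, finest first."""
    return tuple(len(atlas.scales[s]) for s in sorted(atlas.scales, reverse=True))


def rasterize_atlas(atlas: MultiScaleAtlas, grid: VolumeGrid) -> dict:
    """Rasterize each scale to an integer label volume on ``grid``.

    Units must carry a ``voxel`` attribute (volumetric region graph).
    Nesting holds voxel-wise by construction: a voxel's label at scale s is
    the parent of its label at scale s+1.
    """
    if atlas.region_graph is None:
        raise ValueError("atlas has no region graph to rasterize")
    g = atlas.region_graph.graph
    shape = grid.shape3
    out = {}
    for s, parcels in sorted(atlas.scales.items()):
        vol = np.zeros(shape, dtype=np.int32)
        for lab, p in parcels.items():
            for u in p.units:
                vox = g.nodes[u].get("voxel")
                if vox is None:
                    raise ValueError(f"unit {u!r} has no voxel coordinate")
                if any(c < 0 or c >= n for c, n in zip(vox, shape)):
                    raise IndexError(f"unit {u!r} voxel {vox} outside grid {shape}")
                vol[tuple(vox)] = lab
        out[s] = grid.like(vol)
    atlas.label_volumes = out
    return out


def region_graph_from_labels(labels: VolumeGrid, region_table: dict | None = None) -> RegionGraph:
    """Build a volumetric region graph from an integer label volume.

    Each nonzero voxel becomes a unit of area ``voxel face area`` with
    6-neighbour adjacency; the label is the anatomical region id.
    """
    data = labels.data
    vs = labels.voxel_size
    unit_area = float(vs[0] * vs[1]) / 100.0  # mm^2 -> cm^2
    g = nx.Graph()
    idx = {tuple(v): i for i, v in enumerate(np.argwhere(data > 0))}
    for vox, i in idx.items():
        g.add_node(i, area=unit_area, region=int(data[vox]), voxel=vox)
    for vox, i in idx.items():
        for ax in range(3):
            nb = list(vox)
            nb[ax] += 1
            j = idx.get(tuple(nb))
            if j is not None:
                g.add_edge(i, j)
    if region_table is None:
        region_table = {
            int(r): RegionInfo(f"region_{int(r)}") for r in np.unique(data) if r != 0
        }
    return RegionGraph(g, region_table)
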