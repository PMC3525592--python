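"""A packaged five-scale whole-brain hierarchy (synthetic stand-in).

The multi-scale connectome convention nests five parcellations of the
Desikan-Killiany anatomical regions, with label totals 1015, 463, 234, 129
and 83 from finest to coarsest (1000/448/219/114/68 cortical parcels plus
14 deep-grey nuclei and the brainstem, which are never subdivided).

The real per-region parcel tables depend on subject-specific FreeSurfer
surface geometry, which this package does not process.  The hierarchy built
here is therefore SYNTHETIC: region areas are plausible per-region cortical
surface areas, parcels are apportioned to those areas with exact per-scale
totals, and nesting is contiguous grouping.  It reproduces the label counts
and all structural invariants of the convention, not any subject's anatomy.
"""

from __future__ import annotations

import numpy as np

from .parcellation import MultiScaleAtlas, Parcel, RegionGraph, RegionInfo

# Desikan-Killiany cortical regions with approximate per-hemisphere surface
# area weights (arbitrary units ~ cm^2); drives the parcel apportionment.
_DK_CORTICAL = [
    ("bankssts", 10), ("caudalanteriorcingulate", 7), ("caudalmiddlefrontal", 23),
    ("cuneus", 15), ("entorhinal", 7), ("frontalpole", 3), ("fusiform", 35),
    ("inferiorparietal", 55), ("inferiortemporal", 35), ("insula", 25),
    ("isthmuscingulate", 8), ("lateraloccipital", 45), ("lateralorbitofrontal", 27),
    ("lingual", 25), ("medialorbitofrontal", 19), ("middletemporal", 35),
    ("paracentral", 17), ("parahippocampal", 8), ("parsopercularis", 17),
    ("parsorbitalis", 8), ("parstriangularis", 17), ("pericalcarine", 12),
    ("postcentral", 45), ("posteriorcingulate", 12), ("precentral", 55),
    ("precuneus", 40), ("rostralanteriorcingulate", 8), ("rostralmiddlefrontal", 60),
    ("superiorfrontal", 80), ("superiorparietal", 55), ("superiortemporal", 40),
    ("supramarginal", 40), ("temporalpole", 5), ("transversetemporal", 5),
]

_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum",
    "accumbens", "hippocampus", "amygdala",
]

# cortical parcel totals per scale, coarsest -> finest
_CORTICAL_TOTALS = (68, 114, 219, 448, 1000)


def _apportion(total: int, weights, caps=None) -> list:
    """Largest-remainder apportionment with a floor of 1 and optional caps."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    caps = np.full(n, np.inf) if caps is None else np.asarray(caps, dtype=float)
    quota = w / w.sum() * total
    cap_int = np.where(np.isinf(caps), total, caps).astype(int)
    alloc = np.clip(np.floor(quota).astype(int), 1, cap_int)
    rem = quota - alloc
    # add units by descending remainder (ties: lower index) where below cap
    order = sorted(range(n), key=lambda i: (-rem[i], i))
    while alloc.sum() < total:
        added = False
        for i in order:
            if alloc[i] < caps[i]:
                alloc[i] += 1
                added = True
                if alloc.sum() == total:
                    break
        if not added:
            raise ValueError("caps make the apportionment infeasible")
    # remove units by ascending remainder where above the floor
    order = sorted(range(n), key=lambda i: (rem[i], -i))
    while alloc.sum() > total:
        removed = False
        for i in order:
            if alloc[i] > 1:
                alloc[i] -= 1
                removed = True
                if alloc.sum() == total:
                    break
        if not removed:
            raise ValueError("floor makes the apportionment infeasible")
    return [int(a) for a in alloc]


def multiscale_hierarchy() -> MultiScaleAtlas:
    """Build the packaged five-scale hierarchy (synthetic, deterministic).

    Returns a :class:`MultiScaleAtlas` whose atomic units are the finest
    parcels themselves; label counts finest->coarsest are
    ``(1015, 463, 234, 129, 83)``.
    """
    regions = []  # (region id, RegionInfo, weight, splittable)
    for hemi in ("lh", "rh"):
        for name, wt in _DK_CORTICAL:
            regions.append((f"{hemi}.{name}", RegionInfo(name, hemi, "cortical"), wt, True))
    for hemi in ("lh", "rh"):
        for name in _SUBCORTICAL:
            regions.append((f"{hemi}.{name}", RegionInfo(name, hemi, "subcortical"), 1, False))
    regions.append(("brainstem", RegionInfo("brainstem", "", "brainstem"), 1, False))

    cortical_idx = [i for i, r in enumerate(regions) if r[3]]
    weights = [regions[i][2] for i in cortical_idx]

    # per-scale cortical parcel counts per region, nested via caps
    counts = {5: _apportion(_CORTICAL_TOTALS[4], weights)}
    for s, total in zip((4, 3, 2), (_CORTICAL_TOTALS[3], _CORTICAL_TOTALS[2], _CORTICAL_TOTALS[1])):
        counts[s] = _apportion(total, weights, caps=counts[s + 1])
    counts[1] = [1] * len(cortical_idx)

    def region_counts(s: int) -> list:
        per = {}
        for ci, i in enumerate(cortical_idx):
            per[i] = counts[s][ci]
        return [per.get(i, 1) for i in range(len(regions))]

    # finest scale: one atomic unit per finest parcel
    scales: dict = {s: {} for s in range(1, 6)}
    unit_of_region: dict = {}  # region index -> list of unit ids (finest parcels)
    next_unit = 0
    finest = region_counts(5)
    label = 1
    finest_labels_of_region: dict = {}
    for i, (rid, info, wt, splittable) in enumerate(regions):
        k = finest[i]
        labs = []
        units = []
        for p in range(k):
            name = info.name if k == 1 else f"{rid}_{p + 1}"
            scales[5][label] = Parcel(label, name, rid, None, frozenset([next_unit]))
            labs.append(label)
            units.append(next_unit)
            label += 1
            next_unit += 1
        finest_labels_of_region[i] = labs
        unit_of_region[i] = units

    # coarser scales: contiguous grouping of each region's child parcels
    child_labels = finest_labels_of_region
    for s in range(4, 0, -1):
        per_region = region_counts(s)
        label = 1
        new_child_labels: dict = {}
        for i, (rid, info, wt, splittable) in enumerate(regions):
            kids = child_labels[i]
            m = per_region[i]
            groups = np.array_split(np.arange(len(kids)), m)
            labs = []
            for gi, grp in enumerate(groups):
                members = [kids[j] for j in grp]
                units = frozenset().union(*(scales[s + 1][c].units for c in members))
                name = info.name if m == 1 else f"{rid}_s{s}_{gi + 1}"
                scales[s][label] = Parcel(label, name, rid, None, units)
                for c in members:
                    scales[s + 1][c].parent = label
                labs.append(label)
                label += 1
            new_child_labels[i] = labs
        child_labels = new_child_labels

    atlas = MultiScaleAtlas(scales, None)
    atlas.check_invariants()
    return atlas
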