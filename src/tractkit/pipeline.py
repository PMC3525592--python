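"""Configuration-driven batch pipeline: phantom -> recon -> track -> connectome.

A single TOML config describes one subject/timepoint run.  Outputs land in a
hierarchical layout ``<root>/<project>/<subject>/<timepoint>/<stage>/``; each
stage checks its declared inputs before running and its declared outputs
after, so a broken stage fails loudly instead of corrupting downstream
results.  Identical config + seeds reproduce byte-identical matrices.
"""

from __future__ import annotations

import json
import logging
import os
import tomllib
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import connectome as cxn
from . import export as exp
from . import phantom as ph
from . import recon, tracking
from .grid import read_volume, write_volume

log = logging.getLogger("tractkit")

STAGE_ORDER = ["phantom", "recon", "track", "connectome", "export"]


class PreflightError(RuntimeError):
    """A stage's declared input is missing before it runs (exit code 1)."""


class ContractViolation(RuntimeError):
    """A stage finished without producing a declared output (exit code 2)."""


@dataclass
class PipelineConfig:
    project: str = "project"
    subject: str = "subject"
    timepoint: str = "tp1"
    output_root: str = "."
    stages: list = dc_field(default_factory=lambda: list(STAGE_ORDER))
    params: dict = dc_field(default_factory=dict)  # per-stage parameter blocks
    rng_seed: int = 0

    @staticmethod
    def from_toml(path) -> "PipelineConfig":
        with open(str(path), "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        cfg = PipelineConfig(
            project=run.get("project", "project"),
            subject=run.get("subject", "subject"),
            timepoint=run.get("timepoint", "tp1"),
            output_root=run.get("output_root", os.path.dirname(os.path.abspath(str(path)))),
            stages=run.get("stages", list(STAGE_ORDER)),
            rng_seed=int(run.get("rng_seed", 0)),
        )
        cfg.params = {k: v for k, v in raw.items() if k != "run"}
        order = [s for s in STAGE_ORDER if s in cfg.stages]
        if order != cfg.stages:
            raise ValueError(f"stages must respect dependency order {STAGE_ORDER}")
        return cfg

    def base_dir(self) -> str:
        return os.path.join(self.output_root, self.project, self.subject, self.timepoint)

    def stage_dir(self, stage: str) -> str:
        return os.path.join(self.base_dir(), stage)


def _require(paths: dict, stage: str) -> None:
    for name, p in paths.items():
        if not os.path.exists(p):
            raise PreflightError(f"stage {stage!r}: missing input {name} ({p})")


def _check_outputs(paths: dict, stage: str) -> None:
    for name, p in paths.items():
        if not os.path.exists(p):
            raise ContractViolation(f"stage {stage!r}: declared output {name} missing ({p})")


def _phantom_inputs(cfg: PipelineConfig) -> dict:
    d = cfg.stage_dir("phantom")
    return {
        "dwi": os.path.join(d, "dwi.nii.gz"),
        "bval": os.path.join(d, "dwi.bval"),
        "bvec": os.path.join(d, "dwi.bvec"),
        "wm_mask": os.path.join(d, "wm_mask.nii.gz"),
        "labels": os.path.join(d, "labels.nii.gz"),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a manifest of produced files.

    The manifest maps stage -> {output name -> path}.  A ``parameters.json``
    record is written into every stage directory so any stage can be
    inspected and re-run in isolation.
    """
    manifest: dict = {}
    base = cfg.base_dir()
    os.makedirs(base, exist_ok=True)
    handler = logging.FileHandler(os.path.join(base, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in cfg.stages:
            os.makedirs(cfg.stage_dir(stage), exist_ok=True)
            params = cfg.params.get(stage, {})
            log.info("stage %s starting, params=%s", stage, params)
            with open(os.path.join(cfg.stage_dir(stage), "parameters.json"), "w") as fh:
                json.dump({"stage": stage, "params": params, "rng_seed": cfg.rng_seed}, fh, indent=1)
            outputs = _STAGES[stage](cfg, params)
            _check_outputs(outputs, stage)
            manifest[stage] = outputs
            log.info("stage %s done: %s", stage, sorted(outputs))
        manifest_path = os.path.join(base, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        manifest["manifest"] = {"manifest": manifest_path}
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _stage_phantom(cfg: PipelineConfig, params: dict) -> dict:
    out = _phantom_inputs(cfg)
    kind = params.get("kind", "straight")
    builders = {
        "straight": ph.straight_bundle_spec,
        "crossing": ph.crossing_spec,
        "curved": ph.curved_bundle_spec,
    }
    kwargs = {k: v for k, v in params.items() if k != "kind"}
    kwargs.setdefault("rng_seed", cfg.rng_seed)
    spec = builders[kind](**kwargs)
    scheme = ph.default_scheme(int(params.get("n_directions", 30)))
    dwi, wm, labels, truth = ph.make_phantom(spec, scheme)
    write_volume(dwi, out["dwi"])
    write_volume(wm, out["wm_mask"])
    write_volume(labels, out["labels"])
    from .gradients import write_gradient_scheme

    write_gradient_scheme(scheme, out["bval"], out["bvec"])
    truth_path = os.path.join(cfg.stage_dir("phantom"), "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "end_labels": [list(map(int, e)) for e in truth.end_labels],
                "bundle_voxel_counts": [len(v) for v in truth.bundle_voxels],
            },
            fh,
        )
    out["truth"] = truth_path
    return out


def _stage_recon(cfg: PipelineConfig, params: dict) -> dict:
    from .gradients import read_gradient_scheme

    inp = _phantom_inputs(cfg)
    _require(inp, "recon")
    d = cfg.stage_dir("recon")
    dwi = read_volume(inp["dwi"])
    scheme = read_gradient_scheme(inp["bval"], inp["bvec"])
    mask = read_volume(inp["wm_mask"])
    tf = recon.fit_tensor(dwi, scheme, mask)
    scalars = recon.tensor_scalars(tf)
    odf = recon.tensor_to_odf(tf)
    scalars.update(recon.odf_descriptors(odf))
    scalars["P0"] = recon.eap_p0(dwi, scheme, mask)
    dirs = recon.extract_maxima(
        odf,
        rel_threshold=float(params.get("rel_threshold", 0.1)),
        min_separation_deg=float(params.get("min_separation_deg", 25.0)),
        max_directions=int(params.get("max_directions", 3)),
    )
    out = {}
    for name, vol in scalars.items():
        p = os.path.join(d, f"{name}.nii.gz")
        write_volume(vol, p)
        out[name] = p
    # direction field: 4D NIfTI (3*M channels) + JSON sidecar describing layout
    M = dirs.max_directions
    flat = np.nan_to_num(dirs.directions, nan=0.0).reshape(dirs.directions.shape[:3] + (3 * M,))
    p = os.path.join(d, "directions.nii.gz")
    write_volume(dwi.like(flat), p)
    out["directions"] = p
    sidecar = os.path.join(d, "directions.json")
    with open(sidecar, "w") as fh:
        json.dump({"max_directions": M, "layout": "xyz per maximum, zero-padded"}, fh)
    out["directions_sidecar"] = sidecar
    return out


def _load_direction_field(cfg: PipelineConfig):
    d = cfg.stage_dir("recon")
    vol = read_volume(os.path.join(d, "directions.nii.gz"))
    with open(os.path.join(d, "directions.json")) as fh:
        M = json.load(fh)["max_directions"]
    flat = vol.data.reshape(vol.shape3 + (M, 3))
    dirs = np.where(np.linalg.norm(flat, axis=-1, keepdims=True) > 1e-6, flat, np.nan)
    amps = np.where(np.isnan(dirs[..., 0]), np.nan, 1.0)
    return recon.DirectionField(dirs, amps, vol)


def _stage_track(cfg: PipelineConfig, params: dict) -> dict:
    d = cfg.stage_dir("recon")
    inp = {
        "directions": os.path.join(d, "directions.nii.gz"),
        "directions_sidecar": os.path.join(d, "directions.json"),
        "wm_mask": _phantom_inputs(cfg)["wm_mask"],
    }
    _require(inp, "track")
    dirs = _load_direction_field(cfg)
    mask = read_volume(inp["wm_mask"])
    tp = tracking.default_params(
        mask,
        **{
            k: params[k]
            for k in ("step_size", "angle_threshold", "seeds_per_voxel", "min_length", "max_length")
            if k in params
        },
        rng_seed=cfg.rng_seed,
    )
    t = tracking.track_whole_brain(dirs, mask, tp)
    t = tracking.filter_by_length(t, tp.min_length, tp.max_length)
    if params.get("smooth", False):
        t = tracking.smooth_spline(t, float(params.get("control_point_spacing", 4.0)))
    out = {"tractogram": os.path.join(cfg.stage_dir("track"), "streamlines.trk")}
    tracking.write_trk(t, out["tractogram"], mask)
    return out


def _stage_connectome(cfg: PipelineConfig, params: dict) -> dict:
    inp = {
        "tractogram": os.path.join(cfg.stage_dir("track"), "streamlines.trk"),
        "labels": _phantom_inputs(cfg)["labels"],
        "wm_mask": _phantom_inputs(cfg)["wm_mask"],
    }
    _require(inp, "connectome")
    t = tracking.read_trk(inp["tractogram"])
    labels = read_volume(inp["labels"])
    mask = read_volume(inp["wm_mask"])
    scalar_maps = {}
    for name in params.get("scalar_maps", ["FA", "GFA"]):
        p = os.path.join(cfg.stage_dir("recon"), f"{name}.nii.gz")
        if os.path.exists(p):
            scalar_maps[name] = read_volume(p)
    assignment = cxn.assign_endpoints(
        t, labels, mask, float(params.get("search_radius", cxn.DEFAULT_SEARCH_RADIUS_MM))
    )
    surfaces = cxn.node_surfaces(labels, mask)
    c = cxn.build_connectome(assignment, t, scalar_maps, surfaces=surfaces, scale=1)
    d = cfg.stage_dir("connectome")
    paths = exp.export_matrices(c, d)
    exp.export_node_table(c, os.path.join(d, "nodes.json"))
    out = {os.path.basename(p): p for p in paths}
    out["nodes"] = os.path.join(d, "nodes.json")
    # stash for the export stage
    out["_connectome"] = out["nodes"]
    _stage_connectome.last = c  # type: ignore[attr-defined]
    return {k: v for k, v in out.items() if not k.startswith("_")}


def _stage_export(cfg: PipelineConfig, params: dict) -> dict:
    c = getattr(_stage_connectome, "last", None)
    if c is None:
        raise PreflightError("stage 'export': no connectome available (run the connectome stage)")
    d = cfg.stage_dir("export")
    out = {}
    for fmt in params.get("formats", ["graphml"]):
        p = os.path.join(d, f"connectome.{fmt}")
        exp.export_graph(c, fmt, p)
        out[fmt] = p
    return out


_STAGES = {
    "phantom": _stage_phantom,
    "recon": _stage_recon,
    "track": _stage_track,
    "connectome": _stage_connectome,
    "export": _stage_export,
}
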