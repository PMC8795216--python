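"""End-to-end orchestration: volume → t-MIP → paths → delays → pattern.

The pipeline is configured by a single JSON document (see
``PipelineConfig``), runs deterministically for a given configuration and
seed, and writes a reproducible result bundle: per-voxel delays and
conditioned TACs as CSV, per-segment velocities and the case-level flow
pattern as JSON, plus a manifest recording every resolved parameter.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, flowquant, geometry, io, phantom, preprocess

log = logging.getLogger("flowtrace")


_DEFAULTS = {
    "seed": 0,
    "preprocess": {
        "register": False,
        "reference_frame": 0,
        "max_shift": 5,
        "denoise": True,
        "spatial_sigma_mm": 1.0,
        "range_sigma_hu": 30.0,
    },
    "geometry": {
        "method": "threshold",
        "threshold_hu": None,
        "percentile": None,
        "min_component_voxels": 27,
        "prune_mm": 3.0,
        "snap_radius_vox": 3.0,
    },
    "flowquant": {
        "upsample_factor": 10,
        "cutoff_hz": 0.1,
        "order": 4,
        "qc_fraction": 0.05,
        "slope_min_s_per_mm": 0.005,
        "estimator": "ols",
    },
}


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclasses.dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Exactly one of ``phantom_spec`` (a PhantomSpec, inline dict or path
    to a spec JSON) and ``volume`` (path to a 4D NIfTI) must be given.
    Markers may be a path to a markers JSON or, for phantoms, "auto" to
    derive them from the ground-truth tree.
    """

    out_dir: str
    phantom_spec: object = None
    volume: str = None
    sidecar: str = None
    mask: str = None
    roi: str = None
    markers: object = "auto"
    seed: int = 0
    preprocess: dict = dataclasses.field(default_factory=dict)
    geometry: dict = dataclasses.field(default_factory=dict)
    flowquant: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if (self.phantom_spec is None) == (self.volume is None):
            raise ConfigError("provide exactly one of phantom_spec / volume")
        for section in ("preprocess", "geometry", "flowquant"):
            merged = dict(_DEFAULTS[section])
            extra = set(getattr(self, section)) - set(merged)
            if extra:
                raise ConfigError(f"unknown {section} options: {sorted(extra)}")
            merged.update(getattr(self, section))
            setattr(self, section, merged)
        qc = self.flowquant["qc_fraction"]
        if not 0 < qc < 1:
            raise ConfigError(f"qc_fraction must be in (0, 1), got {qc}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc))


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
    return out


def _load_inputs(cfg: PipelineConfig):
    truth = None
    if cfg.phantom_spec is not None:
        spec = cfg.phantom_spec
        if isinstance(spec, (str, Path)):
            p = Path(spec)
            if not p.exists():
                raise ConfigError(f"phantom spec not found: {p}")
            spec = phantom.spec_from_json(p.read_text())
        elif isinstance(spec, dict):
            spec = phantom.spec_from_json(json.dumps(spec))
        spec = dataclasses.replace(spec, seed=cfg.seed)
        dyn = _stage("phantom", phantom.render_dynamic, spec)
        _, truth = phantom.rasterize_tree(spec)
        if cfg.markers == "auto":
            markers = geometry.MarkerSet(**phantom.default_markers(spec))
        else:
            markers = io.load_markers(_existing(cfg.markers, "markers"))
    else:
        dyn = _stage("load", io.load_dynamic,
                     _existing(cfg.volume, "volume"), cfg.sidecar)
        if cfg.markers in (None, "auto"):
            raise ConfigError("a markers file is required for real data")
        markers = io.load_markers(_existing(cfg.markers, "markers"))
    supplied = io.load_mask(_existing(cfg.mask, "mask")) if cfg.mask else None
    roi = io.load_mask(_existing(cfg.roi, "roi")).data if cfg.roi else None
    return dyn, markers, supplied, roi, truth


def _existing(path, what):
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle to config.out_dir.

    Returns a dict with the in-memory results (paths, delay table,
    segment flows, pattern) and the list of files written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    dyn, markers, supplied, roi, truth = _load_inputs(config)
    log.info("volume %s, dt=%.3g s, spacing=%s", dyn.data.shape, dyn.dt,
             dyn.spacing)

    pp = config.preprocess
    shifts = None
    if pp["register"]:
        dyn, shifts = _stage("register", preprocess.register_frames, dyn,
                             pp["reference_frame"], pp["max_shift"])
    if pp["denoise"]:
        dyn = _stage("denoise", preprocess.bilateral_denoise, dyn,
                     pp["spatial_sigma_mm"], pp["range_sigma_hu"])
    tmip = _stage("tmip", preprocess.compute_tmip, dyn)

    geo = config.geometry
    if supplied is not None:
        mask = _stage("segment", geometry.segment_vessels, tmip,
                      method="supplied", supplied_mask=supplied)
    else:
        mask = _stage("segment", geometry.segment_vessels, tmip,
                      method=geo["method"], threshold_hu=geo["threshold_hu"],
                      percentile=geo["percentile"],
                      min_component_voxels=geo["min_component_voxels"])
    if roi is not None:
        mask = _stage("roi", geometry.restrict_to_roi, mask, roi)
    skel = _stage("skeletonize", geometry.skeletonize, mask, geo["prune_mm"])
    log.info("skeleton: %d nodes, %d endpoints, %d branch nodes",
             skel.graph.number_of_nodes(), len(skel.endpoints()),
             len(skel.branch_nodes()))
    paths = _stage("paths", geometry.assemble_paths, tmip, skel, markers,
                   geo["snap_radius_vox"])

    fq = config.flowquant
    delays_rows, tac_rows, flows = [], [], {}
    proximal_ref = None
    for path in paths:
        tacs = _stage(f"tacs[{path.path_id}]", flowquant.extract_tacs, dyn,
                      path)
        conditioned = [flowquant.condition_tac(t, fq["upsample_factor"],
                                               fq["cutoff_hz"], fq["order"])
                       for t in tacs]
        if proximal_ref is None:
            proximal_ref = conditioned[0]  # the snapped proximal marker voxel
        flowquant.qc_discard(conditioned, proximal_ref, fq["qc_fraction"])
        points = [flowquant.xcorr_delay(t, proximal_ref) for t in conditioned]
        series, flagged = flowquant.delay_profile(path, points)
        for seg_id in flagged:
            if seg_id not in ("proximal", "thrombus"):
                log.warning("%s/%s: too few valid points, not fitted",
                            path.path_id, seg_id)
        for seg_id, ser in series.items():
            if seg_id in ("proximal", "thrombus"):
                continue
            if seg_id not in flows:  # mother is shared between paths
                flows[seg_id] = flowquant.fit_segment_velocity(
                    ser, path.path_id, seg_id, fq["slope_min_s_per_mm"],
                    fq["estimator"])
        for seg_id, dp, tac in zip(path.segment_ids, points, conditioned):
            delays_rows.append({
                "path_id": path.path_id, "segment_id": seg_id,
                "i": dp.voxel[0], "j": dp.voxel[1], "k": dp.voxel[2],
                "arclength_mm": dp.arclength_mm, "delay_s": dp.delay_s,
                "corr_peak": dp.correlation_peak, "valid": dp.valid})
            for t, v in zip(tac.times, tac.values):
                tac_rows.append({"path_id": path.path_id,
                                 "segment_id": seg_id,
                                 "arclength_mm": tac.arclength_mm,
                                 "time_s": t, "value_hu": v})

    daughters = [f for s, f in sorted(flows.items())
                 if s.startswith("daughter")]
    if not daughters:
        daughters = [f for s, f in sorted(flows.items()) if s == "mother"]
    pattern = _stage("classify", flowquant.classify_pattern, daughters)
    log.info("pattern %s", pattern.pattern)

    delays = pd.DataFrame(delays_rows)
    tacs_df = pd.DataFrame(tac_rows)
    files = _write_bundle(out_dir, config, delays, tacs_df, flows, pattern,
                          paths, truth, shifts)
    return {"paths": paths, "delays": delays, "flows": flows,
            "pattern": pattern, "files": files}


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _write_bundle(out_dir, config, delays, tacs_df, flows, pattern, paths,
                  truth, shifts):
    files = {}

    def write_json(name, obj):
        p = out_dir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        files[name] = p

    delays.to_csv(out_dir / "delays.csv", index=False)
    files["delays.csv"] = out_dir / "delays.csv"
    tacs_df.to_csv(out_dir / "tacs.csv", index=False)
    files["tacs.csv"] = out_dir / "tacs.csv"
    io.paths_to_frame(paths).to_csv(out_dir / "paths.csv", index=False)
    files["paths.csv"] = out_dir / "paths.csv"
    if truth is not None:
        io.truth_to_frame(truth).to_csv(out_dir / "truth.csv", index=False)
        files["truth.csv"] = out_dir / "truth.csv"
    write_json("segments.json", {
        seg: {"path_id": f.path_id, "slope_s_per_mm": f.slope_s_per_mm,
              "velocity_mm_s": f.velocity_mm_s, "direction": f.direction,
              "n_points": f.n_points, "r_squared": f.r_squared,
              "residual_sd_s": f.residual_sd_s, "reason": f.reason}
        for seg, f in flows.items()})
    write_json("pattern.json", {"pattern": pattern.pattern,
                                "daughters": pattern.daughters,
                                "notes": pattern.notes})
    manifest = {
        "software": {"name": "flowtrace", "version": __version__},
        "seed": config.seed,
        "preprocess": config.preprocess,
        "geometry": config.geometry,
        "flowquant": config.flowquant,
        "registration_shifts_vox":
            None if shifts is None else np.asarray(shifts).tolist(),
    }
    write_json("manifest.json", manifest)
    return files


def make_phantom(spec_path, out_dir) -> dict:
    """Render a phantom spec and write volume, mask, truth and markers."""
    p = Path(spec_path)
    if not p.exists():
        raise ConfigError(f"phantom spec not found: {p}")
    spec = phantom.spec_from_json(p.read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dyn = phantom.render_dynamic(spec)
    mask, truth = phantom.rasterize_tree(spec)
    io.save_dynamic(dyn, out_dir / "phantom.nii.gz",
                    out_dir / "phantom.json")
    io.save_mask(geometry.VesselMask(mask, spec.spacing, spec.origin),
                 out_dir / "mask.nii.gz")
    io.truth_to_frame(truth).to_csv(out_dir / "truth.csv", index=False)
    io.save_markers(phantom.default_markers(spec), out_dir / "markers.json")
    return {"volume": out_dir / "phantom.nii.gz",
            "mask": out_dir / "mask.nii.gz",
            "truth": out_dir / "truth.csv",
            "markers": out_dir / "markers.json"}
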