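"""Study orchestration: simulate → register → segment ×2 → match → vectors → stats.

A study config (YAML) lists groups, samples and per-increment scan pairs
plus the cavity geometry and per-module parameter sections.  The pipeline
processes every scan pair independently through declared files, pools
per-increment fields into cumulative rows (liner, liner + increment 1,
...), runs the statistical battery on the resulting cells, and writes a
manifest with the config hash, derived seeds and per-stage counts so any
output can be reproduced from the manifest alone.  Unmatched-sphere counts
are surfaced in the log and manifest: silent tracer attrition is the main
failure mode of this kind of analysis.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.filters import threshold_otsu

from . import phantom as ph
from .matching import MatchParams, match_scan_pair
from .registration import RegistrationParams, register_rigid
from .segmentation import SegmentationParams, make_cavity_mask, segment_spheres
from .stats import analyze_measure
from .transforms import RigidTransform
from .vectors import (ShrinkageVectorField, compute_vectors, concat_fields,
                      export_glyphs, summarize_field)
from .volume import (Volume, config_hash, read_volume, write_provenance,
                     write_vector_table, write_volume)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, label: str, message: str):
        super().__init__(f"[{stage}] {label}: {message}")
        self.stage = stage
        self.label = label


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed mixed with the stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# phantom simulation from config


def phantom_from_config(cfg: dict):
    """Build (spec, deformation, pose) from a phantom config mapping."""
    spec_cfg = dict(cfg.get("spec", {}))
    preset = spec_cfg.pop("preset", None)
    layers = spec_cfg.pop("layers", None)
    if layers:
        spec_cfg["layers"] = tuple(
            ph.Layer(l["label"], float(l["top_z"]), float(l["bottom_z"]),
                     float(l["attenuation"])) for l in layers)
    if "grid_shape" in spec_cfg:
        spec_cfg["grid_shape"] = tuple(spec_cfg["grid_shape"])
    if "bead_diameter_range" in spec_cfg:
        spec_cfg["bead_diameter_range"] = tuple(
            spec_cfg["bead_diameter_range"])
    maker = {None: ph.PhantomSpec, "desk": ph.PhantomSpec,
             "small": ph.small_spec, "full_scale": ph.full_scale_spec}
    if preset not in maker:
        raise PipelineError("simulate", "config", f"unknown preset {preset!r}")
    spec = maker[preset](**spec_cfg)

    dcfg = dict(cfg.get("deformation", {"kind": "none"}))
    if dcfg.get("center") in (None, "floor"):
        dcfg["center"] = spec.floor_center
    parts = dcfg.pop("parts", None)
    if parts:
        dcfg["parts"] = tuple(
            ph.DeformationModel(**{**p, "center": tuple(
                p.get("center", spec.floor_center))}) for p in parts)
    dcfg["center"] = tuple(dcfg["center"])
    deformation = ph.DeformationModel(**dcfg)

    pcfg = cfg.get("rigid_pose")
    pose = RigidTransform.from_dict(pcfg) if pcfg else RigidTransform()
    return spec, deformation, pose


def simulate_to_dir(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Generate a phantom pair and write pre.mha, post.mha, truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, deformation, pose = phantom_from_config(cfg)
    if seed is None:
        seed = spec.seed
    pre, post, truth = ph.generate_phantom(spec, deformation, pose, seed=seed)
    prov = {"seed": seed, "spec": spec.to_dict(),
            "deformation": deformation.to_dict(),
            "rigid_pose": pose.to_dict()}
    write_volume(pre, out / "pre.mha", provenance=prov)
    write_volume(post, out / "post.mha", provenance=prov)
    truth.table.to_csv(out / "truth.csv", index=False, float_format="%.17g")
    write_provenance(out / "truth.csv", prov)
    (out / "phantom.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True, default=str))
    return {"spec": spec, "deformation": deformation, "pose": pose,
            "paths": {"pre": out / "pre.mha", "post": out / "post.mha",
                      "truth": out / "truth.csv"}}


# ---------------------------------------------------------------------------
# study pipeline


def auto_registration_mask(volume: Volume, cavity: dict,
                           dilate_voxels: float = 3.0) -> np.ndarray:
    """Static-anatomy mask from the scan itself: bright (tooth) voxels
    outside the cavity cylinder dilated by ``dilate_voxels``."""
    thr = float(threshold_otsu(volume.data[::2, ::2, ::2].astype(np.float32)))
    fg = volume.data > thr
    vs = float(volume.voxel_size[0])
    pad = dilate_voxels * vs
    cav = make_cavity_mask(
        volume,
        (cavity["center_x"], cavity["center_y"], cavity["top_z"] - pad),
        cavity["diameter"] + 2 * pad, cavity["depth"] + 2 * pad,
        margin_voxels=0.0)
    return fg & ~cav


def load_study_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineError("config", str(path), "config file not found")
    cfg = yaml.safe_load(path.read_text())
    cfg.setdefault("alpha", 0.05)
    cfg.setdefault("seed", 0)
    cfg.setdefault("cumulative", True)
    cfg["_config_path"] = str(path)
    return cfg


def _validate_config(cfg: dict, base: Path) -> None:
    seen = set()
    if "cavity" not in cfg or "groups" not in cfg:
        raise PipelineError("config", "study",
                            "config must define 'cavity' and 'groups'")
    for grp in cfg["groups"]:
        for sample in grp["samples"]:
            labels = [inc["label"] for inc in sample["increments"]]
            if len(set(labels)) != len(labels):
                raise PipelineError(
                    "config", f"{grp['name']}/{sample['name']}",
                    "duplicate increment labels")
            key = (grp["name"], sample["name"])
            if key in seen:
                raise PipelineError("config", grp["name"],
                                    f"duplicate sample {sample['name']!r}")
            seen.add(key)
            for inc in sample["increments"]:
                for role in ("pre", "post"):
                    p = base / inc[role]
                    if not p.exists():
                        raise PipelineError(
                            "config", f"{grp['name']}/{sample['name']}",
                            f"missing {role} scan: {p}")


def _params_from(cfg: dict, key: str, cls):
    return cls(**cfg.get(key, {}))


def run_pipeline(config: dict, base_dir=None) -> dict:
    """Run the full study; returns the manifest (also written to disk)."""
    base = Path(base_dir) if base_dir else Path(
        config.get("_config_path", ".")).parent
    _validate_config(config, base)
    out_dir = base / config.get("output_dir", "study_out")
    out_dir.mkdir(parents=True, exist_ok=True)

    cavity = config["cavity"]
    seg_params = _params_from(config, "segmentation", SegmentationParams)
    match_params = _params_from(config, "matching", MatchParams)
    reg_cfg = dict(config.get("registration", {}))
    reg_enabled = reg_cfg.pop("enabled", True)
    reg_params = RegistrationParams(**reg_cfg)
    voxel_override = config.get("voxel_size")

    cfg_for_hash = {k: v for k, v in config.items()
                    if not k.startswith("_")}
    manifest: dict = {
        "tool": "shrinkvec", "config_hash": config_hash(cfg_for_hash),
        "seed": config["seed"],
        "derived_seeds": {"shapiro_subsample":
                          derive_seed(config["seed"], "shapiro")},
        "pairs": [], "outputs": [],
    }

    fields_by_sample: dict = {}
    for grp in config["groups"]:
        for sample in grp["samples"]:
            pair_fields = []
            for inc in sample["increments"]:
                label = f"{grp['name']}/{sample['name']}/{inc['label']}"
                try:
                    field = _process_pair(
                        base, out_dir, grp["name"], sample["name"], inc,
                        cavity, voxel_override, reg_enabled, reg_params,
                        seg_params, match_params, manifest)
                except PipelineError:
                    raise
                except Exception as exc:  # noqa: BLE001 - annotate stage
                    raise PipelineError("pair", label, str(exc)) from exc
                pair_fields.append((inc["label"], field))
            fields_by_sample[(grp["name"], sample["name"])] = pair_fields

    # cumulative per-increment cells pooled across samples of each group
    cells: dict[str, list[ShrinkageVectorField]] = {}
    for (gname, sname), pair_fields in fields_by_sample.items():
        running = []
        for label, field in pair_fields:
            running.append((label, field))
            if config["cumulative"]:
                cum_label = "+".join(l for l, _ in running)
                pooled = concat_fields([f for _, f in running],
                                       label=cum_label)
            else:
                cum_label, pooled = label, field
            cells.setdefault(f"{gname}:{cum_label}", []).append(pooled)

    summary_fields = {k: concat_fields(v) for k, v in cells.items()}
    summary = summarize_field(list(summary_fields.values()))
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.17g")
    manifest["outputs"].append(summary_path.name)

    stats_out = {}
    eligible = {k: f.magnitudes for k, f in summary_fields.items()
                if len(f) >= 2}
    if len(eligible) >= 2:
        for measure in ("magnitude", "z"):
            vals = {k: (f.magnitudes if measure == "magnitude"
                        else f.z_components)
                    for k, f in summary_fields.items() if len(f) >= 2}
            res = analyze_measure(vals, alpha=config["alpha"])
            res["posthoc"].pairs.to_csv(
                out_dir / f"posthoc_{measure}.csv", index=False,
                float_format="%.17g")
            stats_out[measure] = {
                "anova": asdict(res["anova"]),
                "normality": res["normality"],
                "letters": res["posthoc"].letters,
            }
            manifest["outputs"].append(f"posthoc_{measure}.csv")
    manifest["stats"] = stats_out

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _process_pair(base, out_dir, gname, sname, inc, cavity, voxel_override,
                  reg_enabled, reg_params, seg_params, match_params,
                  manifest) -> ShrinkageVectorField:
    tag = f"{gname}_{sname}_{inc['label']}"
    pre = read_volume(base / inc["pre"], voxel_size_um=voxel_override)
    post = read_volume(base / inc["post"], voxel_size_um=voxel_override)
    if not np.allclose(pre.voxel_size, post.voxel_size):
        raise PipelineError("read", tag, "pre/post voxel sizes differ")
    vs = float(pre.voxel_size[0])

    if reg_enabled:
        mask = auto_registration_mask(pre, cavity)
        reg = register_rigid(pre, post, mask=mask, params=reg_params)
        transform = reg.transform
        reg_info = {"similarity": reg.final_similarity,
                    "iterations": reg.iterations,
                    "converged": reg.converged,
                    "transform": transform.to_dict()}
    else:
        transform = RigidTransform()
        reg_info = {"skipped": True}

    center = (cavity["center_x"], cavity["center_y"], cavity["top_z"])
    margin = cavity.get("margin_voxels", 2.0)
    mask_pre = make_cavity_mask(pre, center, cavity["diameter"],
                                cavity["depth"], margin_voxels=margin)
    mask_post = make_cavity_mask(post, center, cavity["diameter"],
                                 cavity["depth"], margin_voxels=margin,
                                 transform=transform)
    pre_set = segment_spheres(pre, mask_pre, seg_params)
    post_set = segment_spheres(post, mask_post, seg_params)
    matches = match_scan_pair(pre, post, pre_set, post_set, transform,
                              match_params)
    field = compute_vectors(matches, pre_set, post_set, transform, vs,
                            group=gname, sample=sname,
                            increment=inc["label"])

    vec_path = out_dir / f"vectors_{tag}.csv"
    write_vector_table(field.table, vec_path)
    if len(field):
        export_glyphs(field, out_dir / f"glyphs_{tag}.vtk")
    manifest["pairs"].append({
        "group": gname, "sample": sname, "increment": inc["label"],
        "registration": reg_info,
        "counts": {"pre_spheres": len(pre_set),
                   "post_spheres": len(post_set),
                   "matched": len(matches),
                   "unmatched_pre": len(matches.unmatched_pre),
                   "unmatched_post": len(matches.unmatched_post)},
    })
    manifest["outputs"].append(vec_path.name)
    log.info("%s: %d/%d pre spheres matched (%d post unmatched)", tag,
             len(matches), len(pre_set), len(matches.unmatched_post))
    return field
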