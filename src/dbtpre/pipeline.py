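"""Stage orchestration: simulate -> train -> translate -> reconstruct ->
evaluate, driven by a single YAML/JSON config with a saved snapshot and a
run manifest (file hashes) per stage.

Every stage is a plain function taking the materialized config dict; the
CLI is a thin wrapper.  All defaulted values are resolved into the snapshot
written next to the outputs, so a run can be reproduced from its manifest
alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimator import CycleGANTranslator
from .geometry import AcquisitionGeometry, ProjectionSet
from .metrics import evaluate_image
from .phantom import make_phantom
from .preprocess import extract_patches, normalize_image
from .projection import simulate_acquisition
from .recon import ReconVolume, backproject, in_focus_plane

log = logging.getLogger("dbtpre")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "runs/default",
    "geometry": {
        "n_projections": 15,
        "arc_deg": 15.0,
        "detector_shape": [256, 512],
        "pixel_pitch": 0.14,
        "sweep_axis": 1,
    },
    "phantom": {
        "shape": [16, 256, 512],
        "breast_type": "dense",
        "n_masses": 1,
        "n_mcs": 0,
        "voxel_size": 1.0,
    },
    "dose": {
        "reference_level": 1.0e4,
        "object_level": 1.0e3,
        "EI_target": 2000.0,
        "n_cases": 4,
    },
    "patching": {
        "n_patches": 128,
        "patch_size": 128,
        "flip_prob": 0.5,
        "normalize_mode": "as_printed",
    },
    "network": {"kind": "rSEAG", "depth": 2, "base_channels": 8},
    "trainer": {
        "n_epochs": 3,
        "minibatch": 16,
        "learning_rate": 1.0e-4,
        "gradient_decay": 0.5,
        "squared_gradient_decay": 0.999,
        "lambda_adv": 1.0,
        "lambda_cycle": 10.0,
        "lambda_fidelity": 5.0,
    },
    "reconstruction": {"plane_spacing_mm": 1.0, "filtered": True},
    "metrics": {"glcm_levels": 256, "gumbel_width": 30, "gumbel_profiles": 29},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Materialize a full config: defaults <- file <- overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping: {path}")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, cfg: dict, outputs: list[Path],
                   t0: float):
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": cfg,
        "outputs": {str(p.relative_to(out_dir)): _file_hash(p) for p in outputs},
        "wall_time_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _geometry(cfg: dict) -> AcquisitionGeometry:
    g = cfg["geometry"]
    return AcquisitionGeometry(
        n_projections=g["n_projections"], arc_deg=g["arc_deg"],
        detector_shape=tuple(g["detector_shape"]),
        pixel_pitch=g["pixel_pitch"], sweep_axis=g["sweep_axis"])


def cmd_simulate(cfg: dict, out_dir: str | Path | None = None) -> dict[str, list[Path]]:
    """Simulate reference- and object-dose projection sets for n_cases."""
    t0 = time.time()
    out_dir = Path(out_dir or cfg["output_dir"])
    (out_dir / "projections").mkdir(parents=True, exist_ok=True)
    geom = _geometry(cfg)
    ph = cfg["phantom"]
    dose = cfg["dose"]
    seed = int(cfg["seed"])
    written: dict[str, list[Path]] = {"reference": [], "object": []}
    for case in range(int(dose["n_cases"])):
        phantom = make_phantom(tuple(ph["shape"]), ph["breast_type"],
                               ph["n_masses"], ph["n_mcs"],
                               voxel_size=ph["voxel_size"],
                               seed=seed + 1000 + case)
        for domain, level in (("reference", dose["reference_level"]),
                              ("object", dose["object_level"])):
            ps = simulate_acquisition(phantom, geom, level,
                                      seed=seed + 2000 + 2 * case + (domain == "object"),
                                      EI_target=dose["EI_target"])
            path = out_dir / "projections" / f"case{case:03d}_{domain}.tiff"
            ps.save(path)
            written[domain].append(path)
            for k, d in enumerate(ps.dose_indices):
                log.info("case %d %s proj %d: EI=%.1f DI=%+.2f",
                         case, domain, k, d.EI, d.DI)
    outputs = [p for ps in written.values() for p in ps]
    (out_dir / "config_snapshot.yaml").write_text(yaml.safe_dump(cfg))
    write_manifest(out_dir, "simulate", cfg, outputs, t0)
    return written


def _patch_pool(files: list[Path], cfg: dict, seed_offset: int) -> np.ndarray:
    pcfg = cfg["patching"]
    pools = []
    for i, f in enumerate(sorted(files)):
        ps = ProjectionSet.load(f)
        for j, img in enumerate(ps.images):
            norm = normalize_image(img, pcfg["normalize_mode"])
            size = min(pcfg["patch_size"], *norm.data.shape)
            batch = extract_patches(norm.data, pcfg["n_patches"], size,
                                    pcfg["flip_prob"],
                                    seed=cfg["seed"] + seed_offset + 97 * i + j,
                                    source_id=f"{f.name}:{j}")
            pools.append(batch.patches)
    return np.concatenate(pools, axis=0)


def cmd_train(cfg: dict, out_dir: str | Path | None = None) -> CycleGANTranslator:
    """Build patch pools from simulated projections and train the translator."""
    t0 = time.time()
    out_dir = Path(out_dir or cfg["output_dir"])
    proj_dir = out_dir / "projections"
    ref_files = sorted(proj_dir.glob("*_reference.tiff"))
    obj_files = sorted(proj_dir.glob("*_object.tiff"))
    if not ref_files or not obj_files:
        raise FileNotFoundError("no simulated projections found; run simulate first")
    ref_pool = _patch_pool(ref_files, cfg, 31)
    obj_pool = _patch_pool(obj_files, cfg, 57)
    net, tr = cfg["network"], cfg["trainer"]
    model = CycleGANTranslator(
        kind=net["kind"], depth=net["depth"], base_channels=net["base_channels"],
        n_epochs=tr["n_epochs"], lambda_adv=tr["lambda_adv"],
        lambda_cycle=tr["lambda_cycle"], lambda_fidelity=tr["lambda_fidelity"],
        learning_rate=tr["learning_rate"], gradient_decay=tr["gradient_decay"],
        squared_gradient_decay=tr["squared_gradient_decay"],
        minibatch=tr["minibatch"], tile=cfg["patching"]["patch_size"],
        random_state=int(cfg["seed"]))
    model.fit(obj_pool, ref_pool)
    from .train import save_checkpoint

    ckpt = save_checkpoint(out_dir / "checkpoint.npz", model.models_)
    curves = pd.DataFrame(model.training_state_.loss_curves)
    curves["val_mse"] = pd.Series(model.training_state_.val_mse)
    curves.index = np.arange(1, len(curves) + 1)
    curves.to_csv(out_dir / "loss_curves.csv", index_label="epoch")
    write_manifest(out_dir, "train", cfg, [ckpt, out_dir / "loss_curves.csv"], t0)
    return model


def cmd_translate(cfg: dict, model: CycleGANTranslator,
                  projection_files: list[Path],
                  out_dir: str | Path | None = None) -> list[Path]:
    """Run full projections through the fitted translator, shape preserved."""
    t0 = time.time()
    out_dir = Path(out_dir or cfg["output_dir"])
    (out_dir / "translated").mkdir(parents=True, exist_ok=True)
    written = []
    for f in projection_files:
        ps = ProjectionSet.load(Path(f))
        translated = model.transform(ps.images)
        out = ProjectionSet(images=translated, angles_deg=ps.angles_deg,
                            geometry=ps.geometry, dose_domain="reference",
                            dose_indices=ps.dose_indices, seed=ps.seed)
        path = out_dir / "translated" / Path(f).name
        out.save(path)
        written.append(path)
    write_manifest(out_dir, "translate", cfg, written, t0)
    return written


def cmd_reconstruct(cfg: dict, projection_files: list[Path],
                    out_dir: str | Path | None = None) -> list[Path]:
    """Filtered backprojection of each projection set."""
    t0 = time.time()
    out_dir = Path(out_dir or cfg["output_dir"])
    (out_dir / "recon").mkdir(parents=True, exist_ok=True)
    rcfg = cfg["reconstruction"]
    nz = cfg["phantom"]["shape"][0] * cfg["phantom"]["voxel_size"]
    heights = np.arange(rcfg["plane_spacing_mm"] / 2.0, nz,
                        rcfg["plane_spacing_mm"])
    written = []
    for f in projection_files:
        ps = ProjectionSet.load(Path(f))
        vol = backproject(ps, heights, filtered=rcfg["filtered"])
        path = out_dir / "recon" / Path(f).name
        vol.save(path)
        written.append(path)
    write_manifest(out_dir, "reconstruct", cfg, written, t0)
    return written


def cmd_evaluate(cfg: dict, recon_files: list[Path],
                 out_dir: str | Path | None = None,
                 focus_height: float | None = None) -> Path:
    """Quality report (PIQE + GLCM + Gumbel) per in-focus plane."""
    t0 = time.time()
    out_dir = Path(out_dir or cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    if not recon_files:
        raise FileNotFoundError("no reconstruction volumes to evaluate")
    mcfg = cfg["metrics"]
    rows = []
    for f in recon_files:
        vol = ReconVolume.load(Path(f))
        target = focus_height if focus_height is not None else float(
            np.median(vol.heights))
        plane = in_focus_plane(vol, target)
        report = evaluate_image(plane, image_id=Path(f).stem,
                                glcm_levels=mcfg["glcm_levels"],
                                gumbel_width=mcfg["gumbel_width"],
                                gumbel_profiles=mcfg["gumbel_profiles"],
                                sweep_axis=vol.geometry.sweep_axis)
        rows.append(report.to_dict())
    df = pd.DataFrame(rows)
    csv_path = out_dir / "quality_report.csv"
    json_path = out_dir / "quality_report.json"
    df.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(rows, indent=2))
    write_manifest(out_dir, "evaluate", cfg, [csv_path, json_path], t0)
    return csv_path
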