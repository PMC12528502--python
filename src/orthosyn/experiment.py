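"""End-to-end experiment orchestration: phantom cohort -> preprocessing ->
DRRs -> training (single loss or the four-way ablation) -> masked
evaluation -> statistical comparison, with every artifact reconstructible
from (config, seed) alone.

The experiment configuration is one YAML document with per-module blocks
(``phantom``, ``cohort``, ``model``, ``loss``, ``train``, ``prep``); see
:func:`default_config` for the full set of keys and their defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import compare_losses, evaluate_cohort
from .losses import ABLATION_WEIGHTS, FeatureExtractorSpec, LossWeights
from .network import ModelConfig, build_model
from .phantom import PhantomSpec, make_cohort
from .pipeline import PrepSettings
from .preprocess import truncate_normalize
from .training import (TrainConfig, load_checkpoint, restore_model, run_ablation,
                       save_checkpoint, train)
from .volume import VolumeImage, read_nifti, write_nifti

log = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "run_experiment", "infer"]


def default_config(seed: int = 0) -> dict:
    """Desk-scale defaults: a miniature cohort and a narrow network that the
    full pipeline runs on a single CPU in minutes."""
    return {
        "seed": seed,
        "out_dir": "experiment_out",
        "save_cohort_nifti": False,
        "ablation": True,
        "phantom": {
            "grid_shape": [32, 32, 16],
            "spacing_mm": [8.0, 8.0, 8.0],
            "n_fractions": 3,
            "noise_sigma_hu": 20.0,
            "intensity_offset_hu": 0.0,
        },
        "cohort": {"n_patients": 4, "split_fractions": [0.5, 0.25, 0.25]},
        "model": {"variant": "fusion_skip_res", "base_channels": 8, "n_levels": 4},
        "loss": {"preset": "ALF", "backbone": "seeded_random_cnn",
                 "layer_ids": [3, 8, 15, 22], "feature_seed": 0, "width": 8},
        "train": {"epochs": 3},
        # translation range 1 voxel: the 8 mm desk grid keeps the ~10 mm
        # physical augmentation magnitude of the 1.98 mm reference raster
        "prep": {"use_central_mask": True, "dilation_px": 3, "augment": True,
                 "max_translation_px": 1},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _build_parts(cfg: dict):
    seed = int(cfg["seed"])
    spec = PhantomSpec(
        grid_shape=tuple(cfg["phantom"]["grid_shape"]),
        spacing_mm=tuple(cfg["phantom"]["spacing_mm"]),
        n_fractions=int(cfg["phantom"]["n_fractions"]),
        noise_sigma_hu=float(cfg["phantom"]["noise_sigma_hu"]),
        intensity_offset_hu=float(cfg["phantom"].get("intensity_offset_hu", 0.0)),
    )
    grid = spec.grid_shape
    model_cfg = ModelConfig(
        variant=cfg["model"]["variant"],
        in_shape_3d=grid,
        in_raster_2d=(grid[0], grid[1]),
        base_channels=int(cfg["model"]["base_channels"]),
        n_levels=int(cfg["model"]["n_levels"]),
    )
    loss_cfg = cfg["loss"]
    if "preset" in loss_cfg and loss_cfg["preset"]:
        weights = LossWeights.preset(loss_cfg["preset"])
    else:
        weights = LossWeights(*[float(loss_cfg[k]) for k in ("alpha", "beta", "gamma", "omega")])
    feat_spec = FeatureExtractorSpec(
        backbone=loss_cfg.get("backbone", "seeded_random_cnn"),
        layer_ids=tuple(loss_cfg.get("layer_ids", (3, 8, 15, 22))),
        seed=int(loss_cfg.get("feature_seed", 0)),
        width=int(loss_cfg.get("width", 8)),
    )
    train_cfg = TrainConfig(seed=seed, **{k: v for k, v in cfg["train"].items() if k != "seed"})
    prep = PrepSettings(
        use_central_mask=bool(cfg["prep"].get("use_central_mask", True)),
        dilation_px=int(cfg["prep"].get("dilation_px", 3)),
        augment=bool(cfg["prep"].get("augment", True)),
        max_translation_px=int(cfg["prep"].get("max_translation_px", 5)),
        max_rotation_deg=float(cfg["prep"].get("max_rotation_deg", 4.0)),
    )
    return seed, spec, model_cfg, weights, feat_spec, train_cfg, prep


def run_experiment(cfg: dict) -> Path:
    """Run the configured experiment; returns the artifact directory.

    Artifacts: cohort manifest, per-loss training history and best
    checkpoint, per-case metric reports, the ablation summary table,
    Dunn/Bonferroni comparison tables per metric, and a provenance record
    (config + hash + package version).
    """
    seed, spec, model_cfg, weights, feat_spec, train_cfg, prep = _build_parts(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    cohort = make_cohort(spec, int(cfg["cohort"]["n_patients"]),
                         tuple(cfg["cohort"]["split_fractions"]), seed=seed,
                         out_dir=out / "cohort" if cfg.get("save_cohort_nifti") else None)
    (out / "cohort_manifest.json").write_text(json.dumps(cohort.manifest(), indent=2))

    if cfg.get("ablation", True):
        log.info("training the four loss ablations")
        models, reports, table = run_ablation(cohort, model_cfg, train_cfg,
                                              feat_spec, prep, out_dir=out)
        for name, reps in reports.items():
            with open(out / f"metrics_{name.replace('&', '_')}.json", "w") as fh:
                json.dump(reps, fh, indent=2)
        comparisons = {}
        for metric in ("mmae_hu", "mssim", "mpsnr_db", "clpips"):
            tables = {name: np.array([r[metric] for r in reps if np.isfinite(r[metric])])
                      for name, reps in reports.items()}
            try:
                res = compare_losses(tables)
            except ValueError as exc:
                log.warning("comparison skipped for %s: %s", metric, exc)
                continue
            res.pairwise_adjusted_p.to_csv(out / f"compare_{metric}_padj.csv")
            res.stars.to_csv(out / f"compare_{metric}_stars.csv")
            comparisons[metric] = {"omnibus_p": res.omnibus_p,
                                   "normality_p": res.normality_p}
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
    else:
        log.info("training a single model (%s)", cfg["loss"].get("preset", "custom"))
        model = build_model(model_cfg)
        best, history = train(model, cohort, weights, feat_spec, train_cfg, prep,
                              out_dir=out / "single")
        reports, summary = evaluate_cohort(restore_model(best), cohort, "test",
                                           prep, feat_spec)
        with open(out / "metrics_single.json", "w") as fh:
            json.dump({"reports": reports, "summary": summary}, fh, indent=2)

    provenance = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


def infer(ckpt_path: str | Path, drr0_path: str | Path, drr270_path: str | Path,
          pct_path: str | Path, out_dir: str | Path,
          preprocess_pct: bool = True) -> tuple[Path, Path]:
    """Synthesise a CBCT from a stored DRR pair and a planning CT.

    Writes the volume in both the normalised and the HU domain (the HU
    mapping inverts the planning CT's normalisation record).  Returns the
    two output paths.
    """
    rec = load_checkpoint(ckpt_path)
    model = restore_model(rec)
    cfg = rec.model_config

    def _read2d(path):
        img = read_nifti(path, intensity_domain="HU")
        data = np.squeeze(img.data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D projection")
        return data

    drrs = np.stack([_read2d(drr0_path), _read2d(drr270_path)])
    pct = read_nifti(pct_path, intensity_domain="HU")
    pct01 = truncate_normalize(pct) if preprocess_pct else VolumeImage(
        pct.data, pct.spacing_mm, "normalized01", norm_bounds=(-1000.0, 2000.0))
    if tuple(pct01.shape) != tuple(cfg.in_shape_3d):
        raise ValueError(f"pCT shape {pct01.shape} does not match checkpoint {cfg.in_shape_3d}")
    if drrs.shape[1:] != tuple(cfg.in_raster_2d):
        raise ValueError(f"DRR raster {drrs.shape[1:]} does not match checkpoint {cfg.in_raster_2d}")

    out01 = model(drrs, pct01.data).data
    lo, hi = pct01.norm_bounds
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_norm = out / "scbct_normalized.nii"
    p_hu = out / "scbct_hu.nii"
    write_nifti(VolumeImage(out01, pct.spacing_mm, "HU"), p_norm)
    write_nifti(VolumeImage(out01 * (hi - lo) + lo, pct.spacing_mm, "HU"), p_hu)
    return p_norm, p_hu
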