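"""Training protocol: AdamW, plateau learning-rate decay, best-checkpoint
selection, per-epoch validation, and the loss-ablation harness.

Defaults follow the framework's protocol: AdamW with beta1=0.9,
beta2=0.999, eps=1e-8, weight decay 1e-2, initial learning rate 1e-3,
batch size one, Kaiming-He-uniform initialisation, learning rate divided
by 10 after 5 consecutive epochs without relative validation-loss
improvement above 1e-4, floored at 1e-6, and the checkpoint with the
lowest validation loss kept.  Augmentation is resampled online every epoch
for the training split only; validation uses un-augmented data.  Runs are
a pure function of their seeds (CPU, deterministic ops).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .losses import ABLATION_WEIGHTS, FeatureExtractorSpec, LossWeights, alf_total
from .network import ModelConfig, ReconModel, build_model
from .phantom import Cohort
from .pipeline import PrepSettings, Sample, prepare_fraction
from .preprocess import AugmentParams

__all__ = [
    "TrainConfig", "CheckpointRecord", "PlateauScheduler", "init_weights",
    "train_step", "train", "run_ablation", "save_checkpoint", "load_checkpoint",
]

init_weights = nn.init_weights  # seeded Kaiming-He-uniform conv initialisation


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 1  # the protocol fixes batch size one
    lr0: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-2
    plateau_factor: float = 10.0
    plateau_patience: int = 5
    plateau_threshold: float = 1e-4
    lr_min: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("the training protocol uses batch size one")
        if self.lr_min > self.lr0:
            raise ValueError("lr_min must not exceed lr0")
        if self.plateau_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class CheckpointRecord:
    epoch: int
    validation_loss: float
    lr: float
    state: dict[str, np.ndarray]
    model_config: ModelConfig


class PlateauScheduler:
    """Reduce-on-plateau in relative mode: an epoch improves when its loss
    is below best * (1 - threshold); after `patience` consecutive
    non-improving epochs the rate divides by `factor`, never below
    `lr_min`."""

    def __init__(self, lr0: float, factor: float, patience: int,
                 threshold: float, lr_min: float):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.lr_min = lr_min
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, validation_loss: float) -> float:
        if validation_loss < self.best * (1.0 - self.threshold):
            self.best = validation_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr / self.factor, self.lr_min)
                self.bad_epochs = 0
        self.best = min(self.best, validation_loss)
        return self.lr


def _loss_for_sample(model: ReconModel, sample: Sample, w: LossWeights,
                     feat_spec: FeatureExtractorSpec, compute_all: bool = False):
    out = model(sample.drrs.stacked(), sample.pct01.data)
    total, breakdown = alf_total(out, sample.target01.data, sample.drrs,
                                 sample.umask, w, feat_spec, compute_all=compute_all)
    return out, total, breakdown


def train_step(model: ReconModel, opt: nn.AdamW, sample: Sample, w: LossWeights,
               feat_spec: FeatureExtractorSpec) -> tuple[float, dict[str, float]]:
    """One forward/backward/update on a single sample; returns the loss and
    its unweighted component breakdown.  Aborts on a non-finite loss."""
    _, total, breakdown = _loss_for_sample(model, sample, w, feat_spec)
    loss = total.item()
    if not np.isfinite(loss):
        bad = [k for k, v in breakdown.items() if not np.isfinite(v)]
        raise RuntimeError(f"non-finite training loss; offending component(s): {bad}")
    opt.zero_grad()
    total.backward()
    opt.step()
    return loss, breakdown


def _epoch_seed(base_seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([base_seed, epoch]).generate_state(1)[0] % (2**31 - 1))


def train(model: ReconModel, cohort: Cohort, w: LossWeights,
          feat_spec: FeatureExtractorSpec, cfg: TrainConfig,
          prep: PrepSettings = PrepSettings(), out_dir: str | Path | None = None,
          ) -> tuple[CheckpointRecord, list[dict]]:
    """Full training run over the cohort's train split with per-epoch
    validation; returns the best checkpoint and the epoch history."""
    train_cases = cohort.split("train")
    val_cases = cohort.split("val")
    if not train_cases or not val_cases:
        raise ValueError("cohort needs nonempty train and val splits")

    init_weights(model, cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr0, betas=cfg.betas,
                   eps=cfg.eps, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(cfg.lr0, cfg.plateau_factor, cfg.plateau_patience,
                             cfg.plateau_threshold, cfg.lr_min)

    # validation samples are augmentation-free and can be prepared once
    val_samples = [
        prepare_fraction(case, k, prep, augment_params=None)
        for case in val_cases for k in range(len(case.fractions))
    ]
    pairs = [(case, k) for case in train_cases for k in range(len(case.fractions))]

    history: list[dict] = []
    best: CheckpointRecord | None = None
    from .evaluation import metric_report  # local import: avoid cycle at module load

    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(_epoch_seed(cfg.seed, epoch))
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for j in order:
            case, k = pairs[j]
            params = (AugmentParams.sample(rng, prep.max_translation_px,
                                           prep.max_rotation_deg)
                      if prep.augment else None)
            sample = prepare_fraction(case, k, prep, augment_params=params)
            loss, _ = train_step(model, opt, sample, w, feat_spec)
            epoch_losses.append(loss)

        val_losses = []
        val_metrics = []
        for sample in val_samples:
            out, total, _ = _loss_for_sample(model, sample, w, feat_spec)
            val_losses.append(total.item())
            val_metrics.append(metric_report(sample, out.data))
        val_loss = float(np.mean(val_losses))
        lr_used = opt.lr
        opt.lr = sched.step(val_loss)

        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr": lr_used,
            "val_mmae_hu": float(np.mean([m["mmae_hu"] for m in val_metrics])),
            "val_mssim": float(np.mean([m["mssim"] for m in val_metrics])),
        }
        history.append(record)
        if best is None or val_loss < best.validation_loss:
            best = CheckpointRecord(epoch, val_loss, lr_used, model.state_dict(), model.cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "history.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec) + "\n")
        save_checkpoint(best, out / "best.npz")
    return best, history


def save_checkpoint(rec: CheckpointRecord, path: str | Path) -> None:
    from . import __version__

    meta = json.dumps({
        "epoch": rec.epoch,
        "validation_loss": rec.validation_loss,
        "lr": rec.lr,
        "model_config": rec.model_config.to_dict(),
        "package_version": __version__,
    })
    np.savez(str(path), __meta__=np.array(meta), **rec.state)


def load_checkpoint(path: str | Path) -> CheckpointRecord:
    with np.load(str(path), allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    return CheckpointRecord(meta["epoch"], meta["validation_loss"], meta["lr"],
                            state, ModelConfig.from_dict(meta["model_config"]))


def restore_model(rec: CheckpointRecord) -> ReconModel:
    model = ReconModel(rec.model_config)
    model.load_state_dict(rec.state)
    return model


def run_ablation(cohort: Cohort, model_cfg: ModelConfig, cfg: TrainConfig,
                 feat_spec: FeatureExtractorSpec = FeatureExtractorSpec(),
                 prep: PrepSettings = PrepSettings(),
                 out_dir: str | Path | None = None):
    """Retrain the same architecture from identical initial weights under the
    four loss configurations and evaluate each on the test split.

    Returns (models, reports, table): per-configuration best checkpoints,
    per-case metric reports, and a tidy 4-row summary DataFrame.
    """
    import pandas as pd

    from .evaluation import evaluate_cohort

    models: dict[str, CheckpointRecord] = {}
    reports: dict[str, list[dict]] = {}
    rows = []
    for name in ABLATION_WEIGHTS:
        w = LossWeights.preset(name)
        model = build_model(ModelConfig.from_dict(model_cfg.to_dict()))
        sub_dir = Path(out_dir) / name if out_dir is not None else None
        best, history = train(model, cohort, w, feat_spec, cfg, prep, out_dir=sub_dir)
        models[name] = best
        case_reports, summary = evaluate_cohort(restore_model(best), cohort, "test",
                                                prep=prep)
        reports[name] = case_reports
        rows.append({"loss_config": name, **summary})
    table = pd.DataFrame(rows).set_index("loss_config")
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "ablation_summary.csv")
    return models, reports, table
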