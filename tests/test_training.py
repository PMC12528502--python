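"""Training protocol: initialisation, scheduler, bookkeeping, determinism."""

import numpy as np
import pytest

from orthosyn import nn
from orthosyn.losses import FeatureExtractorSpec, LossWeights
from orthosyn.network import ModelConfig, build_model
from orthosyn.pipeline import PrepSettings, Sample
from orthosyn.training import (CheckpointRecord, PlateauScheduler, TrainConfig,
                               init_weights, load_checkpoint, restore_model,
                               save_checkpoint, train, train_step)


def scheduler_oracle(losses, lr0=1e-3, factor=10.0, patience=5, threshold=1e-4, lr_min=1e-6):
    """Straight transcription of the plateau rule, kept independent of the
    implementation under test."""
    lr, best, bad, out = lr0, np.inf, 0, []
    for loss in losses:
        if loss < best * (1 - threshold):
            best, bad = loss, 0
        else:
            bad += 1
            if bad >= patience:
                lr = max(lr / factor, lr_min)
                bad = 0
        best = min(best, loss)
        out.append(lr)
    return out


def run_scheduler(losses, **kw):
    s = PlateauScheduler(kw.get("lr0", 1e-3), kw.get("factor", 10.0),
                         kw.get("patience", 5), kw.get("threshold", 1e-4),
                         kw.get("lr_min", 1e-6))
    return [s.step(loss) for loss in losses]


def test_scheduler_flat_losses_drop_after_patience():
    lrs = run_scheduler([1.0] * 6)
    assert lrs == [1e-3] * 5 + [1e-4]


def test_scheduler_improving_losses_keep_lr():
    lrs = run_scheduler(list(1.0 / np.arange(1, 11)))
    assert lrs == [1e-3] * 10


def test_scheduler_floors_at_minimum_rate():
    lrs = run_scheduler([1.0] * 40)
    assert lrs[-1] == 1e-6
    assert min(lrs) >= 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_scheduler_matches_hand_simulated_oracle(seed):
    rng = np.random.default_rng(seed)
    losses = rng.random(30).tolist()
    if seed % 2:  # interleave plateaus to exercise the decay branch
        losses[5:15] = [losses[5]] * 10
    assert run_scheduler(losses) == scheduler_oracle(losses)


def test_kaiming_uniform_bounds_and_determinism(desk_model_cfg):
    m1 = build_model(desk_model_cfg, seed=4)
    m2 = build_model(desk_model_cfg, seed=4)
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(p1.data, p2.data)
    for mod in m1.modules():
        if isinstance(mod, (nn.Conv2d, nn.Conv3d)):
            bound = np.sqrt(2.0) * np.sqrt(3.0 / mod.fan_in)
            assert np.abs(mod.weight.data).max() <= bound
            assert np.abs(mod.weight.data).max() > 0  # no all-zero layer
    m3 = build_model(desk_model_cfg, seed=5)
    assert not np.array_equal(m1.parameters()[0].data, m3.parameters()[0].data)


def test_adamw_decoupled_weight_decay_shrinks_parameters():
    from orthosyn.grad import Tensor

    p = Tensor(np.full(4, 10.0), requires_grad=True)
    opt = nn.AdamW([p], lr=0.1, weight_decay=0.5)
    p.grad = np.zeros(4)
    opt.step()
    assert np.allclose(p.data, 10.0 - 0.1 * 0.5 * 10.0)


def make_train_ctx(desk_cohort, desk_model_cfg, epochs=3, seed=0):
    model = build_model(desk_model_cfg)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    return model, desk_cohort, LossWeights.preset("MAE&PL"), FeatureExtractorSpec(), cfg


def test_training_history_and_best_checkpoint(desk_cohort, desk_model_cfg, tmp_path):
    model, cohort, w, fs, cfg = make_train_ctx(desk_cohort, desk_model_cfg)
    best, history = train(model, cohort, w, fs, cfg, out_dir=tmp_path)
    assert len(history) == cfg.epochs
    val_losses = [h["val_loss"] for h in history]
    assert best.epoch == int(np.argmin(val_losses))
    assert best.validation_loss == pytest.approx(min(val_losses))
    assert (tmp_path / "history.jsonl").exists()

    rec = load_checkpoint(tmp_path / "best.npz")
    assert rec.validation_loss == pytest.approx(best.validation_loss)
    restored = restore_model(rec)
    for p1, p2 in zip(restored.parameters(), best.state.values()):
        assert np.array_equal(p1.data, p2)


def test_training_is_deterministic(desk_cohort, desk_model_cfg):
    runs = []
    for _ in range(2):
        model, cohort, w, fs, cfg = make_train_ctx(desk_cohort, desk_model_cfg, epochs=2, seed=3)
        _, history = train(model, cohort, w, fs, cfg)
        runs.append(history)
    assert runs[0] == runs[1]


def test_nan_loss_aborts_with_component_name(desk_sample, desk_model_cfg):
    model = build_model(desk_model_cfg, seed=0)
    opt = nn.AdamW(model.parameters())
    bad = Sample(
        case_id=desk_sample.case_id, fraction=0, drrs=desk_sample.drrs,
        pct01=desk_sample.pct01,
        target01=type(desk_sample.target01)(
            np.full_like(desk_sample.target01.data, np.nan),
            desk_sample.target01.spacing_mm, "normalized01",
            norm_bounds=desk_sample.target01.norm_bounds),
        umask=desk_sample.umask, body=desk_sample.body, eval_mask=desk_sample.eval_mask)
    with pytest.raises(RuntimeError, match="mae"):
        train_step(model, opt, bad, LossWeights(1, 0, 0, 0), FeatureExtractorSpec())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=2)
    with pytest.raises(ValueError):
        TrainConfig(lr_min=1.0, lr0=1e-3)
    with pytest.raises(ValueError):
        TrainConfig(plateau_patience=0)
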