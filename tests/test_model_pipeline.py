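"""Model assembly, training loop, evaluation, checkpointing, ablation."""

from dataclasses import replace

import numpy as np
import pytest

from vesseltext.autodiff import Tensor
from vesseltext.errors import ConfigError
from vesseltext.model_pipeline import (Checkpoint, ModelConfig, TrainConfig,
                                       build_model, evaluate, expected_gate_params,
                                       expected_se_params, predict, run_ablation,
                                       train)
from vesseltext.model_pipeline.training import SegDataset, bce_dice_loss


def _count(model, needle):
    return sum(p.size for name, p in model.named_parameters() if needle in name)


# ------------------------------------------------------------ build_model
def test_baseline_has_zero_se_and_gate_params(tiny_model_cfg):
    cfg = replace(tiny_model_cfg, se_placement="none", gating_enabled=False)
    model = build_model(cfg)
    assert _count(model, "se_down") == 0
    assert _count(model, "se_up") == 0
    assert _count(model, "gate_") == 0


@pytest.mark.parametrize("placement", ["down", "up", "all"])
def test_param_count_deltas_match_closed_form(tiny_model_cfg, placement):
    base = replace(tiny_model_cfg, se_placement="none", gating_enabled=False)
    variant = replace(tiny_model_cfg, se_placement=placement, gating_enabled=True)
    delta = build_model(variant).parameter_count() - build_model(base).parameter_count()
    assert delta == expected_se_params(variant) + expected_gate_params(variant)
    assert expected_se_params(base) == expected_gate_params(base) == 0


def test_se_and_gate_param_counts_by_name(tiny_model_cfg):
    cfg = replace(tiny_model_cfg, se_placement="all", gating_enabled=True)
    model = build_model(cfg)
    assert _count(model, "se_down.") + _count(model, "se_up.") == expected_se_params(cfg)
    assert _count(model, "gate_") == expected_gate_params(cfg)


def test_forward_shape_and_range(tiny_model_cfg, rng):
    model = build_model(tiny_model_cfg, seed=2)
    img = Tensor(rng.random((1, 1, 32, 32)))
    text = Tensor(rng.standard_normal((1, 1, tiny_model_cfg.text_dim)))
    out = model(img, text)
    assert out.shape == (1, 1, 32, 32)
    assert (out.data > 0).all() and (out.data < 1).all()


def test_zeroed_se_halves_first_stage(tiny_model_cfg, rng):
    """With SE perceptron weights zeroed (gates 0.5), the first encoder stage
    of the down-placement model outputs exactly half of the none-placement
    model's stage (their conv weights coincide by construction order)."""
    none_m = build_model(replace(tiny_model_cfg, se_placement="none"), seed=5)
    down_m = build_model(replace(tiny_model_cfg, se_placement="down"), seed=5)
    down_m.se_down[0].w1.data[:] = 0.0
    down_m.se_down[0].w2.data[:] = 0.0
    x = Tensor(rng.random((1, 1, 32, 32)))
    ref = none_m.enc[0](x).data
    np.testing.assert_array_equal(none_m.enc[0].c1.weight.data,
                                  down_m.enc[0].c1.weight.data)
    out = down_m.se_down[0](down_m.enc[0](x)).data
    np.testing.assert_allclose(out, 0.5 * ref, atol=1e-12)


def test_config_validation():
    with pytest.raises(ConfigError):
        ModelConfig(input_size=(30, 30))  # not divisible by the factor
    with pytest.raises(ConfigError):
        ModelConfig(se_placement="everywhere")
    with pytest.raises(ConfigError):
        ModelConfig(vit_dim=30, heads=4)
    with pytest.raises(ConfigError):
        TrainConfig(epochs=0)


def test_train_config_defaults():
    tcfg = TrainConfig()
    assert tcfg.epochs == 300 and tcfg.batch_size == 2
    assert tcfg.optimizer == "adam" and tcfg.learning_rate == 0.001


# --------------------------------------------------------------- training
def test_one_epoch_smoke(tiny_model_cfg, tiny_train_set, tiny_train_cfg, tmp_path):
    model = build_model(tiny_model_cfg, seed=3)
    ckpt = train(model, tiny_train_set, tiny_train_cfg,
                 checkpoint_path=tmp_path / "ckpt.npz",
                 log_path=tmp_path / "log.jsonl")
    assert (tmp_path / "ckpt.npz").exists()
    assert np.isfinite(ckpt.history[0]["loss"])
    assert (tmp_path / "log.jsonl").read_text().count("\n") == 1


def test_zero_learning_rate_leaves_weights(tiny_model_cfg, tiny_train_set):
    model = build_model(tiny_model_cfg, seed=3)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    train(model, tiny_train_set, TrainConfig(epochs=1, batch_size=2, seed=0,
                                             learning_rate=0.0))
    after = model.state_dict()
    for k in before:
        np.testing.assert_array_equal(before[k], after[k])


def test_loss_decreases(tiny_model_cfg, tiny_train_set):
    model = build_model(tiny_model_cfg, seed=3)
    ckpt = train(model, tiny_train_set, TrainConfig(epochs=8, batch_size=2, seed=0))
    assert ckpt.history[-1]["loss"] < ckpt.history[0]["loss"]


def test_fixed_seed_reproduces_loss_trajectory(tiny_model_cfg, tiny_train_set):
    losses = []
    for _ in range(2):
        model = build_model(tiny_model_cfg, seed=4)
        ckpt = train(model, tiny_train_set, TrainConfig(epochs=2, batch_size=2, seed=4))
        losses.append([h["loss"] for h in ckpt.history])
    assert losses[0] == losses[1]  # bitwise


def test_nan_loss_aborts(tiny_model_cfg, tiny_train_set):
    model = build_model(tiny_model_cfg, seed=3)
    model.head.weight.data[:] = np.inf
    with pytest.raises(RuntimeError, match="non-finite"):
        train(model, tiny_train_set, TrainConfig(epochs=1, batch_size=2, seed=0))


def test_bce_dice_loss_perfect_prediction_is_small():
    target = np.zeros((1, 1, 4, 4))
    target[0, 0, :2] = 1.0
    probs = Tensor(np.clip(target, 1e-6, 1 - 1e-6))
    assert bce_dice_loss(probs, target).item() < 0.2


# ------------------------------------------------------------- evaluation
def test_overfit_two_samples(tiny_model_cfg, tiny_train_set):
    two = SegDataset(tiny_train_set.samples[:2])
    model = build_model(tiny_model_cfg, seed=6)
    ckpt = train(model, two, TrainConfig(epochs=350, batch_size=2, seed=6,
                                         learning_rate=0.005))
    report = evaluate(ckpt, two)
    assert report["micro"]["f1"] > 0.95


def test_evaluate_deterministic(tiny_model_cfg, tiny_train_set, tiny_test_set,
                                tiny_train_cfg):
    model = build_model(tiny_model_cfg, seed=3)
    ckpt = train(model, tiny_train_set, tiny_train_cfg)
    r1 = evaluate(ckpt, tiny_test_set)
    r2 = evaluate(ckpt, tiny_test_set)
    assert r1 == r2


def test_evaluate_empty_dataset_errors():
    with pytest.raises(ValueError):
        SegDataset([])


def test_checkpoint_round_trip_bitwise(tiny_model_cfg, tiny_train_set, tiny_train_cfg,
                                       tmp_path, rng):
    model = build_model(tiny_model_cfg, seed=7)
    ckpt = train(model, tiny_train_set, tiny_train_cfg)
    path = tmp_path / "model.npz"
    ckpt.save(path)
    back = Checkpoint.load(path)
    assert back.model_config == ckpt.model_config
    assert back.train_config == ckpt.train_config
    img = Tensor(rng.random((1, 1, 32, 32)))
    text = Tensor(rng.standard_normal((1, 1, tiny_model_cfg.text_dim)))
    out1 = ckpt.build()(img, text).data
    out2 = back.build()(img, text).data
    np.testing.assert_array_equal(out1, out2)


def test_training_without_captions(tiny_model_cfg, tiny_dataset_dir, tiny_train_cfg):
    from vesseltext.model_pipeline import load_dataset
    ds = load_dataset(tiny_dataset_dir, "train", tiny_model_cfg,
                      apply_preprocessing=False, drop_captions=True)
    assert all(np.all(s.text == 0) for s in ds)
    model = build_model(tiny_model_cfg, seed=3)
    ckpt = train(model, ds, tiny_train_cfg)
    report = evaluate(ckpt, ds)
    assert 0.0 <= report["micro"]["acc"] <= 1.0


def test_predict_shapes(tiny_model_cfg, tiny_test_set):
    model = build_model(tiny_model_cfg, seed=3)
    probs = predict(model, tiny_test_set)
    assert set(probs) == {s.image_id for s in tiny_test_set}
    for arr in probs.values():
        assert arr.shape == (32, 32)
        assert (arr >= 0).all() and (arr <= 1).all()


# --------------------------------------------------------------- ablation
def test_run_ablation_table(tiny_model_cfg, tiny_train_set, tiny_test_set, tmp_path):
    tcfg = TrainConfig(epochs=1, batch_size=2, seed=2)
    rows = run_ablation(["none", "down"], [True], tiny_model_cfg, tcfg,
                        tiny_train_set, tiny_test_set, out_dir=tmp_path)
    assert len(rows) == 2
    for row in rows:
        for key in ("f1", "acc", "se", "sp"):
            assert row[key] is None or 0.0 <= row[key] <= 1.0
    assert (tmp_path / "ablation.csv").read_text().startswith("model,f1,acc,se,sp")


def test_run_ablation_needs_two_arms(tiny_model_cfg, tiny_train_set, tiny_test_set):
    with pytest.raises(ValueError):
        run_ablation(["none"], [True], tiny_model_cfg,
                     TrainConfig(epochs=1, seed=0), tiny_train_set, tiny_test_set)
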