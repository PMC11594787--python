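"""Training pipeline: defaults, improvement, determinism, checkpoints."""

import numpy as np
import pytest

from lmnet.datagen import load_images
from lmnet.models import build_lmn, tiny_config
from lmnet.nn import Tensor
from lmnet.train import (TrainConfig, evaluate, load_checkpoint, predict,
                         save_checkpoint, soft_cross_entropy, train)


@pytest.fixture(scope="module")
def loaded(request):
    synth = request.getfixturevalue("synth_dataset")
    parts, root = synth
    xt, yt, names = load_images(parts.subset("train"))
    xv, yv, _ = load_images(parts.subset("val"))
    return xt, yt, xv, yv, names


def test_default_config_is_published_recipe():
    cfg = TrainConfig()
    assert cfg.input_size == 224
    assert cfg.batch_size == 64
    assert cfg.epochs == 150
    assert cfg.learning_rate == 0.001
    assert cfg.loss == "cross_entropy"
    assert cfg.optimizer == "adam"


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(mix_method="mosaic")


def test_zero_epochs_leaves_weights_unchanged(loaded):
    xt, yt, xv, yv, _ = loaded
    model = build_lmn(tiny_config(seed=1))
    before = {k: v.copy() for k, v in model.state_dict().items()}
    hist = train(model, xt, yt, xv, yv,
                 TrainConfig(input_size=32, batch_size=16, epochs=0))
    assert hist.train_loss == [] and hist.val_accuracy == []
    after = model.state_dict()
    for k in before:
        np.testing.assert_array_equal(before[k], after[k])


@pytest.mark.parametrize("mix", ["none", "cutmix"])
def test_loss_improves_over_training(loaded, mix):
    xt, yt, xv, yv, _ = loaded
    model = build_lmn(tiny_config(seed=2))
    cfg = TrainConfig(input_size=32, batch_size=16, epochs=4, seed=3,
                      mix_method=mix)
    hist = train(model, xt, yt, xv, yv, cfg)
    assert hist.train_loss[-1] < hist.train_loss[0]
    assert len(hist.train_loss) == len(hist.val_loss) == len(hist.val_accuracy) == 4
    assert 0 <= hist.best_epoch < 4


def test_soft_cross_entropy_matches_hand_value():
    logits = Tensor(np.log(np.array([[0.7, 0.2, 0.1]], dtype=np.float32)))
    soft = np.array([[0.5, 0.5, 0.0]], dtype=np.float32)
    expect = -(0.5 * np.log(0.7) + 0.5 * np.log(0.2))
    assert soft_cross_entropy(logits, soft).item() == pytest.approx(expect, rel=1e-5)


def test_training_is_seed_reproducible(loaded):
    xt, yt, xv, yv, _ = loaded
    hists = []
    for _ in range(2):
        model = build_lmn(tiny_config(seed=4))
        cfg = TrainConfig(input_size=32, batch_size=16, epochs=2, seed=5,
                          mix_method="cutmix")
        hists.append(train(model, xt, yt, xv, yv, cfg))
    assert hists[0].train_loss == hists[1].train_loss
    assert hists[0].val_accuracy == hists[1].val_accuracy


def test_evaluate_consistency_and_determinism(loaded):
    xt, yt, xv, yv, names = loaded
    model = build_lmn(tiny_config(seed=6))
    rep1 = evaluate(model, xv, yv, names)
    rep2 = evaluate(model, xv, yv, names)
    assert rep1.accuracy == pytest.approx(
        np.trace(rep1.confusion.counts) / rep1.confusion.total)
    assert rep1.to_dict() == rep2.to_dict()


def test_model_memorises_single_batch(loaded):
    """Overfitting one tiny batch drives accuracy on that batch to 1."""
    xt, yt, *_ = loaded
    x, y = xt[:8], yt[:8]
    model = build_lmn(tiny_config(seed=7))
    train(model, x, y, x, y, TrainConfig(input_size=32, batch_size=8,
                                         epochs=25, seed=0))
    assert evaluate(model, x, y).accuracy == 1.0


def test_predict_ranks_and_normalises(loaded):
    xt, *_ , names = loaded
    model = build_lmn(tiny_config(seed=8))
    ranking = predict(model, xt[0], names)
    probs = [p for _, p in ranking]
    assert abs(sum(probs) - 1) < 1e-6
    assert probs == sorted(probs, reverse=True)
    # zero-weight head -> exactly uniform probabilities
    model.head.weight.data[...] = 0
    model.head.bias.data[...] = 0
    uniform = predict(model, xt[0], names)
    assert all(abs(p - 1 / len(names)) < 1e-6 for _, p in uniform)
    with pytest.raises(ValueError):
        predict(model, xt[:2])


def test_predict_agrees_with_evaluate_argmax(loaded):
    xt, yt, *_ , names = loaded
    model = build_lmn(tiny_config(seed=9))
    rep = evaluate(model, xt[:4], yt[:4], names)
    for i in range(4):
        top1 = predict(model, xt[i], names)[0][0]
        logits = model(Tensor(xt[i:i + 1])).data
        assert top1 == names[int(logits.argmax())]


def test_checkpoint_round_trip(tmp_path, loaded):
    xt, yt, xv, yv, names = loaded
    model = build_lmn(tiny_config(seed=10))
    cfg = TrainConfig(input_size=32, batch_size=16, epochs=1, seed=1)
    train(model, xt, yt, xv, yv, cfg, checkpoint_path=tmp_path / "m.ckpt")
    loaded_model, meta = load_checkpoint(tmp_path / "m.ckpt")
    x = Tensor(xt[:2])
    model.eval(), loaded_model.eval()
    np.testing.assert_array_equal(model(x).data, loaded_model(x).data)
    assert meta["train_config"]["epochs"] == 1
    assert meta["model_config"]["stage_types"] == "RRSS"


def test_label_head_mismatch_raises(loaded):
    xt, yt, xv, yv, _ = loaded
    model = build_lmn(tiny_config(num_classes=2))
    with pytest.raises(ValueError):
        train(model, xt, yt, xv, yv, TrainConfig(input_size=32, epochs=1))
    with pytest.raises(ValueError):
        train(model, xt[:0], yt[:0], xv, yv, TrainConfig(epochs=1))


def test_selection_protocol_end_to_end_replay(loaded):
    """Protocol accuracies equal re-running each arm independently."""
    from lmnet.augment import select_augmentation
    xt, yt, xv, yv, names = loaded

    def run_arm(method):
        model = build_lmn(tiny_config(num_classes=len(names), seed=11))
        cfg = TrainConfig(input_size=32, batch_size=16, epochs=2, seed=12,
                          mix_method=method)
        train(model, xt, yt, xv, yv, cfg)
        return evaluate(model, xv, yv, names).accuracy

    report = select_augmentation("cutmix", "mixup", run_arm)
    assert report.chosen in ("cutmix", "mixup")
    for method in ("cutmix", "mixup"):
        assert report.accuracies[method] == run_arm(method)
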