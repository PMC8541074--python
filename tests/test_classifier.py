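"""Classifier architecture, data splitting, and training protocol."""

import time

import numpy as np
import pytest

from conftest import two_class_run
from silentspeech import (
    Epoch, ModelConfig, TrainConfig, build_model, split_dataset, tensorize_epochs,
)
from silentspeech.classifier import load_model, prepare_inputs, save_model
from silentspeech.epoching import EpochSet
from silentspeech.tensorize import InputTensor


def _fake_tensors(n_per_class: int, classes=("forward", "stop"), n_subjects=1, seed=0):
    rng = np.random.default_rng(seed)
    tensors = []
    eid = 0
    for label in classes:
        for i in range(n_per_class):
            subj = f"s{i % n_subjects:02d}"
            for tag in ("Sample01", "Sample02"):
                tensors.append(InputTensor(
                    data=rng.standard_normal((256, 256)), label=label,
                    subject_id=subj, session_id="sess00", sample_tag=tag,
                    epoch_id=eid, row_map=[("all", 0, 256)],
                ))
            eid += 1
    return tensors


def test_fc_input_is_512_for_full_size_config():
    cfg = ModelConfig(gru_hidden=1024, pool_width=2)
    assert cfg.fc_input == 512
    assert cfg.input_size == 256


def test_indivisible_pooling_rejected():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(gru_hidden=1023, pool_width=2)


def test_lite_forward_gives_normalized_probabilities():
    model = build_model(ModelConfig.lite(n_classes=9), seed=0)
    x = np.random.default_rng(0).standard_normal((3, 1, 64, 64))
    p = model.predict_proba(x)
    assert p.shape == (3, 9)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p >= 0)


def test_lite_single_forward_is_fast():
    model = build_model(ModelConfig.lite(n_classes=2), seed=0)
    x = np.zeros((1, 1, 64, 64))
    model.predict_proba(x)  # warm-up
    t0 = time.perf_counter()
    model.predict_proba(x)
    assert time.perf_counter() - t0 < 0.05


def test_softmax_normalization_for_arbitrary_logit_scale():
    from silentspeech.nn.autograd import softmax

    z = np.array([[1e4, -1e4, 0.0], [3.0, 3.0, 3.0]])
    p = softmax(z)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_split_fractions_and_pairing():
    tensors = _fake_tensors(225)  # 450 epochs -> 900 tensors
    splits = split_dataset(tensors, TrainConfig(seed=1))
    assert abs(len(splits.train) - 630) <= 2
    assert abs(len(splits.val) - 180) <= 2
    assert abs(len(splits.test) - 90) <= 2
    # leakage guard: both samples of an epoch share a partition
    for part in (splits.train, splits.val, splits.test):
        keys = {(t.subject_id, t.session_id, t.epoch_id) for t in part}
        assert len(part) == 2 * len(keys)


def test_split_preserves_class_proportions():
    tensors = _fake_tensors(100) + _fake_tensors(100, classes=("up",), seed=1)
    for seed in range(3):
        splits = split_dataset(tensors, TrainConfig(seed=seed))
        for part in ("train", "val", "test"):
            ts = getattr(splits, part)
            frac = np.mean([t.label == "up" for t in ts])
            assert abs(frac - 1 / 3) < 0.02


def test_out_of_sample_subjects_fully_held_out():
    tensors = _fake_tensors(30, n_subjects=3)
    cfg = TrainConfig(out_of_sample_subjects=("s01",), seed=0)
    splits = split_dataset(tensors, cfg)
    assert all(t.subject_id == "s01" for t in splits.out_of_sample)
    for part in (splits.train, splits.val, splits.test):
        assert all(t.subject_id != "s01" for t in part)


def test_prepare_inputs_strides_and_standardizes():
    tensors = _fake_tensors(2)
    x, y = prepare_inputs(tensors, 64, ["forward", "stop"])
    assert x.shape == (8, 1, 64, 64)
    assert np.allclose(x.mean(axis=(2, 3)), 0.0, atol=1e-8)
    assert set(y) == {0, 1}


def test_training_loss_decreases_on_separable_data():
    _, history = two_class_run(4.0)
    first = history.train_loss.iloc[:20].mean()
    last = history.train_loss.iloc[-20:].mean()
    assert last < first


def test_validation_accuracy_nondecreasing_over_windows():
    """On separable data the accuracy trend over training is upward."""
    _, history = two_class_run(4.0)
    accs = history.val_accuracy.dropna().to_numpy()
    assert accs[-1] >= accs[0]
    assert accs[len(accs) // 2:].mean() >= accs[:len(accs) // 2].mean()


def test_accuracy_increases_with_class_effect():
    """Stronger oscillatory signatures → better downstream classification.

    Checked at three effect levels on fixed seeds; the validation partition
    (the largest held-out one) measures generalization, with a small slack
    for its sampling noise.
    """
    def val_accuracy(effect):
        report, _ = two_class_run(effect)
        return report.accuracy["val"]

    a0, a1, a2 = (val_accuracy(e) for e in (0.0, 2.5, 4.0))
    assert a0 + 10 < a2
    assert a0 <= a1 + 5
    assert a1 <= a2 + 5


def test_evaluation_reports_all_partitions_and_consistent_confusion():
    report, _ = two_class_run(4.0)
    for part in ("train", "val", "test"):
        assert 0.0 <= report.accuracy[part] <= 100.0
        assert report.loss[part] >= 0.0
    assert report.accuracy["out_of_sample"] is None
    assert report.confusion.sum() > 0
    assert report.confusion.shape == (2, 2)


def test_model_save_load_round_trip(tmp_path):
    model = build_model(ModelConfig.lite(n_classes=2), seed=3)
    x = np.random.default_rng(1).standard_normal((2, 1, 64, 64))
    p1 = model.predict_proba(x)
    path = tmp_path / "model.npz"
    save_model(model, path)
    p2 = load_model(path).predict_proba(x)
    assert np.allclose(p1, p2)


def test_training_is_deterministic_given_seeds():
    rng = np.random.default_rng(0)
    epochs = [Epoch(rng.normal(size=(40, 2048)), "forward" if i % 2 else "stop",
                    "s00", "sess00") for i in range(24)]
    tensors = tensorize_epochs(EpochSet(epochs=epochs))
    tcfg = TrainConfig(max_iter=10, seed=5)
    from silentspeech import evaluate, train

    accs = []
    for _ in range(2):
        splits = split_dataset(tensors, tcfg)
        model = build_model(ModelConfig.lite(n_classes=2), seed=7)
        model, hist = train(model, splits, tcfg)
        accs.append((hist.train_loss.to_numpy(), evaluate(model, splits).accuracy["train"]))
    assert np.array_equal(accs[0][0], accs[1][0])
    assert accs[0][1] == accs[1][1]
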