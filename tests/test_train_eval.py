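"""Training loop, metrics and the ablation runner."""

import numpy as np
import pytest

from mscfp.backbone import BackboneConfig
from mscfp.data import TEST, TRAIN, LabeledImageSet
from mscfp.model import ModelConfig, MSCFPNet
from mscfp.preprocess import split_dataset
from mscfp.synthetic import GeneratorConfig, generate_image_set
from mscfp.train import (ABLATION_TOGGLES, compute_metrics, evaluate,
                         normalize_images, run_ablation, train)


def tiny_cfg(**kw):
    """Smallest legal architecture (32x32 inputs) for loop-mechanics tests."""
    defaults = dict(backbone=BackboneConfig(depths=(1, 1, 1, 1),
                                            widths=(4, 8, 8, 8, 8),
                                            cardinality=2, bottleneck_width=2),
                    bifpn_width=8, ca_reduction=4, input_size=32)
    defaults.update(kw)
    return ModelConfig(**defaults)


def tiny_data(n_per_class=4, seed=0):
    cfg = GeneratorConfig.easy(n_per_class=n_per_class, image_size=32,
                               seed=seed)
    return split_dataset(generate_image_set(cfg), ratio=0.75, seed=seed)


def test_zero_learning_rate_leaves_parameters_unchanged():
    data = tiny_data()
    result = train(tiny_cfg(), data, epochs=1, seed=3, lr=0.0,
                   weight_decay=0.0)
    fresh = MSCFPNet(tiny_cfg(), seed=3, dtype=np.float32)
    for (name, p), (_, q) in zip(result.model.named_params(),
                                 fresh.named_params()):
        assert p.data.tobytes() == q.data.tobytes(), name


def test_training_is_deterministic_given_seed():
    data = tiny_data()
    r1 = train(tiny_cfg(), data, epochs=2, seed=11)
    r2 = train(tiny_cfg(), data, epochs=2, seed=11)
    assert r1.history.equals(r2.history)
    e1 = evaluate(r1.model, data)
    e2 = evaluate(r2.model, data)
    assert e1.to_dict() == e2.to_dict()


def test_empty_split_rejected():
    data = tiny_data()
    all_train = LabeledImageSet(images=data.images, labels=data.labels,
                                split=[TRAIN] * len(data))
    with pytest.raises(ValueError, match="empty test"):
        evaluate(MSCFPNet(tiny_cfg(), dtype=np.float32), all_train)
    all_test = LabeledImageSet(images=data.images, labels=data.labels,
                               split=[TEST] * len(data))
    with pytest.raises(ValueError, match="empty train"):
        train(tiny_cfg(), all_test, epochs=1)


def test_perfect_predictions_give_all_hundreds():
    y = np.array([0, 1, 2, 3] * 5)
    rep = compute_metrics(y, y.copy())
    assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 100.0
    assert np.trace(rep.confusion) == 20


def test_degenerate_class_f1_is_zero_by_convention():
    # class 1 never predicted and never present among predictions
    y_true = np.array([0, 0, 0, 0, 1])
    y_pred = np.array([0, 0, 0, 0, 0])
    rep = compute_metrics(y_true, y_pred, n_classes=2)
    assert rep.per_class["slight"]["f1"] == 0.0
    assert rep.per_class["slight"]["recall"] == 0.0


def test_metrics_match_hand_computed_confusion():
    """Macro metrics on a fixed 4x4 confusion equal direct formula values."""
    y_true = np.repeat([0, 1, 2, 3], [10, 10, 10, 10])
    y_pred = np.concatenate([
        [0] * 8 + [1] * 2,          # class 0: 8 right, 2 -> 1
        [1] * 7 + [2] * 3,          # class 1
        [2] * 10,                   # class 2
        [3] * 9 + [0],              # class 3
    ])
    rep = compute_metrics(y_true, y_pred)
    cm = rep.confusion
    assert cm.sum() == 40 and np.trace(cm) == 34
    # brute force over the cells
    precisions, recalls, f1s = [], [], []
    for k in range(4):
        tp = cm[k, k]
        p = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
        r = tp / cm[k, :].sum()
        precisions.append(p)
        recalls.append(r)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    assert np.isclose(rep.accuracy, 100 * 34 / 40)
    assert np.isclose(rep.precision, 100 * np.mean(precisions))
    assert np.isclose(rep.recall, 100 * np.mean(recalls))
    assert np.isclose(rep.f1, 100 * np.mean(f1s))
    # row sums are the per-class test counts; identities on ranges
    np.testing.assert_array_equal(cm.sum(axis=1), [10] * 4)
    assert rep.f1 <= max(pc["f1"] for pc in rep.per_class.values())
    for v in (rep.accuracy, rep.precision, rep.recall, rep.f1):
        assert 0.0 <= v <= 100.0


def test_normalize_images_range():
    imgs = [np.array([[1.0, 3.0], [5.0, 9.0]]), np.zeros((2, 2))]
    x = normalize_images(imgs)
    assert x.shape == (2, 1, 2, 2)
    assert x[0].min() == 0.0 and x[0].max() == 1.0
    assert np.all(x[1] == 0.0)  # constant image maps to zero


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_nonfinite_loss_aborts():
    data = tiny_data()
    # the abort can surface either as the loss diagnostic or as a module
    # refusing non-finite parameters, depending on where divergence bites
    with pytest.raises((RuntimeError, ValueError), match="non-finite"):
        train(tiny_cfg(), data, epochs=40, seed=0, lr=1e6)


def test_ablation_grid_shape_and_baseline_equivalence():
    """8 toggle rows; the all-off row's architecture equals the standalone
    plain backbone + head build, parameter for parameter."""
    data = tiny_data(n_per_class=3)
    table = run_ablation(tiny_cfg(), data, seed=0, epochs=1)
    assert len(table) == 8
    assert len(table[["mcfem", "ca", "bifpn"]].drop_duplicates()) == 8
    assert set(table.columns) >= {"group", "accuracy", "precision", "recall",
                                  "f1"}
    off = tiny_cfg().with_toggles(False, False, False)
    baseline = MSCFPNet(off, seed=0)
    plain = MSCFPNet(tiny_cfg(mcfem_enabled=False, ca_enabled=False,
                              bifpn_enabled=False), seed=0)
    assert baseline.n_params() == plain.n_params()
    assert [n for n, _ in baseline.named_params()] == \
        [n for n, _ in plain.named_params()]


def test_ablation_rejects_duplicates():
    data = tiny_data(n_per_class=2)
    with pytest.raises(ValueError, match="duplicate"):
        run_ablation(tiny_cfg(), data, toggles=[(True, True, True)] * 2,
                     epochs=1)


def test_all_off_matches_plain_backbone_head_param_count():
    cfg = tiny_cfg().with_toggles(False, False, False)
    net = MSCFPNet(cfg, seed=0)
    from mscfp.backbone import ResNeXtBackbone
    from mscfp.bifpn import ClassifierHead
    bb = ResNeXtBackbone(cfg.backbone)
    head = ClassifierHead(cfg.backbone.widths[-1], 4)
    assert net.n_params() == bb.n_params() + head.n_params()
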