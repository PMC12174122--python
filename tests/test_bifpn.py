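"""Bi-FPN: harmonization, weighted fusion nodes, head, end-to-end wiring."""

import numpy as np
import pytest

from mscfp.bifpn import (BiFpnLayer, ClassifierHead, FusionNode, Harmonize,
                         PyramidFeatures)
from mscfp.model import BackboneConfig, ModelConfig, MSCFPNet
from mscfp.nn import cross_entropy


def make_levels(rng, widths=(3, 5, 7, 9, 11), sizes=(16, 8, 4, 2, 1), n=2):
    return [rng.standard_normal((n, c, s, s)) for c, s in zip(widths, sizes)]


def test_harmonize_common_width_preserves_resolution(rng):
    h = Harmonize([64, 256, 512, 1024, 2048], width=160, rng=rng)
    feats = [rng.standard_normal((1, c, s, s)) for c, s in
             zip([64, 256, 512, 1024, 2048], [32, 16, 8, 4, 2])]
    p = h.forward(feats)
    assert len(p) == 5
    for lv, f in zip(p.levels, feats):
        assert lv.shape[1] == 160
        assert lv.shape[2:] == f.shape[2:]


def test_harmonize_identity_projection_passthrough(rng):
    h = Harmonize([6, 8], width=6, rng=rng)
    h.projs[0][0].weight.data[...] = np.eye(6)[:, :, None, None]
    for layer in h.projs[0]:
        layer.training = False  # batch norm at fresh running stats ~ identity
    x = [rng.standard_normal((1, 6, 8, 8)), rng.standard_normal((1, 8, 4, 4))]
    p = h.forward(x)
    np.testing.assert_allclose(p.levels[0], x[0], rtol=1e-5, atol=1e-6)


def test_harmonize_rejects_wrong_level_count(rng):
    h = Harmonize([4, 4], width=4, rng=rng)
    with pytest.raises(ValueError, match="expected 2"):
        h.forward([np.zeros((1, 4, 8, 8))])


def test_pyramid_invariants():
    with pytest.raises(ValueError, match="strictly decrease"):
        PyramidFeatures(levels=[np.zeros((1, 4, 4, 4)),
                                np.zeros((1, 4, 4, 4))], width=4)
    with pytest.raises(ValueError, match="same width"):
        PyramidFeatures(levels=[np.zeros((1, 4, 8, 8)),
                                np.zeros((1, 5, 4, 4))], width=4)


def test_fusion_node_weights_normalized_nonnegative(rng):
    node = FusionNode(3, width=4, rng=rng)
    node.fusion_raw.data[:] = [0.2, 1.7, 0.4]
    w = node.normalized_weights()
    assert np.all(w >= 0)
    assert np.isclose(w.sum(), 1.0, atol=1e-3)  # eps-regularized
    node.fusion_raw.data[:] = [1.0, -5.0, 1.0]  # negative clipped to zero
    w = node.normalized_weights()
    assert w[1] == 0.0


def test_equal_weight_fusion_is_mean_of_inputs(rng):
    """With equal weights and no post-conv, a node is the arithmetic mean of
    its (resized) inputs — checked against hand arithmetic on 4x4/2x2 toys."""
    layer = BiFpnLayer(1, n_levels=2, post_conv=False, rng=rng)
    a = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
    b = np.array([[[[8.0, 2.0], [4.0, 6.0]]]])
    p = layer.forward(PyramidFeatures(levels=[a, b], width=1))
    up_b = np.repeat(np.repeat(b, 2, axis=2), 2, axis=3)
    want_td0 = (a + up_b) / (2 + 1e-4)           # eps in the normalizer
    np.testing.assert_allclose(p.levels[0], want_td0, rtol=1e-6)
    # deepest output node: maxpool3x3/s2 of td0 fused with b
    from mscfp.nn import MaxPool2d
    down = MaxPool2d(3, 2, 1).forward(want_td0)
    want_out1 = (b + down) / (2 + 1e-4)
    np.testing.assert_allclose(p.levels[1], want_out1, rtol=1e-6)


def test_zero_pyramid_stays_zero_bias_free(rng):
    layer = BiFpnLayer(3, post_conv=False, rng=rng)
    levels = [np.zeros((1, 3, s, s)) for s in (16, 8, 4, 2, 1)]
    out = layer.forward(PyramidFeatures(levels=levels, width=3))
    for lv in out.levels:
        assert np.all(lv == 0.0)


def test_layer_preserves_shapes_five_levels(rng):
    layer = BiFpnLayer(6, rng=rng)
    levels = make_levels(rng, widths=[6] * 5)
    p = PyramidFeatures(levels=levels, width=6)
    out = layer.forward(p)
    for got, lv in zip(out.levels, levels):
        assert got.shape == lv.shape


def test_resolution_mismatch_rejected(rng):
    node = FusionNode(2, width=3, rng=rng)
    with pytest.raises(ValueError, match="resolution mismatch"):
        node.forward([np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 2, 2))])


def test_head_gap_matches_double_loop(rng):
    head = ClassifierHead(3, n_classes=4, rng=rng)
    x = rng.standard_normal((2, 3, 5, 7))
    gap = head.gap.forward(x)
    for n in range(2):
        for c in range(3):
            want = sum(x[n, c, i, j] for i in range(5) for j in range(7)) / 35
            assert abs(gap[n, c] - want) < 1e-12


def test_head_logit_length_and_linearity(rng):
    head = ClassifierHead(4, n_classes=4, head_level="deepest", rng=rng)
    levels = [np.full((1, 4, 4, 4), 1.0), np.full((1, 4, 2, 2), 2.0)]
    p = PyramidFeatures(levels=levels, width=4)
    out1 = head.forward(p)
    assert out1.shape == (1, 4)
    # GAP of a constant map is the constant: logits linear in the level value
    levels2 = [np.full((1, 4, 4, 4), 1.0), np.full((1, 4, 2, 2), 6.0)]
    out3 = head.forward(PyramidFeatures(levels=levels2, width=4))
    b = head.fc.bias.data
    np.testing.assert_allclose(out3 - b, 3 * (out1 - b), rtol=1e-9)


def test_head_level_selection(rng):
    deep = ClassifierHead(2, head_level="deepest", rng=rng)
    high = ClassifierHead(2, head_level="highest", rng=rng)
    high.fc.weight.data = deep.fc.weight.data.copy()
    high.fc.bias.data = deep.fc.bias.data.copy()
    levels = [np.full((1, 2, 4, 4), 5.0), np.full((1, 2, 2, 2), -3.0)]
    p = PyramidFeatures(levels=levels, width=2)
    assert not np.allclose(deep.forward(p), high.forward(p))


def test_end_to_end_forward_and_gradient_flow(rng):
    """Full assembled network on a 180x180 THz slice: finite 4-logit output,
    and a backward pass reaches every functional parameter group."""
    cfg = ModelConfig(backbone=BackboneConfig(depths=(1, 1, 1, 1),
                                              widths=(8, 16, 16, 16, 16),
                                              cardinality=4,
                                              bottleneck_width=2),
                      bifpn_width=8, ca_reduction=4, input_size=180)
    net = MSCFPNet(cfg, seed=0)
    x = rng.standard_normal((2, 1, 180, 180))
    logits = net.forward(x)
    assert logits.shape == (2, 4)
    assert np.all(np.isfinite(logits))
    loss, dl = cross_entropy(logits, np.array([0, 3]))
    net.zero_grad()
    net.backward(dl)
    for name, p in net.named_params():
        if name.endswith("beta"):
            # shift params feeding a downstream normalization can cancel
            continue
        assert np.linalg.norm(p.grad) > 0, f"no gradient reached {name}"


def test_fusion_weights_stay_normalized_during_training(rng):
    from mscfp.nn import SGD
    levels = [rng.standard_normal((1, 3, s, s)) for s in (8, 4, 2, 1)]
    layer4 = BiFpnLayer(3, n_levels=4, rng=rng)
    opt = SGD(layer4.params(), lr=0.05)
    p = PyramidFeatures(levels=levels, width=3)
    for _ in range(4):
        out = layer4.forward(p)
        layer4.zero_grad()
        layer4.backward([lv.copy() for lv in out.levels])
        opt.step()
        for node in layer4.td_nodes + layer4.out_nodes:
            w = node.normalized_weights()
            assert np.all(w >= 0)
            assert w.sum() <= 1.0 + 1e-6
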