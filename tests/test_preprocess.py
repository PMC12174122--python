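"""Preprocessing chain: DFT vs naive oracle, slicing, masking, splitting."""

import numpy as np
import pytest

from mscfp.data import TEST, TRAIN, LabeledImageSet, THzVolume
from mscfp.preprocess import (remove_background, select_frequency_slice,
                              split_dataset, time_to_frequency)
from mscfp.synthetic import GeneratorConfig, generate_image_set, \
    generate_volume, sample_fields


def make_volume(data, window=90.0):
    t = np.arange(data.shape[2]) * (window / data.shape[2])
    return THzVolume(data=data, time_axis=t)


def test_fft_matches_naive_dft_on_toy_volume(rng):
    """8x8x64 volume: rfft magnitudes equal an O(T^2) DFT to 1e-8 relative."""
    data = rng.standard_normal((8, 8, 64))
    sv = time_to_frequency(make_volume(data), n_keep=33)
    t_len = 64
    dft = np.exp(-2j * np.pi * np.outer(np.arange(t_len), np.arange(t_len))
                 / t_len)
    want = np.abs(np.einsum("hwt,tk->hwk", data, dft)[:, :, :33])
    np.testing.assert_allclose(sv.data, want, rtol=1e-8, atol=1e-10)


def test_parseval_energy_identity(rng):
    """Sum of |X_k|^2 over the full spectrum equals T * trace energy."""
    t_len = 128
    data = rng.standard_normal((3, 3, t_len))
    sv = time_to_frequency(make_volume(data), n_keep=t_len // 2 + 1)
    mag2 = sv.data ** 2
    # reassemble the two-sided sum from the one-sided magnitudes (even T)
    total = mag2[:, :, 0] + 2 * mag2[:, :, 1:-1].sum(axis=2) + mag2[:, :, -1]
    energy = (data ** 2).sum(axis=2)
    np.testing.assert_allclose(total, t_len * energy, rtol=1e-6)


def test_pure_cosine_hits_single_bin():
    t_len, k = 256, 20
    t = np.arange(t_len)
    trace = np.cos(2 * np.pi * k * t / t_len)
    data = np.broadcast_to(trace, (2, 2, t_len)).copy()
    sv = time_to_frequency(make_volume(data), n_keep=64)
    mags = sv.data[0, 0]
    assert np.argmax(mags) == k
    np.testing.assert_allclose(mags[k], t_len / 2, rtol=1e-9)
    others = np.delete(mags, k)
    assert np.all(others < 1e-8 * mags[k])


def test_default_shapes_match_instrument_geometry():
    """180x180x9000 volume -> 180x180x300 spectral cube -> 300 slices."""
    cfg = GeneratorConfig(n_per_class=1, image_size=180, n_time=9000,
                          noise_sigma=0.0, seed=0)
    vol = generate_volume(cfg, "normal", 0)
    assert vol.shape == (180, 180, 9000)
    sv = time_to_frequency(vol)
    assert sv.shape == (180, 180, 300)
    slices = [select_frequency_slice(sv, f) for f in sv.freq_axis]
    assert len(slices) == 300
    assert all(s.shape == (180, 180) for s in slices)


def test_zero_trace_zero_spectrum():
    data = np.zeros((2, 2, 64))
    sv = time_to_frequency(make_volume(data), n_keep=16)
    assert np.all(sv.data == 0)


def test_slice_selection_bin_arithmetic():
    # default axis: delta_f = 1/90 ps ~ 0.0111 THz -> 0.3 THz is bin 27
    data = np.zeros((2, 2, 800))
    sv = time_to_frequency(make_volume(data, window=90.0), n_keep=300)
    k = int(np.argmin(np.abs(sv.freq_axis - 0.3)))
    assert k == 27 == round(0.3 * 90)
    sv.data[:, :, 27] = 5.0
    np.testing.assert_array_equal(select_frequency_slice(sv, 0.3), 5.0)
    # exact bin center maps to itself
    np.testing.assert_array_equal(
        select_frequency_slice(sv, sv.freq_axis[27]), 5.0)
    with pytest.raises(ValueError, match="outside"):
        select_frequency_slice(sv, 99.0)


def test_n_keep_larger_than_available_bins_rejected():
    data = np.zeros((2, 2, 64))
    with pytest.raises(ValueError, match="exceeds"):
        time_to_frequency(make_volume(data), n_keep=64)


def test_background_removal_recovers_generator_ellipse():
    cfg = GeneratorConfig(n_per_class=1, image_size=96, noise_sigma=0.0, seed=5)
    amp, truth = sample_fields(cfg, "normal", 0)
    masked, mask = remove_background(amp)
    np.testing.assert_array_equal(mask, truth)
    assert np.all(masked[~mask] == 0)


def test_background_removal_shift_equivariant(rng):
    cfg = GeneratorConfig(n_per_class=1, image_size=64, noise_sigma=0.02, seed=2)
    amp, _ = sample_fields(cfg, "moderate", 0)
    img = amp + rng.normal(0, 0.02, amp.shape)
    _, m0 = remove_background(img)
    _, m1 = remove_background(img + 3.7)
    assert m0.sum() == m1.sum()
    np.testing.assert_array_equal(m0, m1)


def test_constant_image_yields_empty_mask():
    masked, mask = remove_background(np.zeros((32, 32)))
    assert mask.sum() == 0
    masked, mask = remove_background(np.full((32, 32), 2.5))
    assert mask.sum() == 0


def test_split_nine_to_one_counts():
    cfg = GeneratorConfig(n_per_class=300, image_size=32, seed=0)
    split = split_dataset(generate_image_set(cfg), ratio=0.9, seed=4)
    tags = np.array(split.split)
    assert (tags == TRAIN).sum() == 1080
    assert (tags == TEST).sum() == 120
    for cid in range(4):
        cls_tags = tags[split.labels == cid]
        assert (cls_tags == TRAIN).sum() == 270


def test_split_is_deterministic_partition():
    cfg = GeneratorConfig(n_per_class=20, image_size=32, seed=1)
    base = generate_image_set(cfg)
    a = split_dataset(base, ratio=0.8, seed=9)
    b = split_dataset(base, ratio=0.8, seed=9)
    assert a.split == b.split
    assert set(a.split) == {TRAIN, TEST}
    assert len(a.subset(TRAIN)) + len(a.subset(TEST)) == len(base)
    c = split_dataset(base, ratio=0.8, seed=10)
    assert c.split != a.split


def test_split_ratio_validation():
    cfg = GeneratorConfig(n_per_class=2, image_size=32)
    base = generate_image_set(cfg)
    for bad in (0.0, 1.0, -0.5):
        with pytest.raises(ValueError, match="ratio"):
            split_dataset(base, ratio=bad)
    few = LabeledImageSet(images=base.images[:4], labels=base.labels[:4])
    with pytest.raises(ValueError, match="without images"):
        split_dataset(few, ratio=0.5)
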