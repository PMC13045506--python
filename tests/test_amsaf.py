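"""Invariants of the multi-scale attention fusion pipeline."""

import numpy as np
import pytest

from conftest import make_pyramid
from wheatstage.amsaf import (
    AMSAF,
    AmsafConfig,
    ChannelAttention,
    GlobalContext,
    ScaleAlign,
    SpatialAttention,
    WFA,
)
from wheatstage.backbone import FeaturePyramid
from wheatstage.nn import Tensor, no_grad

TINY = (32, 64, 128, 256)


@pytest.fixture(scope="module")
def amsaf_tiny():
    """Fusion module for tiny 64x64-input pyramids (2x2 deepest level)."""
    return AMSAF(TINY, (2, 2), seed=0).eval()


def zero_pyramid(batch=1, hw=64):
    feats = [Tensor(np.zeros((batch, c, hw // s, hw // s), dtype=np.float32))
             for c, s in zip(TINY, (4, 8, 16, 32))]
    return FeaturePyramid(*feats)


# -- alignment -----------------------------------------------------------------

def test_align_unifies_all_levels_to_deepest_shape(amsaf_tiny, rng):
    pyr = make_pyramid(2, "tiny", 64, rng)
    with no_grad():
        aligned = amsaf_tiny.align(pyr)
    assert all(t.shape == (2, 256, 2, 2) for t in aligned)


def test_align_of_zero_pyramid_is_constant_per_channel(amsaf_tiny):
    with no_grad():
        aligned = amsaf_tiny.align(zero_pyramid())
    for t, proj in zip(aligned, amsaf_tiny.align.projs):
        expected = np.maximum(proj.bias.data, 0.0)  # ReLU(bias) broadcast
        assert np.allclose(t.data, expected[None, :, None, None], atol=1e-7)


def test_reference_align_shapes(reference_model, rng):
    pyr = make_pyramid(1, "reference", 256, rng)
    with no_grad():
        aligned = reference_model.fusion.align(pyr)
    assert all(t.shape == (1, 2048, 8, 8) for t in aligned)


# -- global context ------------------------------------------------------------

def test_global_context_shape_and_bias_only_on_zeros(amsaf_tiny):
    with no_grad():
        aligned = [Tensor(np.zeros((1, 256, 2, 2), dtype=np.float32))] * 4
        g = amsaf_tiny.global_context(aligned)
    expected = np.maximum(amsaf_tiny.global_context.fuse.bias.data, 0.0)
    assert g.shape == (1, 256, 2, 2)
    assert np.allclose(g.data, expected[None, :, None, None], atol=1e-7)


def test_global_context_averaging_weights_reproduce_identical_input(rng):
    """With the 1x1 fusion conv set to average the four concat blocks, four
    identical nonnegative maps pass through unchanged."""
    c = 16
    gc = GlobalContext(c, seed=0)
    w = np.zeros((c, 4 * c, 1, 1), dtype=np.float32)
    for blk in range(4):
        w[np.arange(c), blk * c + np.arange(c)] = 0.25
    gc.fuse.weight.data = w
    gc.fuse.bias.data[:] = 0.0
    x = Tensor(rng.random((2, c, 3, 3), dtype=np.float32))
    with no_grad():
        out = gc([x, x, x, x])
    assert np.allclose(out.data, x.data, atol=1e-6)


# -- attention gates -----------------------------------------------------------

def test_channel_gate_range_and_spatial_permutation_invariance(amsaf_tiny, rng):
    g = Tensor(rng.normal(size=(2, 256, 2, 2)).astype(np.float32))
    with no_grad():
        gate = amsaf_tiny.csib.channel_attention(g)
        perm = rng.permutation(4)
        g_perm = g.data.reshape(2, 256, 4)[:, :, perm].reshape(2, 256, 2, 2)
        gate_perm = amsaf_tiny.csib.channel_attention(Tensor(g_perm))
    assert gate.shape == (2, 256, 1, 1)
    assert (gate.data > 0).all() and (gate.data < 1).all()
    assert np.allclose(gate.data, gate_perm.data, atol=1e-6)


def test_channel_gate_closed_form_at_zero_input():
    ca = ChannelAttention(32, ratio=16, seed=5)
    with no_grad():
        gate = ca(Tensor(np.zeros((1, 32, 4, 4), dtype=np.float32)))
    hidden = np.maximum(ca.fc1.bias.data, 0.0)
    logits = ca.fc2.weight.data @ hidden + ca.fc2.bias.data
    expected = 1.0 / (1.0 + np.exp(-logits))
    assert np.allclose(gate.data.reshape(-1), expected, atol=1e-6)


def test_spatial_gate_range_shape_and_channel_permutation_invariance(amsaf_tiny, rng):
    g = Tensor(rng.normal(size=(2, 256, 2, 2)).astype(np.float32))
    with no_grad():
        gate = amsaf_tiny.csib.spatial_attention(g)
        gate_perm = amsaf_tiny.csib.spatial_attention(
            Tensor(g.data[:, rng.permutation(256)]))
    assert gate.shape == (2, 1, 2, 2)
    assert (gate.data > 0).all() and (gate.data < 1).all()
    assert np.allclose(gate.data, gate_perm.data, atol=1e-6)


# -- CSIB ----------------------------------------------------------------------

def test_csib_with_unit_gates_equals_encoder_of_flattened_input(amsaf_tiny, rng):
    x = Tensor(rng.normal(size=(1, 256, 2, 2)).astype(np.float32))
    ones_c = Tensor(np.ones((1, 256, 1, 1), dtype=np.float32))
    ones_s = Tensor(np.ones((1, 1, 2, 2), dtype=np.float32))
    with no_grad():
        refined = amsaf_tiny.csib.refine(x, ones_c, ones_s, n=2)
        tokens = x.reshape(1, 256, 4).transpose(0, 2, 1)
        manual = amsaf_tiny.csib.encoders[1](
            tokens + amsaf_tiny.csib.pos_embed[1].weight)
        manual = manual.transpose(0, 2, 1).reshape(1, 256, 2, 2)
    assert np.allclose(refined.data, manual.data, atol=1e-6)


def test_csib_spatial_permutation_equivariance(amsaf_tiny, rng):
    """Permuting tokens and the positional table identically permutes the
    refined output (self-attention has no inherent token order)."""
    csib = amsaf_tiny.csib
    x = rng.normal(size=(1, 256, 2, 2)).astype(np.float32)
    ones_c = Tensor(np.ones((1, 256, 1, 1), dtype=np.float32))
    ones_s = Tensor(np.ones((1, 1, 2, 2), dtype=np.float32))
    perm = np.array([2, 0, 3, 1])
    original_pos = csib.pos_embed[0].weight.data.copy()
    with no_grad():
        base = csib.refine(Tensor(x), ones_c, ones_s, n=1)
        x_perm = x.reshape(1, 256, 4)[:, :, perm].reshape(1, 256, 2, 2)
        csib.pos_embed[0].weight.data = original_pos[:, perm]
        try:
            permuted = csib.refine(Tensor(x_perm), ones_c, ones_s, n=1)
        finally:
            csib.pos_embed[0].weight.data = original_pos
    base_tokens = base.data.reshape(1, 256, 4)
    perm_tokens = permuted.data.reshape(1, 256, 4)
    assert np.allclose(base_tokens[:, :, perm], perm_tokens, atol=1e-5)


def test_csib_rejects_bad_scale_index(amsaf_tiny, rng):
    x = Tensor(rng.normal(size=(1, 256, 2, 2)).astype(np.float32))
    ones_c = Tensor(np.ones((1, 256, 1, 1), dtype=np.float32))
    ones_s = Tensor(np.ones((1, 1, 2, 2), dtype=np.float32))
    with pytest.raises(ValueError, match="scale index"):
        amsaf_tiny.csib.refine(x, ones_c, ones_s, n=5)


# -- WFA -----------------------------------------------------------------------

def test_wfa_identical_maps_reproduce_input_for_any_weights(rng):
    wfa = WFA(32, seed=0)
    x = Tensor(rng.normal(size=(3, 32, 2, 2)).astype(np.float32))
    with no_grad():
        fused, weights = wfa([x, x, x, x])
    assert np.allclose(fused.data, x.data, atol=1e-5)
    assert np.allclose(weights.data.sum(axis=1), 1.0, atol=1e-6)


def test_wfa_weights_strictly_positive_and_normalized(rng):
    wfa = WFA(32, seed=1)
    for _ in range(20):
        maps = [Tensor(rng.normal(size=(2, 32, 2, 2)).astype(np.float32))
                for _ in range(4)]
        with no_grad():
            _, w = wfa(maps)
        assert (w.data > 0).all()
        assert np.allclose(w.data.sum(axis=1), 1.0, atol=1e-6)


def test_wfa_softmax_of_known_logits():
    """Logits (2,0,0,0) give weights e^2/(e^2+3) = (0.7112, 0.0963, 0.0963,
    0.0963) to 4 dp, evaluated by hand."""
    wfa = WFA(8, seed=0)
    wfa.fc.weight.data[:] = 0.0
    wfa.fc.bias.data = np.array([2.0, 0.0, 0.0, 0.0], dtype=np.float32)
    maps = [Tensor(np.ones((1, 8, 2, 2), dtype=np.float32)) for _ in range(4)]
    with no_grad():
        _, w = wfa(maps)
    assert np.allclose(w.data[0], [0.7112, 0.0963, 0.0963, 0.0963], atol=5e-5)


# -- full pipeline -------------------------------------------------------------

def test_amsaf_forward_shapes(amsaf_tiny, reference_model, rng):
    with no_grad():
        fused, w = amsaf_tiny(make_pyramid(2, "tiny", 64, rng))
    assert fused.shape == (2, 256, 2, 2) and w.shape == (2, 4)
    with no_grad():
        fused_ref, w_ref = reference_model.fusion(
            make_pyramid(1, "reference", 256, rng))
    assert fused_ref.shape == (1, 2048, 8, 8) and w_ref.shape == (1, 4)


def test_fusion_weights_on_simplex_for_100_random_pyramids(amsaf_tiny, rng):
    with no_grad():
        _, w = amsaf_tiny(make_pyramid(100, "tiny", 64, rng))
    assert w.shape == (100, 4)
    assert (w.data >= 0).all()
    assert np.allclose(w.data.sum(axis=1), 1.0, atol=1e-6)
    # batch-mean weights stay on the simplex (convexity)
    assert abs(w.data.mean(axis=0).sum() - 1.0) < 1e-6


def test_fusion_weights_are_content_adaptive(amsaf_tiny, rng):
    """Perturbing the one signal-carrying scale must move the weights."""
    base = zero_pyramid()
    signal = zero_pyramid()
    signal.c3.data[:] = rng.random(signal.c3.shape, dtype=np.float32) * 3.0
    with no_grad():
        _, w_zero = amsaf_tiny(base)
        _, w_sig = amsaf_tiny(signal)
    assert np.abs(w_sig.data - w_zero.data).max() > 1e-4


def test_gating_identity_reduction_to_weighted_average_of_aligned_scales(rng):
    """With unit gates and identity encoders, the pipeline collapses to the
    WFA-weighted average of the aligned scales."""
    amsaf = AMSAF(TINY, (2, 2), seed=3).eval()
    # identity encoders: zero both residual branches and the positional table
    for enc in amsaf.csib.encoders:
        layer = enc._modules["0"]
        layer.attn.out_proj.weight.data[:] = 0.0
        layer.attn.out_proj.bias.data[:] = 0.0
        layer.ffn._modules["2"].weight.data[:] = 0.0
        layer.ffn._modules["2"].bias.data[:] = 0.0
    for holder in amsaf.csib.pos_embed:
        holder.weight.data[:] = 0.0
    # unit gates
    amsaf.csib.channel_attention = _OnesGate(channel=True)
    amsaf.csib.spatial_attention = _OnesGate(channel=False)

    pyr = make_pyramid(2, "tiny", 64, rng)
    with no_grad():
        aligned = amsaf.align(pyr)
        fused, w = amsaf(pyr)
    expected = sum(a.data * w.data[:, i, None, None, None]
                   for i, a in enumerate(aligned))
    assert np.allclose(fused.data, expected, atol=1e-5)


class _OnesGate:
    def __init__(self, channel: bool):
        self.channel = channel

    def __call__(self, g):
        n, c, h, w = g.shape
        shape = (n, c, 1, 1) if self.channel else (n, 1, h, w)
        return Tensor(np.ones(shape, dtype=np.float32))
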