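"""Adaptive multi-scale attention fusion (AMSAF).

Takes the four-level backbone pyramid and produces a single fused map at the
deepest level's resolution, in four steps:

1. *Align and unify*: every level is average-pooled to the conv5 spatial
   size and mapped to the conv5 channel count by a learned 1x1 convolution
   (the conv5 branch too, so all four branches are learned mappings).
2. *Global context*: the four aligned maps are channel-concatenated and
   reconciled by a 1x1 convolution back to C channels.
3. *Cross-scale interaction block (CSIB)*: the global context yields a
   channel gate (squeeze-and-excitation) and a spatial gate (channel-pooled
   saliency map); each aligned scale is multiplied by both gates, flattened
   to h*w tokens of dimension C, and refined by a per-scale transformer
   encoder with learned positional embeddings.
4. *Weighted feature aggregation (WFA)*: a C/2 channel-reduction branch per
   scale is globally pooled, concatenated and mapped by a linear layer to
   four logits; their softmax gives one confidence weight per scale, and the
   fused output is the convex combination of the *full-C* refined maps.

The fusion weights are therefore content-adaptive, one simplex vector per
image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeaturePyramid, _rng
from .nn import Tensor, avg_pool2d_to, concat, softmax


@dataclass
class AmsafConfig:
    """Hyper-parameters of the fusion module (defaults are the package's
    reference construction)."""

    se_ratio: int = 16
    spatial_kernel: int = 7
    tf_layers: int = 1
    tf_heads: int = 8
    tf_ffn_mult: int = 1
    share_tf: bool = False

    def ffn_dim(self, c: int) -> int:
        return max(int(self.tf_ffn_mult * c), 1)


class ScaleAlign(nn.Module):
    """Pool every pyramid level to the deepest resolution and unify channels
    with per-level 1x1 convolutions (bias + ReLU)."""

    def __init__(self, in_channels: tuple[int, ...], seed: int = 0):
        super().__init__()
        self.out_channels = in_channels[-1]
        self.projs = nn.ModuleList([
            nn.Conv2d(c, self.out_channels, 1, bias=True, rng=_rng(seed, 10, i))
            for i, c in enumerate(in_channels)
        ])
        self.relu = nn.ReLU()

    def forward(self, pyramid: FeaturePyramid) -> list[Tensor]:
        levels = pyramid.as_list()
        th, tw = levels[-1].shape[2], levels[-1].shape[3]
        aligned = []
        for x, proj in zip(levels, self.projs):
            if (x.shape[2], x.shape[3]) != (th, tw):
                x = avg_pool2d_to(x, (th, tw))
            aligned.append(self.relu(proj(x)))
        return aligned


class GlobalContext(nn.Module):
    """Stacking fusion of the aligned scales: concat along channels, then a
    1x1 convolution back down to C."""

    def __init__(self, c: int, seed: int = 0):
        super().__init__()
        self.fuse = nn.Conv2d(4 * c, c, 1, bias=True, rng=_rng(seed, 20))
        self.relu = nn.ReLU()

    def forward(self, aligned: list[Tensor]) -> Tensor:
        return self.relu(self.fuse(concat(aligned, axis=1)))


class ChannelAttention(nn.Module):
    """Squeeze-and-excitation gate: GAP -> C/r -> ReLU -> C -> sigmoid,
    emitted as a [N,C,1,1] gate in (0,1)."""

    def __init__(self, c: int, ratio: int = 16, seed: int = 0):
        super().__init__()
        hidden = max(c // ratio, 1)
        self.fc1 = nn.Linear(c, hidden, rng=_rng(seed, 30))
        self.fc2 = nn.Linear(hidden, c, rng=_rng(seed, 31))
        self.relu = nn.ReLU()

    def forward(self, g: Tensor) -> Tensor:
        n, c = g.shape[0], g.shape[1]
        squeezed = g.mean(axis=(2, 3))
        gate = self.fc2(self.relu(self.fc1(squeezed))).sigmoid()
        return gate.reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    """Channel-pooled saliency gate: [mean; max] over channels -> kxk conv
    -> sigmoid, emitted as a [N,1,h,w] gate in (0,1)."""

    def __init__(self, kernel: int = 7, seed: int = 0):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, pad=kernel // 2, bias=True,
                              rng=_rng(seed, 40))

    def forward(self, g: Tensor) -> Tensor:
        pooled = concat([g.mean(axis=1, keepdims=True),
                         g.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()


class CSIB(nn.Module):
    """Cross-scale interaction block: dual-gate recalibration followed by a
    per-scale transformer encoder over flattened spatial tokens."""

    def __init__(self, c: int, tokens: int, cfg: AmsafConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.channel_attention = ChannelAttention(c, cfg.se_ratio, seed=seed)
        self.spatial_attention = SpatialAttention(cfg.spatial_kernel, seed=seed)
        n_enc = 1 if cfg.share_tf else 4
        self.encoders = nn.ModuleList()
        for i in range(n_enc):
            layers = [nn.TransformerEncoderLayer(c, cfg.tf_heads, cfg.ffn_dim(c),
                                                 rng=_rng(seed, 50, i, l))
                      for l in range(cfg.tf_layers)]
            self.encoders.append(nn.Sequential(*layers))
        self.pos_embed = nn.ModuleList()
        for i in range(n_enc):
            holder = nn.Module()
            holder.weight = nn.Parameter(
                _rng(seed, 60, i).normal(0.0, 0.02, (1, tokens, c)))
            self.pos_embed.append(holder)
        self.tokens = tokens

    def _encoder_index(self, n: int) -> int:
        return 0 if self.cfg.share_tf else n - 1

    def refine(self, scale: Tensor, ca: Tensor, sa: Tensor, n: int) -> Tensor:
        """Refine scale ``n`` (1-based, conv2..conv5): gate by ``ca`` then
        ``sa``, flatten to h*w tokens, run the scale's encoder, reshape."""
        if n not in (1, 2, 3, 4):
            raise ValueError(f"scale index must be in 1..4, got {n}")
        nb, c, h, w = scale.shape
        gated = scale * ca * sa
        tokens = gated.reshape(nb, c, h * w).transpose(0, 2, 1)
        if tokens.shape[1] != self.tokens:
            raise RuntimeError(
                f"flatten produced {tokens.shape[1]} tokens, expected {self.tokens}")
        i = self._encoder_index(n)
        refined = self.encoders[i](tokens + self.pos_embed[i].weight)
        return refined.transpose(0, 2, 1).reshape(nb, c, h, w)

    def forward(self, aligned: list[Tensor], g: Tensor) -> list[Tensor]:
        ca = self.channel_attention(g)
        sa = self.spatial_attention(g)
        return [self.refine(x, ca, sa, n) for n, x in enumerate(aligned, start=1)]


class WFA(nn.Module):
    """Weighted feature aggregation: per-scale C/2 reduction -> GAP ->
    concat -> linear -> softmax weights; fused = sum_n w_n * refined_n."""

    def __init__(self, c: int, seed: int = 0):
        super().__init__()
        half = max(c // 2, 1)
        self.reduce = nn.ModuleList([
            nn.Conv2d(c, half, 1, bias=True, rng=_rng(seed, 70, i))
            for i in range(4)
        ])
        self.relu = nn.ReLU()
        self.fc = nn.Linear(4 * half, 4, rng=_rng(seed, 71))

    def weight_logits(self, refined: list[Tensor]) -> Tensor:
        pooled = [self.relu(conv(x)).mean(axis=(2, 3))
                  for conv, x in zip(self.reduce, refined)]
        return self.fc(concat(pooled, axis=1))

    def forward(self, refined: list[Tensor]) -> tuple[Tensor, Tensor]:
        if len(refined) != 4:
            raise ValueError(f"expected 4 refined scales, got {len(refined)}")
        weights = softmax(self.weight_logits(refined), axis=1)  # [N,4]
        n = weights.shape[0]
        fused = None
        for i, x in enumerate(refined):
            term = x * weights[:, i].reshape(n, 1, 1, 1)
            fused = term if fused is None else fused + term
        return fused, weights


class AMSAF(nn.Module):
    """Full fusion pipeline: align -> global context -> CSIB -> WFA."""

    def __init__(self, in_channels: tuple[int, ...], spatial: tuple[int, int],
                 cfg: AmsafConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or AmsafConfig()
        c = in_channels[-1]
        tokens = spatial[0] * spatial[1]
        self.align = ScaleAlign(in_channels, seed=seed)
        self.global_context = GlobalContext(c, seed=seed)
        self.csib = CSIB(c, tokens, self.cfg, seed=seed)
        self.wfa = WFA(c, seed=seed)
        self.out_channels = c

    def forward(self, pyramid: FeaturePyramid) -> tuple[Tensor, Tensor]:
        aligned = self.align(pyramid)
        g = self.global_context(aligned)
        refined = self.csib(aligned, g)
        return self.wfa(refined)
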