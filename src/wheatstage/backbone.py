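"""Shallow stem and hierarchical multi-scale feature extractor.

The stem is a 7x7 stride-2 convolution (bias-free), batch normalization,
ReLU and a 3x3 stride-2 max pool: a 3xHxW image becomes a 64 x H/4 x W/4
map in the reference width preset.  The hierarchical extractor is the
standard bottleneck residual composition of ResNet-101 (stages conv2_x to
conv5_x, block counts 3/4/23/3, expansion 4, stride-2 downsampling with
projection shortcuts at the first block of conv3-conv5), exposing all four
stage outputs as a feature pyramid for downstream fusion.

A "tiny" width preset divides every channel count by 8 so the whole network
trains on a desktop CPU; all shape logic is width-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

#: channel widths per preset: stem output plus the four stage outputs.
WIDTH_PRESETS: dict[str, dict] = {
    "reference": {"stem": 64, "stages": (256, 512, 1024, 2048)},
    "tiny": {"stem": 8, "stages": (32, 64, 128, 256)},
}

#: bottleneck blocks per stage, the ResNet-101 composition.
STAGE_BLOCKS: tuple[int, int, int, int] = (3, 4, 23, 3)

EXPANSION = 4


class ShapeError(ValueError):
    """Raised when an input violates the image/feature shape contract."""


def _check_image(x: Tensor | np.ndarray) -> None:
    shape = x.shape
    if len(shape) == 4:
        shape = shape[1:]
    if len(shape) != 3:
        raise ShapeError(f"expected [3,H,W] image, got shape {tuple(x.shape)}")
    c, h, w = shape
    if c != 3:
        raise ShapeError(f"expected 3 input channels, got {c}")
    if h % 32:
        raise ShapeError(f"image height {h} not divisible by 32")
    if w % 32:
        raise ShapeError(f"image width {w} not divisible by 32")


def _rng(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *offsets]))


class Stem(nn.Module):
    """7x7/2 conv (no bias) -> BN -> ReLU -> 3x3/2 max pool."""

    def __init__(self, width_preset: str = "reference", seed: int = 0):
        super().__init__()
        width = WIDTH_PRESETS[width_preset]["stem"]
        self.conv = nn.Conv2d(3, width, 7, stride=2, pad=3, bias=False,
                              rng=_rng(seed, 0))
        self.bn = nn.BatchNorm2d(width)
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        _check_image(x)
        return self.pool(self.relu(self.bn(self.conv(x))))


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 expand residual block (expansion 4).

    The last BN gain is zero-initialized so every block starts as the
    identity, which keeps very deep stacks trainable from scratch.
    """

    def __init__(self, cin: int, width: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, pad=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        self.bn3.weight.data[:] = 0.0
        self.relu = nn.ReLU()
        if stride != 1 or cin != cout:
            self.shortcut: nn.Module = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout))
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return (out + self.shortcut(x)).relu()


@dataclass
class FeaturePyramid:
    """The four stage outputs, shallow (c2) to deep (c5)."""

    c2: Tensor
    c3: Tensor
    c4: Tensor
    c5: Tensor

    def as_list(self) -> list[Tensor]:
        return [self.c2, self.c3, self.c4, self.c5]

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(t.shape[1] for t in self.as_list())


class Hierarchical(nn.Module):
    """Stages conv2_x..conv5_x producing the four-level pyramid."""

    def __init__(self, width_preset: str = "reference", seed: int = 0):
        super().__init__()
        preset = WIDTH_PRESETS[width_preset]
        self.stage_channels = preset["stages"]
        cin = preset["stem"]
        self.stages = nn.ModuleList()
        for s, (cout, nblocks) in enumerate(zip(self.stage_channels, STAGE_BLOCKS)):
            width = cout // EXPANSION
            blocks = []
            for b in range(nblocks):
                stride = 2 if (b == 0 and s > 0) else 1
                blocks.append(Bottleneck(cin if b == 0 else cout, width, cout,
                                         stride, _rng(seed, 1 + s, b)))
            self.stages.append(nn.Sequential(*blocks))
            cin = cout

    def forward(self, stem_out: Tensor) -> FeaturePyramid:
        if stem_out.shape[1] != self.stages[0]._modules["0"].conv1.weight.shape[1]:
            raise ValueError(
                f"stem output has {stem_out.shape[1]} channels, configured "
                f"width preset expects {self.stages[0]._modules['0'].conv1.weight.shape[1]}")
        feats = []
        x = stem_out
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)


class Backbone(nn.Module):
    """Stem + hierarchical extractor; maps an image to the feature pyramid."""

    def __init__(self, width_preset: str = "reference", seed: int = 0):
        super().__init__()
        if width_preset not in WIDTH_PRESETS:
            raise ValueError(f"unknown width preset {width_preset!r}; "
                             f"valid: {sorted(WIDTH_PRESETS)}")
        self.width_preset = width_preset
        self.stem = Stem(width_preset, seed=seed)
        self.hierarchical = Hierarchical(width_preset, seed=seed)

    def forward(self, x: Tensor) -> FeaturePyramid:
        return self.hierarchical(self.stem(x))


# -- independent layer-shape enumeration oracle --------------------------------

def enumerate_backbone_layers(width_preset: str = "reference") -> list[dict]:
    """Declared layer list of stem + stages, by pure arithmetic.

    Each entry carries enough to price the layer:
    ``{"name", "kind", "k", "cin", "cout", "bias"}`` for convolutions and
    ``{"name", "kind", "features"}`` for affine norms.  This walks the
    architecture *description*, never the built model, so it can audit the
    framework-reported parameter counts independently.
    """
    preset = WIDTH_PRESETS[width_preset]
    layers: list[dict] = [
        {"name": "stem.conv", "kind": "conv", "k": 7, "cin": 3,
         "cout": preset["stem"], "bias": False},
        {"name": "stem.bn", "kind": "norm", "features": preset["stem"]},
    ]
    cin = preset["stem"]
    for s, (cout, nblocks) in enumerate(zip(preset["stages"], STAGE_BLOCKS)):
        width = cout // EXPANSION
        for b in range(nblocks):
            pre = f"conv{s + 2}_x.{b}"
            bin_ = cin if b == 0 else cout
            layers += [
                {"name": f"{pre}.conv1", "kind": "conv", "k": 1, "cin": bin_,
                 "cout": width, "bias": False},
                {"name": f"{pre}.bn1", "kind": "norm", "features": width},
                {"name": f"{pre}.conv2", "kind": "conv", "k": 3, "cin": width,
                 "cout": width, "bias": False},
                {"name": f"{pre}.bn2", "kind": "norm", "features": width},
                {"name": f"{pre}.conv3", "kind": "conv", "k": 1, "cin": width,
                 "cout": cout, "bias": False},
                {"name": f"{pre}.bn3", "kind": "norm", "features": cout},
            ]
            if b == 0 and (s > 0 or cin != cout):
                layers += [
                    {"name": f"{pre}.shortcut.conv", "kind": "conv", "k": 1,
                     "cin": bin_, "cout": cout, "bias": False},
                    {"name": f"{pre}.shortcut.bn", "kind": "norm", "features": cout},
                ]
        cin = cout
    return layers


def count_layer_params(layers: list[dict]) -> int:
    """Price a declared layer list: k*k*cin*cout (+cout bias) per conv,
    2*features per affine norm."""
    total = 0
    for lay in layers:
        if lay["kind"] == "conv":
            total += lay["k"] ** 2 * lay["cin"] * lay["cout"]
            if lay["bias"]:
                total += lay["cout"]
        elif lay["kind"] == "norm":
            total += 2 * lay["features"]
        elif lay["kind"] == "linear":
            total += lay["cin"] * lay["cout"] + (lay["cout"] if lay["bias"] else 0)
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown layer kind {lay['kind']!r}")
    return total


def expected_stem_params(width_preset: str = "reference") -> int:
    layers = [l for l in enumerate_backbone_layers(width_preset)
              if l["name"].startswith("stem")]
    return count_layer_params(layers)


def expected_hierarchical_params(width_preset: str = "reference") -> int:
    layers = [l for l in enumerate_backbone_layers(width_preset)
              if not l["name"].startswith("stem")]
    return count_layer_params(layers)
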