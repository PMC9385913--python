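"""3D feature-pyramid regression network for contour quality estimation.

The model maps a 2-channel volume (image + candidate contour) to a single
scalar in (0, 1), an estimate of the contour's Dice coefficient against the
unseen ground truth.  It is an EfficientDet-style design adapted to 3D:

* an EfficientNet-flavored backbone of MBConv stages (expansion factor 2)
  emitting a seven-level feature pyramid P1..P7 with channel counts
  (32, 16, 24, 40, 80, 112, 192) by default;
* bidirectional feature pyramid (BiFPN) blocks, repeated three times with
  64 channels, fusing levels P3..P7 with fast normalized fusion;
* a regression head that resamples the fused levels to the coarsest (P7)
  resolution, collapses them through serially connected fast normalized
  fusion nodes, then batch norm → PReLU → a single-channel convolution →
  global average pooling → sigmoid.

In-plane resolution halves at every pyramid level.  Because typical axial
volumes have far fewer slices than in-plane voxels, the z axis is halved
alongside x/y only while more than 4 slices remain, then keeps stride 1;
convolution kernels are isotropic 3×3×3 (anisotropic voxel spacing is not
compensated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from contourqa.nn import autograd as ag
from contourqa.nn.layers import (
    BatchNorm3d,
    Conv1x1,
    Conv3x3,
    FastNormalizedFusion,
    MBConv,
    Module,
    PReLU,
    SeparableConvBlock,
)

#: Pyramid levels fed to the BiFPN (0-based indices into P1..P7).
_BIFPN_LEVELS = (2, 3, 4, 5, 6)

#: Minimum in-plane extent able to form a 7-level pyramid meaningfully.
MIN_INPLANE = 16


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``backbone_channels`` are the P1..P7 channel counts; ``stage_repeats``
    the number of MBConv blocks per stage for P2..P7 (extra blocks keep
    stride 1).  ``input_shape`` is (nx, ny, nz, channels) with channels = 2.
    """

    backbone_channels: tuple[int, ...] = (32, 16, 24, 40, 80, 112, 192)
    mbconv_expansion: int = 2
    bifpn_repeats: int = 3
    bifpn_channels: int = 64
    stage_repeats: tuple[int, ...] = (2, 2, 3, 3, 4, 1)
    input_shape: tuple[int, int, int, int] = (160, 160, 28, 2)
    fusion_epsilon: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.backbone_channels) != 7:
            raise ValueError("backbone_channels must list 7 pyramid levels")
        if any(c < 1 for c in self.backbone_channels):
            raise ValueError("all channel counts must be >= 1")
        if len(self.stage_repeats) != 6 or any(r < 1 for r in self.stage_repeats):
            raise ValueError("stage_repeats must list 6 counts >= 1")
        if min(self.mbconv_expansion, self.bifpn_repeats, self.bifpn_channels) < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.input_shape) != 4 or self.input_shape[3] != 2:
            raise ValueError("input_shape must be (nx, ny, nz, 2)")
        if min(self.input_shape[0], self.input_shape[1]) < MIN_INPLANE:
            raise ValueError(
                f"input in-plane extent {self.input_shape[:2]} too small for a "
                f"7-level pyramid; need at least {MIN_INPLANE}×{MIN_INPLANE}"
            )

    @classmethod
    def tiny(cls, input_shape: tuple[int, int, int, int] = (32, 32, 8, 2),
             seed: int = 0) -> "NetConfig":
        """A desk-scale configuration (~0.25 width, single-block stages)."""
        return cls(
            backbone_channels=(8, 4, 8, 12, 20, 28, 48),
            mbconv_expansion=2,
            bifpn_repeats=1,
            bifpn_channels=16,
            stage_repeats=(1, 1, 1, 1, 1, 1),
            input_shape=input_shape,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "backbone_channels": list(self.backbone_channels),
            "mbconv_expansion": self.mbconv_expansion,
            "bifpn_repeats": self.bifpn_repeats,
            "bifpn_channels": self.bifpn_channels,
            "stage_repeats": list(self.stage_repeats),
            "input_shape": list(self.input_shape),
            "fusion_epsilon": self.fusion_epsilon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        for key in ("backbone_channels", "stage_repeats", "input_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def level_strides(input_shape: Sequence[int]) -> list[tuple[int, int, int]]:
    """Per-level downsampling strides: x/y always halve; z halves while > 4."""
    strides = []
    z = input_shape[2]
    for _ in range(7):
        sz = 2 if z > 4 else 1
        strides.append((2, 2, sz))
        z = (z - 1) // 2 + 1 if sz == 2 else z
    return strides


def level_shapes(input_shape: Sequence[int]) -> list[tuple[int, int, int]]:
    """Spatial shape of each pyramid level for a given input shape."""
    shapes = []
    cur = tuple(input_shape[:3])
    for s in level_strides(input_shape):
        cur = tuple((n - 1) // st + 1 for n, st in zip(cur, s))
        shapes.append(cur)
    return shapes


class Backbone(Module):
    """Stem + MBConv stages emitting the 7-level feature pyramid."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        ch = cfg.backbone_channels
        strides = level_strides(cfg.input_shape)
        self.stem = Conv3x3(2, ch[0], rng, stride=strides[0], bias=False)
        self.stem_bn = BatchNorm3d(ch[0])
        self.stages = []
        for i in range(1, 7):
            blocks = [MBConv(ch[i - 1], ch[i], rng, cfg.mbconv_expansion, strides[i])]
            for _ in range(cfg.stage_repeats[i - 1] - 1):
                blocks.append(MBConv(ch[i], ch[i], rng, cfg.mbconv_expansion))
            self.stages.append(blocks)

    def forward(self, x: ag.Tensor) -> list[ag.Tensor]:
        levels = [ag.silu(self.stem_bn(self.stem(x)))]
        h = levels[0]
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h)
            levels.append(h)
        return levels  # P1..P7


class BiFPNBlock(Module):
    """One bidirectional fusion pass over the P3..P7 levels."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        n = len(_BIFPN_LEVELS)
        eps = cfg.fusion_epsilon
        # top-down nodes for levels n-2..0, bottom-up for levels 1..n-1
        self.td_fuse = [FastNormalizedFusion(2, eps) for _ in range(n - 1)]
        self.td_conv = [SeparableConvBlock(cfg.bifpn_channels, rng) for _ in range(n - 1)]
        self.bu_fuse = [
            FastNormalizedFusion(3 if 0 < i < n - 1 else 2, eps) for i in range(1, n)
        ]
        self.bu_conv = [SeparableConvBlock(cfg.bifpn_channels, rng) for _ in range(n - 1)]

    def forward(self, feats: list[ag.Tensor]) -> list[ag.Tensor]:
        n = len(feats)
        shapes = [f.shape[2:] for f in feats]
        # Top-down: coarse to fine.
        td = [None] * n
        td[n - 1] = feats[n - 1]
        for i in range(n - 2, -1, -1):
            up = ag.nearest_resize(td[i + 1], shapes[i])
            td[i] = self.td_conv[i](self.td_fuse[i]([feats[i], up]))
        # Bottom-up: fine to coarse.
        out = [None] * n
        out[0] = td[0]
        for i in range(1, n):
            down = ag.nearest_resize(out[i - 1], shapes[i])
            inputs = [feats[i], td[i], down] if i < n - 1 else [feats[i], down]
            out[i] = self.bu_conv[i - 1](self.bu_fuse[i - 1](inputs))
        return out


class RegressionHead(Module):
    """Serial fusion collapse of the pyramid into one sigmoid scalar."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        n = len(_BIFPN_LEVELS)
        self.fusions = [FastNormalizedFusion(2, cfg.fusion_epsilon) for _ in range(n - 1)]
        self.bn = BatchNorm3d(cfg.bifpn_channels)
        self.act = PReLU(cfg.bifpn_channels)
        self.final_conv = Conv1x1(cfg.bifpn_channels, 1, rng)

    def forward(self, feats: list[ag.Tensor]) -> ag.Tensor:
        coarsest = feats[-1].shape[2:]
        h = feats[-1]
        for fusion, f in zip(self.fusions, reversed(feats[:-1])):
            h = fusion([h, ag.nearest_resize(f, coarsest)])
        h = self.final_conv(self.act(self.bn(h)))
        pooled = ag.global_avg_pool(h)  # (B, 1)
        # Clamp the logit so the output stays strictly inside (0, 1) in
        # float32 even for saturated (e.g. untrained) networks.
        return ag.sigmoid(ag.clip(pooled, -15.0, 15.0))


class QaNet(Module):
    """The full quality regression model.

    Deterministic given ``cfg.seed``: two builds from the same config have
    identical initial parameters.
    """

    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng)
        self.laterals = [
            Conv1x1(cfg.backbone_channels[lv], cfg.bifpn_channels, rng, bias=False)
            for lv in _BIFPN_LEVELS
        ]
        self.lateral_bns = [BatchNorm3d(cfg.bifpn_channels) for _ in _BIFPN_LEVELS]
        self.bifpns = [BiFPNBlock(cfg, rng) for _ in range(cfg.bifpn_repeats)]
        self.head = RegressionHead(cfg, rng)

    def forward(self, batch: np.ndarray) -> ag.Tensor:
        """Map a (B, nx, ny, nz, 2) channels-last batch to (B,) in (0, 1)."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 5 or batch.shape[1:] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"expected batch of shape (B, {', '.join(map(str, self.cfg.input_shape))}), "
                f"got {batch.shape}"
            )
        x_cf = np.ascontiguousarray(np.moveaxis(batch, -1, 1))
        # Model-entry standardization: the image channel arrives on the
        # [0, 255] normalization scale and is mapped to ~[-1, 1]; the binary
        # contour channel is kept at 0/1.
        x_cf[:, 0] = x_cf[:, 0] / 127.5 - 1.0
        x = ag.Tensor(x_cf)
        pyramid = self.backbone(x)
        feats = [
            bn(lat(pyramid[lv]))
            for lv, lat, bn in zip(_BIFPN_LEVELS, self.laterals, self.lateral_bns)
        ]
        for block in self.bifpns:
            feats = block(feats)
        out = self.head(feats)  # (B, 1)
        out_flat = ag.Tensor(
            out.data[:, 0], parents=(out,),
            backward=lambda g: out.accumulate(g[:, None]),
        )
        return out_flat

    def predict(self, tensors: Sequence[np.ndarray], batch_size: int = 4) -> np.ndarray:
        """Eval-mode predictions for a sequence of (nx, ny, nz, 2) tensors."""
        was_training = self.training
        self.eval()
        try:
            preds = []
            for i in range(0, len(tensors), batch_size):
                batch = np.stack(tensors[i:i + batch_size])
                preds.append(self.forward(batch).data)
            return np.concatenate(preds)
        finally:
            self.train(was_training)

    # -- checkpointing ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for mod in [self, *self.modules()]:
            if isinstance(mod, BatchNorm3d):
                arrays.extend([mod.running_mean, mod.running_var])
        return arrays

    def save(self, path) -> None:
        """Save parameters + BN buffers with the config embedded."""
        import yaml

        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, config=np.str_(yaml.safe_dump(self.cfg.to_dict())), **arrays)

    @classmethod
    def load(cls, path) -> "QaNet":
        import yaml

        with np.load(path, allow_pickle=False) as f:
            cfg = NetConfig.from_dict(yaml.safe_load(str(f["config"])))
            model = cls(cfg)
            for i, a in enumerate(model.state_arrays()):
                a[...] = f[f"a{i}"]
        return model


def build_backbone(cfg: NetConfig) -> Backbone:
    """Standalone backbone builder (feature-pyramid producer)."""
    return Backbone(cfg, np.random.default_rng(cfg.seed))


def build_model(cfg: NetConfig) -> QaNet:
    return QaNet(cfg)
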