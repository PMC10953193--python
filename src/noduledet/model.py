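"""3D region proposal network: backbone, neck and dense head.

The detector follows the one-stage RPN layout: a 3D convolutional backbone
(ResNet, ResNeXt or CSP-ResNeXt blocks) produces features at strides
2, 4 and 8; the neck either passes per-level lateral features straight
through or fuses them top-down (FPN); each level's head emits 15 channels —
3 anchor sizes x (probability logit, z, y, x, d).

Residual blocks are pre-activation (norm - relu - conv) so a block is the
identity when its final convolution is zero.  The CSP variant splits the
channels in half, routes one half through a grouped-convolution ResNeXt
unit, concatenates and fuses with a 1x1x1 transition — cutting parameters
relative to the plain ResNeXt block at equal width.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

BACKBONE_VARIANTS = ("resnet", "resnext", "csp_resnext")


@dataclass
class ModelConfig:
    backbone_variant: str = "csp_resnext"
    use_fpn: bool = True
    base_channels: int = 8
    cardinality: int = 8
    stage_blocks: int = 1
    pyramid_strides: tuple[int, int, int] = (2, 4, 8)
    anchors_per_level: int = 3
    anchor_sizes: tuple[float, float, float] = (5.0, 10.0, 20.0)
    neck_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_variant not in BACKBONE_VARIANTS:
            raise ValueError(
                f"unknown backbone variant {self.backbone_variant!r}; "
                f"choose from {BACKBONE_VARIANTS}")
        if len(self.pyramid_strides) != 3:
            raise ValueError("exactly 3 pyramid levels are required")
        if len(self.anchor_sizes) != self.anchors_per_level:
            raise ValueError("anchor_sizes must match anchors_per_level")

    @property
    def head_channels(self) -> int:
        return self.anchors_per_level * 5    # probability + (z, y, x, d)

    @classmethod
    def full_scale(cls) -> "ModelConfig":
        """Preset sized for real CT training (~1.28 M parameters)."""
        return cls(base_channels=40, cardinality=32, stage_blocks=3,
                   neck_channels=64)


@dataclass
class HeadOutput:
    """Per-level dense predictions.

    ``cls_logits[i]`` has shape ``(A, d, h, w)`` and ``regression[i]``
    ``(A, 4, d, h, w)`` with A anchors per cell and the regression channels
    ordered (dz, dy, dx, dd); spatial shapes are input shape / level stride.
    """

    cls_logits: list[np.ndarray]
    regression: list[np.ndarray]

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate levels into per-anchor arrays matching the canonical
        anchor order (level-major, z, y, x, size ascending)."""
        logits, regs = [], []
        for cl, rg in zip(self.cls_logits, self.regression):
            logits.append(cl.transpose(1, 2, 3, 0).reshape(-1))
            regs.append(rg.transpose(2, 3, 4, 0, 1).reshape(-1, 4))
        return np.concatenate(logits), np.concatenate(regs)


def _group_count(mid_channels: int, cardinality: int) -> int:
    return math.gcd(mid_channels, cardinality)


class _PreActUnit(nn.Module):
    """Pre-activation residual unit: x + conv(...(relu(norm(x))))."""

    def __init__(self, layers: list[nn.Module]) -> None:
        self.branch = nn.Sequential(*layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.branch.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.branch.backward(dy)


def _basic_block(c: int, rng) -> nn.Module:
    return _PreActUnit([
        nn.GroupNorm(c), nn.ReLU(), nn.Conv3d(c, c, 3, rng=rng),
        nn.GroupNorm(c), nn.ReLU(), nn.Conv3d(c, c, 3, rng=rng),
    ])


def _resnext_block(c: int, cardinality: int, rng) -> nn.Module:
    mid = max(c // 2, 1)
    g = _group_count(mid, cardinality)
    return _PreActUnit([
        nn.GroupNorm(c), nn.ReLU(), nn.Conv3d(c, mid, 1, rng=rng),
        nn.GroupNorm(mid), nn.ReLU(), nn.Conv3d(mid, mid, 3, groups=g, rng=rng),
        nn.GroupNorm(mid), nn.ReLU(), nn.Conv3d(mid, c, 1, rng=rng),
    ])


class CSPResNeXtBlock(nn.Module):
    """Cross-stage-partial ResNeXt block.

    The input is split 50/50 along channels; one half passes through a
    grouped-convolution ResNeXt residual unit, the other half bypasses;
    the concatenated halves are fused by a 1x1x1 transition convolution.
    Spatial shape is preserved (striding lives in stage transitions).
    """

    def __init__(self, channels: int, cardinality: int, rng) -> None:
        if channels % 2:
            raise ValueError(f"CSP block needs an even channel count, got {channels}")
        self.channels = channels
        half = channels // 2
        self.unit = _resnext_block(half, cardinality, rng)
        self.transition = nn.Sequential(
            nn.Conv3d(channels, channels, 1, rng=rng),
            nn.GroupNorm(channels), nn.ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        half = self.channels // 2
        y2 = self.unit.forward(x[half:])
        return self.transition.forward(np.concatenate([x[:half], y2], axis=0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        half = self.channels // 2
        dcat = self.transition.backward(dy)
        dx2 = self.unit.backward(dcat[half:])
        return np.concatenate([dcat[:half], dx2], axis=0)


def _make_block(variant: str, c: int, cardinality: int, rng) -> nn.Module:
    if variant == "resnet":
        return _basic_block(c, rng)
    if variant == "resnext":
        return _resnext_block(c, cardinality, rng)
    return CSPResNeXtBlock(c, cardinality, rng)


class _Backbone(nn.Module):
    """Stem + three stages producing features at strides 2, 4, 8."""

    def __init__(self, cfg: ModelConfig, rng) -> None:
        c1, c2, c3 = cfg.base_channels, cfg.base_channels * 2, cfg.base_channels * 4
        self.channels = (c1, c2, c3)
        blocks = cfg.stage_blocks
        v, card = cfg.backbone_variant, cfg.cardinality
        self.stem = nn.Sequential(nn.Conv3d(1, c1, 3, stride=2, rng=rng),
                                  nn.GroupNorm(c1), nn.ReLU())
        self.stage1 = nn.Sequential(*[_make_block(v, c1, card, rng) for _ in range(blocks)])
        self.down2 = nn.Sequential(nn.Conv3d(c1, c2, 3, stride=2, rng=rng),
                                   nn.GroupNorm(c2), nn.ReLU())
        self.stage2 = nn.Sequential(*[_make_block(v, c2, card, rng) for _ in range(blocks)])
        self.down3 = nn.Sequential(nn.Conv3d(c2, c3, 3, stride=2, rng=rng),
                                   nn.GroupNorm(c3), nn.ReLU())
        self.stage3 = nn.Sequential(*[_make_block(v, c3, card, rng) for _ in range(blocks)])

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f1 = self.stage1.forward(self.stem.forward(x))
        f2 = self.stage2.forward(self.down2.forward(f1))
        f3 = self.stage3.forward(self.down3.forward(f2))
        return f1, f2, f3

    def backward_features(self, df1, df2, df3) -> np.ndarray:
        d2 = self.down3.backward(self.stage3.backward(df3)) + df2
        d1 = self.down2.backward(self.stage2.backward(d2)) + df1
        return self.stem.backward(self.stage1.backward(d1))


class _Head(nn.Module):
    """Per-level dense head: 3x3x3 conv tower + 1x1x1 predictor (15 channels).

    The classification bias is initialized so the initial foreground
    probability is ~1%, the standard focal-loss prior for dense detection.
    """

    def __init__(self, in_channels: int, n_anchors: int, rng) -> None:
        self.n_anchors = n_anchors
        self.tower = nn.Sequential(nn.Conv3d(in_channels, in_channels, 3, rng=rng),
                                   nn.GroupNorm(in_channels), nn.ReLU())
        self.pred = nn.Conv3d(in_channels, n_anchors * 5, 1, rng=rng)
        prior = 0.01
        self.pred.bias.data[:n_anchors] = -math.log((1 - prior) / prior)
        self.pred.weight.data *= 0.1

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pred.forward(self.tower.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.tower.backward(self.pred.backward(dy))


class RPN3D(nn.Module):
    """The assembled detector: backbone -> neck -> per-level heads."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = _Backbone(cfg, rng)
        nc = cfg.neck_channels
        self.laterals = [nn.Conv3d(c, nc, 1, rng=rng) for c in self.backbone.channels]
        if cfg.use_fpn:
            self.upsamples = [nn.Upsample2(), nn.Upsample2()]
            self.smooths = [nn.Sequential(nn.Conv3d(nc, nc, 3, rng=rng),
                                          nn.GroupNorm(nc), nn.ReLU())
                            for _ in range(3)]
        self.heads = [_Head(nc, cfg.anchors_per_level, rng) for _ in range(3)]

    # -- forward / backward ------------------------------------------------
    def _check_input(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=np.float32)
        if patch.ndim == 3:
            patch = patch[None]
        stride = max(self.cfg.pyramid_strides)
        if any(s % stride for s in patch.shape[1:]):
            raise ValueError(
                f"patch spatial dims {patch.shape[1:]} must be divisible by {stride}")
        return patch

    def forward(self, patch: np.ndarray) -> HeadOutput:
        x = self._check_input(patch)
        feats = self.backbone.forward(x)
        lats = [lat.forward(f) for lat, f in zip(self.laterals, feats)]
        if self.cfg.use_fpn:
            p3 = lats[2]
            p2 = lats[1] + self.upsamples[1].forward(p3)
            p1 = lats[0] + self.upsamples[0].forward(p2)
            qs = [sm.forward(p) for sm, p in zip(self.smooths, (p1, p2, p3))]
        else:
            qs = lats
        cls_logits, regression = [], []
        a = self.cfg.anchors_per_level
        for head, q in zip(self.heads, qs):
            out = head.forward(q)
            d, h, w = out.shape[1:]
            cls_logits.append(out[:a])
            regression.append(out[a:].reshape(a, 4, d, h, w))
        return HeadOutput(cls_logits, regression)

    def backward_from_head(self, d_cls: list[np.ndarray],
                           d_reg: list[np.ndarray]) -> None:
        """Backpropagate per-level gradients on the head outputs."""
        a = self.cfg.anchors_per_level
        dqs = []
        for head, dc, dr in zip(self.heads, d_cls, d_reg):
            d, h, w = dc.shape[1:]
            dout = np.concatenate([dc, dr.reshape(a * 4, d, h, w)], axis=0)
            dqs.append(head.backward(dout))
        if self.cfg.use_fpn:
            dp1, dp2, dp3 = [sm.backward(dq) for sm, dq in zip(self.smooths, dqs)]
            dp2 = dp2 + self.upsamples[0].backward(dp1)
            dp3 = dp3 + self.upsamples[1].backward(dp2)
            dls = [dp1, dp2, dp3]
        else:
            dls = dqs
        dfs = [lat.backward(dl) for lat, dl in zip(self.laterals, dls)]
        self.backbone.backward_features(*dfs)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i:04d}": p.data for i, p in enumerate(self.params())}

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights plus an embedded config snapshot."""
        path = Path(path)
        arrays = self.state_arrays()
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RPN3D":
        with np.load(Path(path)) as data:
            cfg_json = json.loads(bytes(data["__config__"].tobytes()).decode())
            for key in ("pyramid_strides", "anchor_sizes"):
                cfg_json[key] = tuple(cfg_json[key])
            model = cls(ModelConfig(**cfg_json))
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"p{i:04d}"]
        return model


def build_model(cfg: ModelConfig) -> RPN3D:
    """Build a detector; backbone variants are interchangeable behind RPN3D."""
    return RPN3D(cfg)


def level_shapes(patch_shape: tuple[int, int, int],
                 strides: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Feature-grid shape at each pyramid level for a given patch shape."""
    return [tuple(s // st for s in patch_shape) for st in strides]
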