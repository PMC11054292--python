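"""The localization network: ResNet backbone, ELAN / SPP+CSP neck, three heads.

The network is a keypoint detector: a fully convolutional backbone feeds a
feature-pyramid neck whose fusion blocks are ELAN (efficient layer
aggregation) and SPP+CSP (spatial pyramid pooling inside a cross-stage
partial split); three small heads on the final stride-4 feature emit the
per-class center heatmap, the fractional-cell offset map, and the
normalized depth map.

Backbones: ``resnet50`` (the full-scale configuration whose neck shapes
are audited in the tests), ``resnet18``, and ``tiny`` — a width-reduced
variant for CPU-scale experiments, with the neck rescaled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .codec import TargetMaps

__all__ = [
    "BACKBONES",
    "CenterXFNet",
    "SPPCSP",
    "ELAN",
    "LossWeights",
    "build_backbone",
    "total_loss",
    "shape_audit",
    "save_checkpoint",
    "load_checkpoint",
]


BACKBONES = {
    # block, blocks per stage, stem width, stage widths, SPP+CSP c2 per level,
    # ELAN c1 per level, head hidden width
    "resnet50": dict(block="bottleneck", layers=(3, 4, 6, 3), stem=64, widths=(64, 128, 256, 512),
                     spp_c2=(256, 256, 128), elan_c1=(256, 128, 64), head=64),
    "resnet18": dict(block="basic", layers=(2, 2, 2, 2), stem=64, widths=(64, 128, 256, 512),
                     spp_c2=(128, 128, 64), elan_c1=(128, 64, 32), head=32),
    "tiny": dict(block="basic", layers=(1, 1, 1, 1), stem=16, widths=(16, 32, 64, 128),
                 spp_c2=(32, 32, 16), elan_c1=(32, 16, 16), head=16),
}


@dataclass
class LossWeights:
    lambda_heat: float = 1.0
    lambda_offset: float = 1.0
    lambda_depth: float = 1.0
    focal_alpha: float = 2.0
    focal_beta: float = 4.0


# ---------------------------------------------------------------------------
# backbone


class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, c_in, width, stride, rng):
        c_out = width * self.expansion
        self.conv1 = nn.ConvBNReLU(c_in, width, 3, stride, rng=rng)
        self.conv2 = nn.Conv2d(width, c_out, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = nn.Sequential(nn.Conv2d(c_in, c_out, 1, stride, bias=False, rng=rng), nn.BatchNorm2d(c_out))

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = self.bn2(self.conv2(self.conv1(x)))
        return nn.relu(nn.add(out, identity))


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, c_in, width, stride, rng):
        c_out = width * self.expansion
        self.conv1 = nn.ConvBNReLU(c_in, width, 1, rng=rng)
        self.conv2 = nn.ConvBNReLU(width, width, 3, stride, rng=rng)
        self.conv3 = nn.Conv2d(width, c_out, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = nn.Sequential(nn.Conv2d(c_in, c_out, 1, stride, bias=False, rng=rng), nn.BatchNorm2d(c_out))

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = self.bn3(self.conv3(self.conv2(self.conv1(x))))
        return nn.relu(nn.add(out, identity))


class Backbone(nn.Module):
    """ResNet-style feature pyramid at strides 4 / 8 / 16 / 32, grayscale stem."""

    def __init__(self, name: str, in_channels: int = 1, rng: np.random.Generator | None = None):
        if name not in BACKBONES:
            raise ValueError(f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}")
        rng = rng or np.random.default_rng(0)
        spec = BACKBONES[name]
        self.name = name
        block = _Bottleneck if spec["block"] == "bottleneck" else _BasicBlock
        stem = spec["stem"]
        self.stem_conv = nn.Conv2d(in_channels, stem, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        c_in = stem
        self.out_channels = []
        for si, (width, n_blocks) in enumerate(zip(spec["widths"], spec["layers"])):
            mods = []
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                mods.append(block(c_in, width, stride, rng))
                c_in = width * block.expansion
            self.stages.append(nn.Sequential(*mods))
            self.out_channels.append(c_in)

    def forward(self, x: Tensor) -> list[Tensor]:
        h, w = x.data.shape[2:]
        if h != w:
            raise ValueError(f"input must be square, got {h}x{w}")
        if h % 32 != 0:
            raise ValueError(f"input edge {h} not divisible by 32")
        x = self.pool(nn.relu(self.stem_bn(self.stem_conv(x))))
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats  # strides 4, 8, 16, 32


def build_backbone(name: str, in_channels: int = 1, rng=None) -> Backbone:
    return Backbone(name, in_channels, rng)


# ---------------------------------------------------------------------------
# neck blocks


class SPPCSP(nn.Module):
    """Spatial pyramid pooling inside a cross-stage-partial split.

    One 1x1 branch bypasses; the other passes parallel max-pools of window
    5/9/13 (spatial size preserved), a 3x3 fuse, then the two branches are
    concatenated and fused 1x1 down to c2.
    """

    def __init__(self, c1: int, c2: int, rng=None):
        self.c1, self.c2 = c1, c2
        self.bypass = nn.ConvBNReLU(c1, c2, 1, rng=rng)
        self.pre = nn.ConvBNReLU(c1, c2, 1, rng=rng)
        self.pools = [nn.MaxPool2d(k, 1, k // 2) for k in (5, 9, 13)]
        self.post = nn.ConvBNReLU(4 * c2, c2, 3, rng=rng)
        self.fuse = nn.ConvBNReLU(2 * c2, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.c1:
            raise ValueError(f"SPP+CSP expected {self.c1} channels, got {x.data.shape[1]}")
        a = self.bypass(x)
        b = self.pre(x)
        b = self.post(nn.concat([b] + [p(b) for p in self.pools]))
        return self.fuse(nn.concat([a, b]))


class ELAN(nn.Module):
    """Efficient layer aggregation block.

    Two parallel 1x1 stems to c2/2; one stem feeds a chain of four 3x3
    convolutions (width c2/2) tapped after conv 2 and conv 4; the four
    tensors concatenate to 2*c2 channels and fuse 1x1 to c_out.
    """

    def __init__(self, c1: int, c2: int, c_out: int, rng=None):
        if c2 % 2:
            raise ValueError("ELAN c2 must be even")
        self.c1, self.c2, self.c_out = c1, c2, c_out
        half = c2 // 2
        self.stem1 = nn.ConvBNReLU(c1, half, 1, rng=rng)
        self.stem2 = nn.ConvBNReLU(c1, half, 1, rng=rng)
        self.chain = [nn.ConvBNReLU(half, half, 3, rng=rng) for _ in range(4)]
        self.fuse = nn.ConvBNReLU(2 * c2, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.c1:
            raise ValueError(f"ELAN expected {self.c1} channels, got {x.data.shape[1]}")
        s1 = self.stem1(x)
        s2 = self.stem2(x)
        y = self.chain[1](self.chain[0](s2))
        tap1 = y
        tap2 = self.chain[3](self.chain[2](y))
        return self.fuse(nn.concat([s1, s2, tap1, tap2]))


class _Head(nn.Module):
    def __init__(self, c_in: int, hidden: int, c_out: int, rng=None, bias_init: float = 0.0):
        self.conv1 = nn.Conv2d(c_in, hidden, 3, rng=rng)
        self.conv2 = nn.Conv2d(hidden, c_out, 1, rng=rng)
        if bias_init:
            self.conv2.bias.data[:] = bias_init

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(nn.relu(self.conv1(x)))


# ---------------------------------------------------------------------------
# full model


class CenterXFNet(nn.Module):
    """Backbone + FPN-style ELAN / SPP+CSP neck + heatmap/offset/depth heads."""

    STRIDE = 4

    def __init__(self, n_classes: int, backbone: str = "resnet50", rng: np.random.Generator | None = None,
                 use_spp_csp: bool = True, use_elan: bool = True):
        rng = rng or np.random.default_rng(0)
        self.n_classes = n_classes
        self.backbone = Backbone(backbone, 1, rng)
        spec = BACKBONES[backbone]
        c2, c3, c4, c5 = self.backbone.out_channels
        s1, s2, s3 = spec["spp_c2"]
        e1, e2, e3 = spec["elan_c1"]

        # ablation hooks: either block family is replaceable by a plain
        # conv -> batch-norm -> ReLU of the same in/out channels
        def spp(c_in, c_out):
            return SPPCSP(c_in, c_out, rng) if use_spp_csp else nn.ConvBNReLU(c_in, c_out, 3, rng=rng)

        def elan(c_in, c_out):
            return ELAN(c_in, 2 * c_in, c_out, rng) if use_elan else nn.ConvBNReLU(c_in, c_out, 3, rng=rng)

        # top-down path: SPP+CSP laterals at strides 32/16/8, 1x1 lateral at stride 4
        self.spp1 = spp(c5, s1)
        self.spp2 = spp(c4, s2)
        self.spp3 = spp(c3, s3)
        self.proj5 = nn.ConvBNReLU(s1, s2, 1, rng=rng)  # after upsample of spp1
        self.fuse1 = nn.ConvBNReLU(2 * s2, e1, 1, rng=rng)
        self.elan1 = elan(e1, e1)
        self.proj4 = nn.ConvBNReLU(e1, s3, 1, rng=rng)
        self.fuse2 = nn.ConvBNReLU(2 * s3, e2, 1, rng=rng)
        self.elan2 = elan(e2, e2)
        self.proj3 = nn.ConvBNReLU(e2, e3, 1, rng=rng)
        self.lat2 = nn.ConvBNReLU(c2, e3, 1, rng=rng)
        self.fuse3 = nn.ConvBNReLU(2 * e3, e3, 1, rng=rng)
        self.elan3 = elan(e3, e3)
        self.use_spp_csp = use_spp_csp
        self.use_elan = use_elan
        head = spec["head"]
        # heatmap bias starts at -2.19 so initial peak probability ~0.1;
        # depth head is linear with bias at mid-range (z = 0)
        self.head_heat = _Head(e3, head, n_classes, rng, bias_init=-2.19)
        self.head_offset = _Head(e3, head, 2, rng)
        self.head_depth = _Head(e3, head, 1, rng, bias_init=0.5)

    def forward(self, image: np.ndarray | Tensor) -> dict[str, Tensor]:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.data.ndim != 4:
            raise ValueError("expected (N, 1, H, W) input")
        f4, f8, f16, f32 = self.backbone(x)
        n5 = self.spp1(f32)
        l4 = self.spp2(f16)
        p4 = self.elan1(self.fuse1(nn.concat([self.proj5(nn.upsample_nearest2(n5)), l4])))
        l3 = self.spp3(f8)
        p3 = self.elan2(self.fuse2(nn.concat([self.proj4(nn.upsample_nearest2(p4)), l3])))
        l2 = self.lat2(f4)
        p2 = self.elan3(self.fuse3(nn.concat([self.proj3(nn.upsample_nearest2(p3)), l2])))
        return {
            "heatmap": nn.sigmoid(self.head_heat(p2)),
            "offset": self.head_offset(p2),
            "depth": self.head_depth(p2),
        }


def total_loss(
    pred: dict[str, Tensor],
    heat: np.ndarray,
    offset: np.ndarray,
    depth: np.ndarray,
    mask: np.ndarray,
    weights: LossWeights | None = None,
    depth_mask: np.ndarray | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Focal heatmap loss plus masked L1 on offset and depth.

    Targets are batched numpy arrays: heat (N,C,Hs,Ws), offset (N,2,Hs,Ws),
    depth (N,1,Hs,Ws), mask (N,1,Hs,Ws) bool. Offset is supervised at
    center cells; depth over ``depth_mask`` (defaults to the center mask).
    """
    w = weights or LossWeights()
    for key, arr in (("heatmap", heat), ("offset", offset), ("depth", depth)):
        if pred[key].data.shape != arr.shape:
            raise ValueError(f"{key}: prediction {pred[key].data.shape} vs target {arr.shape}")
    l_heat = nn.focal_loss(pred["heatmap"], heat, w.focal_alpha, w.focal_beta)
    l_off = nn.masked_l1(pred["offset"], offset, mask)
    l_dep = nn.masked_l1(pred["depth"], depth, mask if depth_mask is None else depth_mask)
    total = l_heat * w.lambda_heat + l_off * w.lambda_offset + l_dep * w.lambda_depth
    return total, {"heat": l_heat.item(), "offset": l_off.item(), "depth": l_dep.item(), "total": total.item()}


def batch_targets(maps_list: list[TargetMaps]):
    heat = np.stack([m.heatmap for m in maps_list])
    offset = np.stack([m.offset for m in maps_list])
    depth = np.stack([m.depth for m in maps_list])
    mask = np.stack([m.center_mask[None] for m in maps_list])
    depth_mask = np.stack([m.depth_mask[None] for m in maps_list])
    return heat, offset, depth, mask, depth_mask


# ---------------------------------------------------------------------------
# shape audit


def shape_audit(backbone: str = "resnet50", input_size: int = 1024) -> list[dict]:
    """Per-stage neck geometry for a given input size.

    Derived from a constructed model's actual layer widths (weight
    shapes), not from a lookup table, so the audit fails if the
    architecture drifts.
    """
    model = CenterXFNet(n_classes=2, backbone=backbone)
    rows = []
    sizes = {32: input_size // 32, 16: input_size // 16, 8: input_size // 8, 4: input_size // 4}
    for i, (blk, stride) in enumerate([(model.spp1, 32), (model.spp2, 16), (model.spp3, 8)], start=1):
        c_in = blk.bypass.conv.weight.data.shape[1]
        c_out = blk.fuse.conv.weight.data.shape[0]
        c2 = blk.bypass.conv.weight.data.shape[0]
        rows.append(
            {"idx": f"SPP+CSP {i}", "c1": c_in, "c2": c2, "in_size": sizes[stride], "out_size": sizes[stride],
             "in_channel": c_in, "out_channel": c_out}
        )
    for i, (blk, stride) in enumerate([(model.elan1, 16), (model.elan2, 8), (model.elan3, 4)], start=1):
        c_in = blk.stem1.conv.weight.data.shape[1]
        half = blk.stem1.conv.weight.data.shape[0]
        c_out = blk.fuse.conv.weight.data.shape[0]
        rows.append(
            {"idx": f"ELAN {i}", "c1": c_in, "c2": 2 * half, "in_size": sizes[stride], "out_size": sizes[stride],
             "in_channel": c_in, "out_channel": c_out}
        )
    rows.append({"idx": "maps", "out_size": input_size // CenterXFNet.STRIDE,
                 "out_channel": model.head_heat.conv2.weight.data.shape[0]})
    return rows


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: CenterXFNet, path: str | Path, meta: dict) -> Path:
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    sidecar = dict(meta)
    sidecar.setdefault("stride", CenterXFNet.STRIDE)
    sidecar["n_classes"] = model.n_classes
    sidecar["backbone"] = model.backbone.name
    sidecar["use_spp_csp"] = model.use_spp_csp
    sidecar["use_elan"] = model.use_elan
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def load_checkpoint(path: str | Path, expect: dict | None = None) -> tuple[CenterXFNet, dict]:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    if expect:
        for key, val in expect.items():
            if meta.get(key) != val:
                raise ValueError(f"checkpoint sidecar mismatch for {key!r}: {meta.get(key)!r} != {val!r}")
    model = CenterXFNet(
        n_classes=meta["n_classes"],
        backbone=meta["backbone"],
        use_spp_csp=meta.get("use_spp_csp", True),
        use_elan=meta.get("use_elan", True),
    )
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model, meta
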