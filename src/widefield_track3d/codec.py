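"""Annotation <-> network-output conversion.

The network describes each particle by a Gaussian peak on a per-class
center heatmap, a fractional-cell offset at the peak's cell, and a
normalized depth value at the same cell, all on a grid downsampled by the
output stride S (4). Decoding inverts the scheme: 3x3 local maxima of the
heatmap are candidate centers; each survivor yields
x = (cx + offset_x)·S, y = (cy + offset_y)·S and a de-normalized z.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
from scipy.ndimage import maximum_filter

from .config import BeadClass, OpticalConfig
from .simulate import pattern_footprint_px

__all__ = ["TargetMaps", "Detection", "encode_targets", "decode_detections", "gaussian_radius"]


@dataclass
class TargetMaps:
    heatmap: np.ndarray  # (C, Hs, Ws) in [0, 1]
    offset: np.ndarray  # (2, Hs, Ws), fractional cells, defined at center cells
    depth: np.ndarray  # (1, Hs, Ws), normalized z, defined where depth_mask is true
    center_mask: np.ndarray  # (Hs, Ws) bool
    stride: int
    # depth is supervised over each object's splat footprint so the
    # regression sees more gradient signal; decoding still reads the peak cell
    depth_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.depth_mask is None:
            self.depth_mask = self.center_mask


@dataclass
class Detection:
    x_px: float
    y_px: float
    z_um: float
    bead_class: str
    score: float
    z_clamped: bool = False


def z_normalize(z_um: float | np.ndarray, optical: OpticalConfig) -> float | np.ndarray:
    return (z_um - optical.z_min_um) / (optical.z_max_um - optical.z_min_um)


def z_denormalize(z_norm: float | np.ndarray, optical: OpticalConfig):
    return optical.z_min_um + z_norm * (optical.z_max_um - optical.z_min_um)


def gaussian_radius(box_size: float, min_overlap: float = 0.7) -> float:
    """Size-adaptive splat radius.

    Largest displacement of a square box of edge ``box_size`` (in output
    cells) such that the shifted box still overlaps the original with
    IoU >= min_overlap; the standard rule of the keypoint-detection
    family. For a square box shifted diagonally the binding case reduces
    to one quadratic.
    """
    # corner kept inside: (size - 2r)^2 >= IoU * ... use the three CornerNet cases
    h = w = box_size
    a1 = 1.0
    b1 = h + w
    c1 = w * h * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - sqrt(b1**2 - 4 * a1 * c1)) / (2 * a1)
    a2 = 4.0
    b2 = 2 * (h + w)
    c2 = (1 - min_overlap) * w * h
    r2 = (b2 - sqrt(b2**2 - 4 * a2 * c2)) / (2 * a2)
    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (h + w)
    c3 = (min_overlap - 1) * w * h
    r3 = (-b3 + sqrt(b3**2 - 4 * a3 * c3)) / (2 * a3)
    return max(min(r1, r2, r3), 0.0)


def encode_targets(
    annotations,
    image_size: int,
    stride: int,
    classes: list[BeadClass],
    optical: OpticalConfig,
) -> TargetMaps:
    """Build heatmap / offset / depth grids for one scene's annotations.

    Per object, the center cell is (floor(x/S), floor(y/S)); its class
    channel receives a Gaussian splat with size-adaptive sigma (floor of
    one cell), channels combine across objects by elementwise max; offset
    and depth are written only at center cells.
    """
    if image_size % stride != 0 or image_size // stride <= 0:
        raise ValueError(f"stride {stride} does not divide image size {image_size} into a positive map")
    hs = ws = ceil(image_size / stride)
    labels = [b.label for b in classes]
    heat = np.zeros((len(classes), hs, ws), dtype=np.float32)
    offset = np.zeros((2, hs, ws), dtype=np.float32)
    depth = np.zeros((1, hs, ws), dtype=np.float32)
    mask = np.zeros((hs, ws), dtype=bool)
    depth_mask = np.zeros((hs, ws), dtype=bool)
    vv, uu = np.mgrid[0:hs, 0:ws]
    for ann in annotations:
        if not (0 <= ann.x_px < image_size and 0 <= ann.y_px < image_size):
            raise ValueError(f"annotation at ({ann.x_px}, {ann.y_px}) outside {image_size}-px image")
        ci = labels.index(ann.bead_class)
        cx = int(ann.x_px // stride)
        cy = int(ann.y_px // stride)
        bead = classes[ci]
        box_cells = pattern_footprint_px(bead, ann.z_um) / stride
        sigma = max(gaussian_radius(box_cells) / 3.0, 1.0)
        splat = np.exp(-((uu - cx) ** 2 + (vv - cy) ** 2) / (2.0 * sigma**2)).astype(np.float32)
        np.maximum(heat[ci], splat, out=heat[ci])
        heat[ci, cy, cx] = 1.0
        offset[0, cy, cx] = ann.x_px / stride - cx
        offset[1, cy, cx] = ann.y_px / stride - cy
        zn = z_normalize(ann.z_um, optical)
        # depth is supervised wherever this object's splat is strong
        # (~1.5 sigma), at least over the 3x3 block around the center
        region = splat > 0.3
        region[max(cy - 1, 0) : cy + 2, max(cx - 1, 0) : cx + 2] = True
        depth[0, region] = zn
        depth_mask |= region
        mask[cy, cx] = True
    return TargetMaps(
        heatmap=heat, offset=offset, depth=depth, center_mask=mask, stride=stride, depth_mask=depth_mask
    )


def decode_detections(
    heatmap: np.ndarray,
    offset: np.ndarray,
    depth: np.ndarray,
    stride: int,
    classes: list[BeadClass],
    optical: OpticalConfig,
    score_threshold: float = 0.3,
    top_k: int = 100,
) -> list[Detection]:
    """Decode detections from (already-squashed) output maps.

    Candidate cells are 3x3 local maxima (ties kept); the top_k by score
    are then filtered by ``score_threshold``.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if heatmap.size == 0:
        raise ValueError("empty heatmap")
    c, hs, ws = heatmap.shape
    keep = heatmap >= maximum_filter(heatmap, size=(1, 3, 3), mode="constant", cval=-np.inf)
    scores = np.where(keep, heatmap, -np.inf).ravel()
    order = np.argsort(scores)[::-1][:top_k]
    detections: list[Detection] = []
    for flat in order:
        score = scores[flat]
        if not np.isfinite(score) or score < score_threshold:
            break
        ci, cy, cx = np.unravel_index(flat, heatmap.shape)
        x = (cx + float(offset[0, cy, cx])) * stride
        y = (cy + float(offset[1, cy, cx])) * stride
        zn = float(depth[0, cy, cx])
        clamped = not (0.0 <= zn <= 1.0)
        z = float(z_denormalize(np.clip(zn, 0.0, 1.0), optical))
        detections.append(
            Detection(
                x_px=x,
                y_px=y,
                z_um=z,
                bead_class=classes[ci].label,
                score=float(score),
                z_clamped=clamped,
            )
        )
    return detections
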