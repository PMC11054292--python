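"""Calibrated single-bead defocus patterns and the calibration library.

A real calibration is acquired by stepping immobilized beads through focus
with a piezo stage and cropping one feature image per (bead, z) position.
This module generates the same artifact from a documented parametric model
of the wide-field defocus pattern, so the whole pipeline has exact,
download-free ground truth:

    I(r, z) = B + A * env(r; w(|z|)) * (1 + m(z) * cos(2π f(|z|) r))

with a Gaussian envelope whose width w and ring frequency f grow affinely
with |z|, and a modulation depth m odd in z. The odd term is what makes
patterns above and below focus distinguishable — the practical advantage
of wide-field over coherent illumination.

Sub-pixel centers are recovered with the radial-symmetry method
(intensity gradients of a radially symmetric spot all point through its
center; the center is the weighted least-squares intersection of the
gradient lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BeadClass, OpticalConfig
from .util import read_gray, substream, write_gray

__all__ = [
    "FeaturePatch",
    "CalibrationLibrary",
    "DegenerateImageError",
    "make_z_grid",
    "simulate_bead_pattern",
    "bead_pattern_noise_free",
    "build_calibration_library",
    "radial_symmetry_center",
    "pattern_footprint_px",
    "save_library",
    "load_library",
]


class DegenerateImageError(ValueError):
    """Raised when an image has no usable intensity gradients."""


@dataclass
class FeaturePatch:
    """A single-bead defocus crop with calibrated sub-pixel center."""

    pixels: np.ndarray  # float32 in [0, 1]
    z_um: float
    bead_class: str
    center: tuple[float, float]  # (x, y), 0-based pixel coordinates

    def __post_init__(self):
        h, w = self.pixels.shape
        x, y = self.center
        if not (0 < x < w - 1 and 0 < y < h - 1):
            raise ValueError("patch center must lie strictly inside the patch")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("patch intensities must be finite")


@dataclass
class CalibrationLibrary:
    """One FeaturePatch per (bead class, z-grid position)."""

    patches: dict[tuple[str, int], FeaturePatch]
    z_grid: np.ndarray
    classes: list[BeadClass]
    config: OpticalConfig

    def __len__(self) -> int:
        return len(self.patches)

    def __post_init__(self):
        expected = len(self.classes) * len(self.z_grid)
        if len(self.patches) != expected:
            raise ValueError(f"library has {len(self.patches)} patches, expected {expected}")
        steps = np.diff(self.z_grid)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9):
            raise ValueError("z_grid must be strictly increasing with uniform spacing")

    def get(self, label: str, iz: int) -> FeaturePatch:
        return self.patches[(label, iz)]

    def bead(self, label: str) -> BeadClass:
        for b in self.classes:
            if b.label == label:
                return b
        raise KeyError(label)


def make_z_grid(z_min_um: float, z_max_um: float, z_step_um: float) -> np.ndarray:
    """Axial calibration grid: segment starts, z_max excluded.

    The 20 μm scan divided into 50 nm segments yields exactly 400
    positions under this half-open convention.
    """
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")
    if z_min_um >= z_max_um:
        raise ValueError("z_min_um must be < z_max_um")
    span = z_max_um - z_min_um
    k = span / z_step_um
    n = round(k)
    if abs(k - n) > 1e-9 * max(1.0, abs(k)):
        raise ValueError(
            f"z range {span:g} μm is not divisible by step {z_step_um:g} μm "
            f"(remainder {span - n * z_step_um:g} μm)"
        )
    return z_min_um + z_step_um * np.arange(n)


def _radial_profile_params(bead: BeadClass, z_um: float):
    p = bead.pattern
    w = p.env_width0_px + p.env_width_slope_px_per_um * abs(z_um)
    f = p.ring_freq0 + p.ring_freq_slope * abs(z_um)
    m = p.asym * np.tanh(z_um / p.asym_scale_um)
    return w, f, m


def pattern_footprint_px(bead: BeadClass, z_um: float) -> float:
    """Approximate diameter (px) of the visible defocus pattern at z."""
    w, _, _ = _radial_profile_params(bead, z_um)
    return float(min(4.0 * w, bead.patch_size_px))


def bead_pattern_noise_free(bead: BeadClass, z_um: float,
                            subpixel_shift: tuple[float, float] = (0.0, 0.0)) -> tuple[np.ndarray, tuple[float, float]]:
    """Render the noise-free pattern; returns (pixels, center).

    The nominal center is the geometric patch center, optionally offset by
    ``subpixel_shift`` = (dx, dy); the model is evaluated analytically at
    the shifted center so no interpolation is involved.
    """
    n = bead.patch_size_px
    cx = (n - 1) / 2.0 + subpixel_shift[0]
    cy = (n - 1) / 2.0 + subpixel_shift[1]
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    r = np.hypot(xx - cx, yy - cy)
    w, f, m = _radial_profile_params(bead, z_um)
    p = bead.pattern
    img = p.background + p.amplitude * np.exp(-(r**2) / (2.0 * w**2)) * (1.0 + m * np.cos(2.0 * np.pi * f * r))
    return np.clip(img, 0.0, 1.0), (cx, cy)


def simulate_bead_pattern(bead: BeadClass, z_um: float, config: OpticalConfig,
                          rng: np.random.Generator | None = None,
                          subpixel_shift: tuple[float, float] = (0.0, 0.0)) -> FeaturePatch:
    """One calibration feature image: parametric pattern plus camera noise."""
    if not (config.z_min_um <= z_um <= config.z_max_um):
        raise ValueError(f"z = {z_um:g} μm outside calibration range [{config.z_min_um:g}, {config.z_max_um:g}]")
    img, center = bead_pattern_noise_free(bead, z_um, subpixel_shift)
    if config.noise_sd > 0:
        if rng is None:
            rng = substream(config.seed, "pattern", bead.label, round(z_um * 1e6))
        img = np.clip(img + rng.normal(0.0, config.noise_sd, img.shape), 0.0, 1.0)
    return FeaturePatch(pixels=img, z_um=float(z_um), bead_class=bead.label, center=center)


def build_calibration_library(classes: list[BeadClass], config: OpticalConfig) -> CalibrationLibrary:
    """Assemble the full (class × z-grid) library.

    Library patches are noise-free — a real calibration averages several
    exposures per stage position, and the averaged crop is what gets
    spliced — and each patch's center is fixed by the radial-symmetry
    localizer run on that noise-free pattern.
    """
    if not classes:
        raise ValueError("at least one bead class is required")
    z_grid = make_z_grid(config.z_min_um, config.z_max_um, config.z_step_um)
    patches: dict[tuple[str, int], FeaturePatch] = {}
    for bead in classes:
        for iz, z in enumerate(z_grid):
            img, _ = bead_pattern_noise_free(bead, float(z))
            center = radial_symmetry_center(img)
            patches[(bead.label, iz)] = FeaturePatch(
                pixels=img, z_um=float(z), bead_class=bead.label, center=center
            )
    return CalibrationLibrary(patches=patches, z_grid=z_grid, classes=list(classes), config=config)


# ---------------------------------------------------------------------------
# radial-symmetry sub-pixel localization


def _gradient_terms(pixels: np.ndarray):
    """Gradient directions on the inter-pixel midpoint grid plus weights.

    Each midpoint contributes a line through (xm, ym) along its intensity
    gradient, as unit direction (gx, gy); weight is gradient magnitude²
    divided by distance to the magnitude-weighted centroid. The direction
    form has no singularity for vertical lines, unlike slope-intercept.
    """
    img = pixels.astype(np.float64)
    ny, nx = img.shape
    # 45°-rotated derivatives at the midpoints of each 2x2 pixel block
    didu = img[:-1, 1:] - img[1:, :-1]
    didv = img[:-1, :-1] - img[1:, 1:]
    # 3x3 boxcar smoothing tames pixel noise
    from scipy.ndimage import uniform_filter

    didu = uniform_filter(didu, size=3, mode="nearest")
    didv = uniform_filter(didv, size=3, mode="nearest")
    mag2 = didu**2 + didv**2
    total = mag2.sum()
    if total <= 0:
        raise DegenerateImageError("uniform image: no intensity gradients to localize on")
    # rotate back to image axes; only the direction matters
    gx = didu - didv
    gy = -(didu + didv)
    norm = np.sqrt(mag2)
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = np.where(norm > 0, gx / norm, 0.0)
        gy = np.where(norm > 0, gy / norm, 0.0)
    ym, xm = np.mgrid[0 : ny - 1, 0 : nx - 1].astype(np.float64)
    xm += 0.5
    ym += 0.5
    xc = (mag2 * xm).sum() / total
    yc = (mag2 * ym).sum() / total
    dist = np.hypot(xm - xc, ym - yc)
    w = mag2 / np.maximum(dist, 0.1)
    return xm, ym, gx, gy, w


def radial_symmetry_center(pixels: np.ndarray) -> tuple[float, float]:
    """Sub-pixel center of a radially symmetric spot.

    Weighted least-squares intersection point of the gradient-direction
    lines through inter-pixel midpoints. Returns (x, y) in 0-based pixel
    coordinates; raises :class:`DegenerateImageError` on gradient-free
    input.
    """
    if pixels.ndim != 2 or min(pixels.shape) < 5:
        raise ValueError("radial_symmetry_center needs a 2-D grid of at least 5x5 pixels")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("non-finite intensities")
    xm, ym, gx, gy, w = _gradient_terms(pixels)
    # distance of (x, y) to a line through (xm, ym) with direction (gx, gy)
    # is |gx (y - ym) - gy (x - xm)|; normal equations of the weighted LSQ
    k = gx * ym - gy * xm
    a11 = (w * gy * gy).sum()
    a12 = -(w * gx * gy).sum()
    a22 = (w * gx * gx).sum()
    b1 = -(w * gy * k).sum()
    b2 = (w * gx * k).sum()
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-300:
        raise DegenerateImageError("degenerate gradient geometry")
    xc = (b1 * a22 - a12 * b2) / det
    yc = (a11 * b2 - a12 * b1) / det
    ny, nx = pixels.shape
    if not (0 <= xc <= nx - 1 and 0 <= yc <= ny - 1):
        raise DegenerateImageError("radial-symmetry center fell outside the image")
    return float(xc), float(yc)


def symmetry_objective(pixels: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Sum of weighted squared line distances for candidate centers.

    The same objective minimized in closed form by
    :func:`radial_symmetry_center`; used by the brute-force grid-search
    oracle in the tests. ``candidates`` is (K, 2) of (x, y).
    """
    xm, ym, gx, gy, w = _gradient_terms(pixels)
    k = (gx * ym - gy * xm).ravel()
    gx, gy, w = gx.ravel(), gy.ravel(), w.ravel()
    cand = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    xc, yc = cand[:, 0], cand[:, 1]
    # quadratic in (xc, yc); evaluate through its coefficients
    return (
        (w * gx * gx).sum() * yc**2
        + (w * gy * gy).sum() * xc**2
        - 2.0 * (w * gx * gy).sum() * xc * yc
        - 2.0 * (w * gx * k).sum() * yc
        + 2.0 * (w * gy * k).sum() * xc
        + (w * k * k).sum()
    )


# ---------------------------------------------------------------------------
# persistence: one 16-bit TIFF per patch plus an index CSV


def save_library(library: CalibrationLibrary, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "patches").mkdir(parents=True, exist_ok=True)
    rows = []
    for (label, iz), patch in sorted(library.patches.items()):
        fname = f"patches/{label}_{iz:04d}.tif"
        write_gray(out_dir / fname, patch.pixels, library.config.bit_depth)
        rows.append(
            {
                "class": label,
                "z_um": patch.z_um,
                "patch_file": fname,
                "center_x_px": patch.center[0],
                "center_y_px": patch.center[1],
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "index.csv", index=False)
    import yaml

    meta = {
        "optical": library.config.model_dump(mode="json"),
        "beads": [b.model_dump(mode="json") for b in library.classes],
    }
    (out_dir / "library.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out_dir


def load_library(path: str | Path) -> CalibrationLibrary:
    path = Path(path)
    import yaml

    meta = yaml.safe_load((path / "library.yaml").read_text())
    config = OpticalConfig(**meta["optical"])
    classes = [BeadClass(**b) for b in meta["beads"]]
    index = pd.read_csv(path / "index.csv")
    z_grid = make_z_grid(config.z_min_um, config.z_max_um, config.z_step_um)
    patches: dict[tuple[str, int], FeaturePatch] = {}
    for _, row in index.iterrows():
        iz = int(np.argmin(np.abs(z_grid - row["z_um"])))
        patches[(row["class"], iz)] = FeaturePatch(
            pixels=read_gray(path / row["patch_file"]),
            z_um=float(row["z_um"]),
            bead_class=row["class"],
            center=(float(row["center_x_px"]), float(row["center_y_px"])),
        )
    return CalibrationLibrary(patches=patches, z_grid=z_grid, classes=classes, config=config)
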