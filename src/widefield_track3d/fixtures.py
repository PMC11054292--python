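"""Deterministic desk-scale fixtures binding all modules together.

Each fixture is small enough to regenerate in seconds and is used both by
the test suite and as a worked example: a two-class mini calibration
library, a 12-scene dataset, a stepped-z validation video, and ideal
target maps for codec tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codec import encode_targets
from .compose import build_dataset, compose_scene
from .config import ComposeConfig, OpticalConfig, default_bead_classes
from .net import CenterXFNet
from .simulate import CalibrationLibrary, build_calibration_library, save_library
from .track import StageProfile
from .util import substream, write_gray

__all__ = ["mini_optical_config", "mini_library", "make_fixture", "make_stepped_video", "DEFAULT_VIDEO_LEVELS"]

# stage offsets (μm) for the default fixture video; same rising shape as a
# piezo step validation, kept on the mini library's (half-open) z grid
DEFAULT_VIDEO_LEVELS = (-2.0, -0.5, 0.0, 0.5, 1.0, 1.5)


def mini_optical_config(seed: int = 0) -> OpticalConfig:
    return OpticalConfig(z_min_um=-2.0, z_max_um=2.0, z_step_um=0.5, seed=seed)


def mini_library(seed: int = 0) -> CalibrationLibrary:
    return build_calibration_library(default_bead_classes(), mini_optical_config(seed))


def make_stepped_video(
    library: CalibrationLibrary,
    out_dir: str | Path,
    levels: tuple[float, ...] = DEFAULT_VIDEO_LEVELS,
    frames_per_level: int = 5,
    seed: int = 0,
    image_size: int = 256,
    particles: list[tuple[str, float, float]] | None = None,
    noise_sd: float = 0.02,
    background: float = 0.15,
) -> Path:
    """Render a stepped-z video: fixed-xy beads whose z follows the stage.

    Every level's z must be on the library grid. Writes frames/*.tif, a
    per-frame truth.csv and profile.yaml describing the commanded steps.
    """
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    if particles is None:
        particles = [("small", image_size * 0.3, image_size * 0.35), ("big", image_size * 0.68, image_size * 0.62)]
    z_grid = library.z_grid
    rows = []
    frame = 0
    level_rows = []
    for li, off in enumerate(levels):
        iz = int(np.argmin(np.abs(z_grid - off)))
        if abs(z_grid[iz] - off) > 1e-9:
            raise ValueError(f"stage level {off} μm not on the library z grid")
        level_rows.append((frame, frame + frames_per_level - 1, float(off)))
        for _ in range(frames_per_level):
            rng = substream(seed, "video-frame", frame)
            img = np.full((image_size, image_size), background, dtype=np.float32)
            for label, x, y in particles:
                patch = library.get(label, iz)
                from .compose import _patch_background
                from scipy import ndimage

                ps = patch.pixels.shape[0]
                x0 = x - patch.center[0]
                y0 = y - patch.center[1]
                ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
                dx, dy = x0 - ix0, y0 - iy0
                fg = patch.pixels - _patch_background(patch.pixels)
                if dx or dy:
                    fg = ndimage.shift(fg, (dy, dx), order=3, mode="nearest", prefilter=True)
                img[iy0 : iy0 + ps, ix0 : ix0 + ps] += fg
                rows.append(
                    {"frame": frame, "class": label, "x_px": x, "y_px": y, "z_um": float(z_grid[iz])}
                )
            if noise_sd > 0:
                img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
            np.clip(img, 0.0, 1.0, out=img)
            write_gray(out_dir / "frames" / f"frame_{frame:04d}.tif", img, library.config.bit_depth)
            frame += 1
    pd.DataFrame(rows).to_csv(out_dir / "truth.csv", index=False)
    profile = {"levels": [{"first_frame": f0, "last_frame": f1, "offset_um": off} for f0, f1, off in level_rows]}
    (out_dir / "profile.yaml").write_text(yaml.safe_dump(profile, sort_keys=False))
    return out_dir


def load_stage_profile(path: str | Path) -> StageProfile:
    doc = yaml.safe_load(Path(path).read_text())
    return StageProfile([(lv["first_frame"], lv["last_frame"], lv["offset_um"]) for lv in doc["levels"]])


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Generate one of the standard fixtures: calib | dataset | video | ideal_maps."""
    out_dir = Path(out_dir)
    if kind == "calib":
        save_library(mini_library(seed), out_dir)
    elif kind == "dataset":
        lib = mini_library(seed)
        cc = ComposeConfig(
            image_size_min_px=256, image_size_max_px=256, n_particles_min=2, n_particles_max=4, noise_sd=0.02
        )
        build_dataset(lib, 12, out_dir, seed, compose_cfg=cc, split_fractions=(0.75, 0.25))
    elif kind == "video":
        make_stepped_video(mini_library(seed), out_dir, seed=seed)
    elif kind == "ideal_maps":
        lib = mini_library(seed)
        rng = substream(seed, "ideal-maps")
        scene = compose_scene(lib, 4, 256, rng, noise_sd=0.0, seed=seed)
        maps = encode_targets(scene.annotations, 256, CenterXFNet.STRIDE, lib.classes, lib.config)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gray(out_dir / "scene.tif", scene.pixels)
        np.savez(
            out_dir / "maps.npz",
            heatmap=maps.heatmap,
            offset=maps.offset,
            depth=maps.depth,
            center_mask=maps.center_mask,
            stride=maps.stride,
        )
        pd.DataFrame(
            [
                {"class": a.bead_class, "x_px": a.x_px, "y_px": a.y_px, "z_um": a.z_um}
                for a in scene.annotations
            ]
        ).to_csv(out_dir / "annotations.csv", index=False)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose calib, dataset, video or ideal_maps")
    return out_dir
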