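"""Random splicing of calibration patches into labelled multi-particle scenes.

Each scene starts from a flat background; for every particle a library
patch is chosen uniformly over (class, z-grid index), given a sub-pixel
shift, and blended additively after background subtraction, so the exact
3-D position of every particle is known by construction. Datasets of such
scenes are written as 16-bit TIFFs with per-split annotation CSVs and a
YAML manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .config import ComposeConfig, OpticalConfig
from .simulate import CalibrationLibrary, load_library  # noqa: F401  (re-export for callers)
from .util import substream, write_gray

__all__ = [
    "ParticleAnnotation",
    "Scene",
    "DatasetManifest",
    "OvercrowdedError",
    "compose_scene",
    "build_dataset",
    "load_manifest",
]

SPLIT_NAMES = ("train", "eval", "test")


class OvercrowdedError(RuntimeError):
    """Raised when the separation constraint cannot be met; carries the count placed."""

    def __init__(self, requested: int, placed: int):
        super().__init__(
            f"could only place {placed} of {requested} particles under the separation constraint"
        )
        self.requested = requested
        self.placed = placed


@dataclass
class ParticleAnnotation:
    x_px: float
    y_px: float
    z_um: float
    bead_class: str
    source_patch: tuple[str, int]


@dataclass
class Scene:
    pixels: np.ndarray
    annotations: list[ParticleAnnotation]
    seed: int


def _patch_background(pixels: np.ndarray) -> float:
    border = np.concatenate([pixels[0], pixels[-1], pixels[1:-1, 0], pixels[1:-1, -1]])
    return float(np.median(border))


def compose_scene(
    library: CalibrationLibrary,
    n_particles: int,
    image_size: int,
    rng: np.random.Generator,
    min_separation: float | None = None,
    separation_factor: float = 0.6,
    background_level: float = 0.15,
    noise_sd: float = 0.02,
    max_attempts_per_particle: int = 200,
    seed: int = 0,
) -> Scene:
    """Splice ``n_particles`` random library patches onto a background.

    ``min_separation`` fixes the pairwise center distance in px; when None
    the default policy is ``separation_factor`` times the summed patch
    half-sizes of the pair (0 disables the constraint and allows
    collisions). Placement is rejection sampling with a bounded attempt
    budget; overcrowding raises :class:`OvercrowdedError`.
    """
    largest = max(b.patch_size_px for b in library.classes)
    if image_size < largest:
        raise ValueError(f"image_size {image_size} smaller than largest patch {largest}")
    img = np.full((image_size, image_size), background_level, dtype=np.float32)
    labels = [b.label for b in library.classes]
    nz = len(library.z_grid)
    placed: list[tuple[float, float, float]] = []  # x, y, half-size
    annotations: list[ParticleAnnotation] = []
    for _ in range(n_particles):
        # draw (class, z) once so the library sampling stays uniform;
        # only the position is re-drawn on a separation rejection
        label = labels[rng.integers(len(labels))]
        iz = int(rng.integers(nz))
        patch = library.get(label, iz)
        ps = patch.pixels.shape[0]
        half = ps / 2.0
        ok = False
        for _attempt in range(max_attempts_per_particle):
            # integer anchor + sub-pixel jitter; footprint stays inside the image
            x0 = int(rng.integers(0, image_size - ps))
            y0 = int(rng.integers(0, image_size - ps))
            dx = float(rng.uniform(0.0, 1.0))
            dy = float(rng.uniform(0.0, 1.0))
            cx = x0 + patch.center[0] + dx
            cy = y0 + patch.center[1] + dy
            sep_ok = True
            for px, py, phalf in placed:
                need = min_separation if min_separation is not None else separation_factor * (half + phalf)
                if np.hypot(cx - px, cy - py) < need:
                    sep_ok = False
                    break
            if sep_ok:
                ok = True
                break
        if not ok:
            raise OvercrowdedError(n_particles, len(annotations))
        fg = patch.pixels - _patch_background(patch.pixels)
        if dx or dy:
            fg = ndimage.shift(fg, (dy, dx), order=3, mode="nearest", prefilter=True)
        img[y0 : y0 + ps, x0 : x0 + ps] += fg
        placed.append((cx, cy, half))
        annotations.append(
            ParticleAnnotation(x_px=cx, y_px=cy, z_um=patch.z_um, bead_class=label, source_patch=(label, iz))
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    np.clip(img, 0.0, 1.0, out=img)
    return Scene(pixels=img, annotations=annotations, seed=seed)


def render_isolated_particle(library: CalibrationLibrary, ann: ParticleAnnotation, image_size: int) -> np.ndarray:
    """Noise-free re-render of one placed patch on a zero background.

    Used to verify that stored annotation centers are exact.
    """
    patch = library.patches[ann.source_patch]
    ps = patch.pixels.shape[0]
    x0 = ann.x_px - patch.center[0]
    y0 = ann.y_px - patch.center[1]
    ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
    dx, dy = x0 - ix0, y0 - iy0
    fg = patch.pixels - _patch_background(patch.pixels)
    if dx or dy:
        fg = ndimage.shift(fg, (dy, dx), order=3, mode="nearest", prefilter=True)
    img = np.zeros((image_size, image_size), dtype=np.float32)
    img[iy0 : iy0 + ps, ix0 : ix0 + ps] = fg
    return img


# ---------------------------------------------------------------------------
# dataset construction


@dataclass
class DatasetManifest:
    root: Path
    splits: dict[str, list[str]]  # split -> image file names
    annotations: pd.DataFrame  # image, particle_id, class, x_px, y_px, z_um, split
    optical: OpticalConfig

    def split_frame(self, split: str) -> pd.DataFrame:
        return self.annotations[self.annotations["split"] == split]

    def validate(self) -> None:
        names = [n for files in self.splits.values() for n in files]
        if len(set(names)) != len(names):
            raise ValueError("manifest splits are not disjoint")
        for n in names:
            if not (self.root / "images" / n).exists():
                raise ValueError(f"missing image file {n}")


def split_counts(n_images: int, fractions: tuple[float, ...]) -> list[int]:
    """Floor-based split sizes; the remainder goes to the first (train) split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions sum to {sum(fractions):g}, expected 1")
    counts = [int(np.floor(n_images * f)) for f in fractions]
    counts[0] += n_images - sum(counts)
    return counts


def build_dataset(
    library: CalibrationLibrary,
    n_images: int,
    out_dir: str | Path,
    seed: int,
    compose_cfg: ComposeConfig | None = None,
    split_fractions: tuple[float, ...] = (0.7, 0.3),
) -> DatasetManifest:
    """Compose ``n_images`` scenes and write images + annotations + manifest."""
    cc = compose_cfg or ComposeConfig()
    if len(split_fractions) > len(SPLIT_NAMES):
        raise ValueError("at most three splits (train/eval/test) are supported")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    counts = split_counts(n_images, split_fractions)
    split_of = []
    for name, cnt in zip(SPLIT_NAMES, counts):
        split_of += [name] * cnt
    rows = []
    splits: dict[str, list[str]] = {name: [] for name, c in zip(SPLIT_NAMES, counts) if c >= 0}
    for i in range(n_images):
        rng = substream(seed, "scene", i)
        size = int(rng.integers(cc.image_size_min_px, cc.image_size_max_px + 1))
        n_p = int(rng.integers(cc.n_particles_min, cc.n_particles_max + 1))
        scene = compose_scene(
            library,
            n_p,
            size,
            rng,
            separation_factor=cc.min_separation_factor,
            background_level=cc.background_level,
            noise_sd=cc.noise_sd,
            max_attempts_per_particle=cc.max_place_attempts,
            seed=seed,
        )
        fname = f"scene_{i:05d}.tif"
        write_gray(out_dir / "images" / fname, scene.pixels, library.config.bit_depth)
        splits[split_of[i]].append(fname)
        for pid, ann in enumerate(scene.annotations):
            rows.append(
                {
                    "image": fname,
                    "particle_id": pid,
                    "class": ann.bead_class,
                    "x_px": round(ann.x_px, 4),
                    "y_px": round(ann.y_px, 4),
                    "z_um": ann.z_um,
                    "split": split_of[i],
                }
            )
    annotations = pd.DataFrame(
        rows, columns=["image", "particle_id", "class", "x_px", "y_px", "z_um", "split"]
    )
    for name, files in splits.items():
        sub = annotations[annotations["split"] == name].drop(columns=["split"])
        sub.to_csv(out_dir / f"annotations_{name}.csv", index=False)
    manifest_doc = {
        "seed": seed,
        "n_images": n_images,
        "split_fractions": list(split_fractions),
        "splits": {k: v for k, v in splits.items()},
        "optical": library.config.model_dump(mode="json"),
        "compose": cc.model_dump(mode="json"),
        "beads": [b.model_dump(mode="json") for b in library.classes],
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest_doc, sort_keys=True))
    manifest = DatasetManifest(root=out_dir, splits=splits, annotations=annotations, optical=library.config)
    manifest.validate()
    return manifest


def load_manifest(path: str | Path) -> DatasetManifest:
    root = Path(path)
    doc = yaml.safe_load((root / "manifest.yaml").read_text())
    optical = OpticalConfig(**doc["optical"])
    frames = []
    for split in doc["splits"]:
        csv = root / f"annotations_{split}.csv"
        df = pd.read_csv(csv)
        df["split"] = split
        frames.append(df)
    annotations = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["image", "particle_id", "class", "x_px", "y_px", "z_um", "split"])
    )
    manifest = DatasetManifest(root=root, splits=doc["splits"], annotations=annotations, optical=optical)
    manifest.validate()
    return manifest
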