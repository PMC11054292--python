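"""Shared helpers: named RNG substreams and grayscale image IO."""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["substream", "to_uint", "from_uint", "write_gray", "read_gray", "setup_run_logging"]


def setup_run_logging(out_dir: str | Path, seed: int) -> "logging.Logger":
    """Per-run logger: console plus ``<out_dir>/run.log``.

    The seed and the versions of the numerical libraries are always
    recorded, so a run directory documents its own provenance.
    """
    import logging

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("widefield_track3d")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    import scipy

    import widefield_track3d

    logger.info(
        "run seed=%d | widefield_track3d %s | numpy %s | scipy %s",
        seed, widefield_track3d.__version__, np.__version__, scipy.__version__,
    )
    return logger


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named RNG substream.

    All stochastic operations in the package draw from substreams of one
    root seed, keyed by purpose (and indices), so any single artifact is
    regenerable in isolation.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def to_uint(img: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Quantize a float image in [0, 1] to 8- or 16-bit integers."""
    vmax = (1 << bit_depth) - 1
    q = np.clip(np.round(img * vmax), 0, vmax)
    return q.astype(np.uint8 if bit_depth == 8 else np.uint16)


def from_uint(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_uint`: integer image to float32 in [0, 1]."""
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    return img.astype(np.float32)


def write_gray(path: str | Path, img: np.ndarray, bit_depth: int = 16) -> None:
    tifffile.imwrite(str(path), to_uint(img, bit_depth))


def read_gray(path: str | Path) -> np.ndarray:
    """Read a single-channel image (TIFF, or PNG via imageio) as float32 [0,1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        raw = iio.imread(str(path))
    raw = np.asarray(raw)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return from_uint(raw)
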