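"""Validated run configuration.

A single YAML document drives every stage (calibration synthesis, scene
composition, network, training, evaluation, tracking). Unknown keys are
rejected and every constraint violation is reported with its dotted path,
so a typo in a config never silently changes an experiment.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "OpticalConfig",
    "PatternParams",
    "BeadClass",
    "ComposeConfig",
    "NetConfig",
    "TrainConfig",
    "EvalConfig",
    "TrackConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "default_bead_classes",
]


class ConfigError(ValueError):
    """Raised when a configuration document fails validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticalConfig(_Strict):
    """Imaging geometry and the axial calibration grid."""

    pixel_scale_um: float = Field(0.0233, gt=0, description="object-space size of one pixel, μm")
    z_min_um: float = -10.0
    z_max_um: float = 10.0
    z_step_um: float = Field(0.05, gt=0)
    noise_sd: float = Field(0.02, ge=0, description="additive Gaussian noise SD, fraction of dynamic range")
    bit_depth: int = Field(16, description="bit depth used when patches/scenes are written to disk")
    seed: int = 0

    @model_validator(mode="after")
    def _check_grid(self):
        if self.z_min_um >= self.z_max_um:
            raise ValueError("optical.z_min_um must be < optical.z_max_um")
        span = self.z_max_um - self.z_min_um
        k = span / self.z_step_um
        if abs(k - round(k)) > 1e-9 * max(1.0, k):
            raise ValueError(
                f"optical.z_step_um does not divide the z range: remainder {span - round(k) * self.z_step_um:g} μm"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("optical.bit_depth must be 8 or 16")
        return self


class PatternParams(_Strict):
    """Coefficients of the parametric defocus-ring model.

    The noise-free single-bead intensity is
        I(r, z) = B + A * exp(-r^2 / (2 w(|z|)^2)) * (1 + m(z) cos(2π f(|z|) r))
    with envelope width w(|z|) = env_width0 + env_width_slope*|z| (px),
    ring frequency f(|z|) = ring_freq0 + ring_freq_slope*|z| (cycles/px),
    and modulation depth m(z) = asym * tanh(z / asym_scale), odd in z so
    that patterns above and below focus are distinguishable.
    """

    amplitude: float = Field(0.5, gt=0, le=1)
    background: float = Field(0.15, ge=0, lt=1)
    env_width0_px: float = Field(2.5, gt=0)
    env_width_slope_px_per_um: float = Field(1.5, ge=0)
    ring_freq0: float = Field(0.08, ge=0)
    ring_freq_slope: float = Field(0.012, ge=0)
    asym: float = Field(0.6, ge=0, lt=1)
    asym_scale_um: float = Field(2.0, gt=0)


class BeadClass(_Strict):
    label: Literal["small", "big"]
    radius_um: float = Field(gt=0)
    patch_size_px: int = Field(ge=9)
    pattern: PatternParams = PatternParams()


def default_bead_classes() -> list[BeadClass]:
    """The two polystyrene bead classes (1 μm and 2 μm radius).

    Patch sizes are chosen so the widest defocus halo at |z| = 10 μm still
    fits inside the crop.
    """
    small = BeadClass(label="small", radius_um=1.0, patch_size_px=64)
    big = BeadClass(
        label="big",
        radius_um=2.0,
        patch_size_px=96,
        pattern=PatternParams(
            env_width0_px=4.0,
            env_width_slope_px_per_um=2.2,
            ring_freq0=0.06,
            ring_freq_slope=0.010,
        ),
    )
    return [small, big]


class ComposeConfig(_Strict):
    image_size_min_px: int = Field(950, ge=32)
    image_size_max_px: int = 1050
    n_particles_min: int = Field(3, ge=0)
    n_particles_max: int = 8
    min_separation_factor: float = Field(
        0.6, ge=0, description="pairwise center separation as a fraction of the summed patch half-sizes; 0 allows collisions"
    )
    background_level: float = Field(0.15, ge=0, lt=1)
    noise_sd: float = Field(0.02, ge=0)
    max_place_attempts: int = Field(200, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.image_size_max_px < self.image_size_min_px:
            raise ValueError("compose.image_size_max_px must be >= compose.image_size_min_px")
        if self.n_particles_max < self.n_particles_min:
            raise ValueError("compose.n_particles_max must be >= compose.n_particles_min")
        return self


class NetConfig(_Strict):
    backbone: Literal["resnet50", "resnet18", "tiny"] = "resnet50"
    input_size_px: int = Field(1024, description="square network input; images are rescaled to this size")
    stride: int = 4
    score_threshold: float = Field(0.3, ge=0, le=1)
    top_k: int = Field(100, ge=1)
    # ablation hooks: swap either neck block family for a plain conv-BN-ReLU
    use_spp_csp: bool = True
    use_elan: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.input_size_px % 32 != 0:
            raise ValueError("net.input_size_px must be divisible by 32")
        if self.stride != 4:
            raise ValueError("net.stride must be 4 (the output stride of the neck)")
        return self


class TrainConfig(_Strict):
    epochs: int = Field(200, ge=1)
    batch_size: int = Field(2, ge=1)
    lr: float = Field(1.25e-4, gt=0)
    lr_decay_at: tuple[float, float] = (0.6, 0.85)
    lr_decay_factor: float = Field(0.1, gt=0, le=1)
    flip_augment: bool = True
    lambda_heat: float = Field(1.0, ge=0)
    lambda_offset: float = Field(1.0, ge=0)
    # the axial estimate is the system's point, so its loss term is emphasized
    lambda_depth: float = Field(5.0, ge=0)
    focal_alpha: float = 2.0
    focal_beta: float = 4.0
    eval_every: int = Field(5, ge=1)
    seed: int = 0


class EvalConfig(_Strict):
    match_gate_um: float = Field(2.0, gt=0, description="xy gate for detection-truth matching, μm")
    depth_bin_um: float = Field(1.0, gt=0)


class TrackConfig(_Strict):
    max_disp_px: float = Field(20.0, gt=0)
    max_misses: int = Field(3, ge=0)
    global_assignment: bool = False
    score_threshold: float = Field(0.3, ge=0, le=1)


class RunConfig(_Strict):
    seed: int = 0
    optical: OpticalConfig = OpticalConfig()
    beads: list[BeadClass] = Field(default_factory=default_bead_classes)
    compose: ComposeConfig = ComposeConfig()
    net: NetConfig = NetConfig()
    train: TrainConfig = TrainConfig()
    eval: EvalConfig = EvalConfig()
    track: TrackConfig = TrackConfig()

    @model_validator(mode="after")
    def _check_beads(self):
        labels = [b.label for b in self.beads]
        if len(set(labels)) != len(labels):
            raise ValueError("beads: duplicate class labels")
        if not labels:
            raise ValueError("beads: at least one class required")
        return self

    def bead(self, label: str) -> BeadClass:
        for b in self.beads:
            if b.label == label:
                return b
        raise KeyError(label)


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        path = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"{path}: {e['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Either ``path`` or an already-parsed ``data`` mapping may be given.
    Raises :class:`ConfigError` naming the offending dotted key path.
    """
    if data is None:
        if path is None:
            raise ValueError("load_config needs a path or a data mapping")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; round-trips through :func:`load_config`."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _isclose(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12)
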