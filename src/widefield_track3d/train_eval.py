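"""Training loop and the size-class-resolved localization error protocol.

Evaluation matches detections to ground truth one-to-one (Hungarian
assignment on xy distance, gated), then reports horizontal error as the
Euclidean xy distance converted to μm through the pixel scale and
vertical error as |Δz|, overall, per bead class, and per 1-μm depth bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as nd_zoom
from scipy.optimize import linear_sum_assignment

from .codec import Detection, decode_detections, encode_targets
from .compose import DatasetManifest
from .config import RunConfig
from .net import CenterXFNet, LossWeights, batch_targets, save_checkpoint, total_loss
from .nn import Adam
from .util import read_gray, substream

__all__ = [
    "SceneSample",
    "SceneDataset",
    "MatchResult",
    "EvalReport",
    "TrainResult",
    "train",
    "evaluate",
    "detect_image",
    "match_detections",
    "compute_errors",
]


@dataclass
class Truth:
    x_px: float
    y_px: float
    z_um: float
    bead_class: str


@dataclass
class SceneSample:
    image: np.ndarray  # (H, W) float32 in [0, 1], already resized to the net input
    truths: list[Truth]  # coordinates in resized-image px
    scale: float  # resized px per original px
    name: str


def _normalize(img: np.ndarray) -> np.ndarray:
    """Background-subtract (median) and scale by a fixed constant.

    The median tracks the background level regardless of how many
    particles are in view; the fixed scale keeps pattern contrast — which
    encodes the sign and magnitude of z — comparable across scenes.
    Per-image standardization by the sd would rescale contrast with
    particle count and measurably degrades depth estimates on sparse
    frames.
    """
    return ((img - np.median(img)) / 0.25).astype(np.float32)


class SceneDataset:
    """Scenes of one split, rescaled to the square network input size."""

    def __init__(self, manifest: DatasetManifest, split: str, input_size: int):
        self.manifest = manifest
        self.input_size = input_size
        self.names = list(manifest.splits.get(split, []))
        ann = manifest.split_frame(split)
        self._by_image = {name: df for name, df in ann.groupby("image")}

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, i: int) -> SceneSample:
        name = self.names[i]
        img = read_gray(self.manifest.root / "images" / name)
        h, w = img.shape
        if h != w:
            raise ValueError(f"{name}: expected square scene, got {h}x{w}")
        scale = self.input_size / h
        if scale != 1.0:
            img = nd_zoom(img, scale, order=1, grid_mode=True, mode="nearest")
            img = img[: self.input_size, : self.input_size]
        truths = []
        for _, row in self._by_image.get(name, pd.DataFrame()).iterrows():
            # pixel-center convention: position p maps to (p + 0.5)*s - 0.5
            truths.append(
                Truth(
                    x_px=(row["x_px"] + 0.5) * scale - 0.5,
                    y_px=(row["y_px"] + 0.5) * scale - 0.5,
                    z_um=float(row["z_um"]),
                    bead_class=row["class"],
                )
            )
        return SceneSample(image=img.astype(np.float32), truths=truths, scale=scale, name=name)


def _flip_sample(sample: SceneSample, flip_x: bool, flip_y: bool) -> SceneSample:
    img = sample.image
    size = img.shape[0]
    truths = sample.truths
    if flip_x:
        img = img[:, ::-1]
        truths = [Truth(size - 1 - t.x_px, t.y_px, t.z_um, t.bead_class) for t in truths]
    if flip_y:
        img = img[::-1]
        truths = [Truth(t.x_px, size - 1 - t.y_px, t.z_um, t.bead_class) for t in truths]
    return SceneSample(np.ascontiguousarray(img), truths, sample.scale, sample.name)


# ---------------------------------------------------------------------------
# matching and error computation


@dataclass
class MatchedPair:
    pred: Detection
    truth: Truth
    dist_px: float

    @property
    def class_mismatch(self) -> bool:
        return self.pred.bead_class != self.truth.bead_class


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    missed: list[Truth]
    spurious: list[Detection]


def match_detections(preds: list[Detection], truths: list[Truth], gate_px: float) -> MatchResult:
    """Optimal one-to-one xy assignment among pairs within ``gate_px``.

    Distance is class-agnostic; a class mismatch is recorded on the pair.
    Unmatched truths are missed, unmatched predictions spurious.
    """
    if gate_px <= 0:
        raise ValueError("gate must be positive")
    if not preds or not truths:
        return MatchResult(pairs=[], missed=list(truths), spurious=list(preds))
    cost = np.zeros((len(preds), len(truths)))
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            cost[i, j] = np.hypot(p.x_px - t.x_px, p.y_px - t.y_px)
    big = gate_px * 1e6
    rows, cols = linear_sum_assignment(np.where(cost <= gate_px, cost, big))
    pairs, used_p, used_t = [], set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] <= gate_px:
            pairs.append(MatchedPair(pred=preds[i], truth=truths[j], dist_px=float(cost[i, j])))
            used_p.add(i)
            used_t.add(j)
    missed = [t for j, t in enumerate(truths) if j not in used_t]
    spurious = [p for i, p in enumerate(preds) if i not in used_p]
    return MatchResult(pairs=pairs, missed=missed, spurious=spurious)


@dataclass
class EvalReport:
    horizontal_mae_um: float | None
    vertical_mae_um: float | None
    per_class: dict[str, dict]
    depth_bins: list[dict]
    n_matched: int
    n_missed: int
    n_spurious: int
    pixel_scale_um: float

    def to_dict(self) -> dict:
        return {
            "horizontal_mae_um": self.horizontal_mae_um,
            "vertical_mae_um": self.vertical_mae_um,
            "per_class": self.per_class,
            "depth_bins": self.depth_bins,
            "n_matched": self.n_matched,
            "n_missed": self.n_missed,
            "n_spurious": self.n_spurious,
            "pixel_scale_um": self.pixel_scale_um,
        }


def compute_errors(
    match: MatchResult,
    pixel_scale_um: float,
    z_bounds: tuple[float, float] = (-10.0, 10.0),
    depth_bin_um: float = 1.0,
) -> EvalReport:
    """Horizontal / vertical mean absolute error from matched pairs.

    Horizontal error per pair is the xy Euclidean distance in px times the
    pixel scale; vertical error is |z_pred - z_true|. Means are reported
    overall, per class (by truth class), and per depth bin. With no pairs
    the MAEs are None, never zero.
    """
    pairs = match.pairs
    if not pairs:
        return EvalReport(None, None, {}, [], 0, len(match.missed), len(match.spurious), pixel_scale_um)
    h_err = np.array([p.dist_px * pixel_scale_um for p in pairs])
    v_err = np.array([abs(p.pred.z_um - p.truth.z_um) for p in pairs])
    per_class: dict[str, dict] = {}
    for label in sorted({p.truth.bead_class for p in pairs}):
        idx = [i for i, p in enumerate(pairs) if p.truth.bead_class == label]
        per_class[label] = {
            "horizontal_mae_um": float(h_err[idx].mean()),
            "vertical_mae_um": float(v_err[idx].mean()),
            "n_matched": len(idx),
        }
    z0, z1 = z_bounds
    edges = np.arange(z0, z1 + depth_bin_um * 0.5, depth_bin_um)
    z_true = np.array([p.truth.z_um for p in pairs])
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (z_true >= lo) & (z_true < hi)
        if sel.any():
            bins.append(
                {
                    "z_lo_um": float(lo),
                    "z_hi_um": float(hi),
                    "horizontal_mae_um": float(h_err[sel].mean()),
                    "vertical_mae_um": float(v_err[sel].mean()),
                    "n": int(sel.sum()),
                }
            )
    return EvalReport(
        horizontal_mae_um=float(h_err.mean()),
        vertical_mae_um=float(v_err.mean()),
        per_class=per_class,
        depth_bins=bins,
        n_matched=len(pairs),
        n_missed=len(match.missed),
        n_spurious=len(match.spurious),
        pixel_scale_um=pixel_scale_um,
    )


# ---------------------------------------------------------------------------
# inference


def detect_image(model: CenterXFNet, image: np.ndarray, config: RunConfig,
                 score_threshold: float | None = None) -> list[Detection]:
    """Run the detector on one raw scene; detections in original-image px."""
    h, w = image.shape
    if h != w:
        raise ValueError("expected a square scene")
    scale = config.net.input_size_px / h
    img = image
    if scale != 1.0:
        img = nd_zoom(image, scale, order=1, grid_mode=True, mode="nearest")[
            : config.net.input_size_px, : config.net.input_size_px
        ]
    x = _normalize(img)[None, None]
    model.eval()
    out = model(x)
    dets = decode_detections(
        out["heatmap"].data[0],
        out["offset"].data[0],
        out["depth"].data[0],
        CenterXFNet.STRIDE,
        config.beads,
        config.optical,
        score_threshold=config.net.score_threshold if score_threshold is None else score_threshold,
        top_k=config.net.top_k,
    )
    if scale != 1.0:
        for d in dets:
            d.x_px = (d.x_px + 0.5) / scale - 0.5
            d.y_px = (d.y_px + 0.5) / scale - 0.5
    return dets


def evaluate(model: CenterXFNet, manifest: DatasetManifest, config: RunConfig, split: str = "eval") -> EvalReport:
    """Detect on every scene of a split and score against the annotations.

    Matching and errors are computed in original-image pixel coordinates,
    so the physical pixel scale applies directly.
    """
    gate_px = config.eval.match_gate_um / config.optical.pixel_scale_um
    ann = manifest.split_frame(split)
    all_pairs: list[MatchedPair] = []
    missed: list[Truth] = []
    spurious: list[Detection] = []
    for name in manifest.splits.get(split, []):
        image = read_gray(manifest.root / "images" / name)
        dets = detect_image(model, image, config)
        rows = ann[ann["image"] == name]
        truths = [
            Truth(float(r["x_px"]), float(r["y_px"]), float(r["z_um"]), r["class"]) for _, r in rows.iterrows()
        ]
        m = match_detections(dets, truths, gate_px)
        all_pairs += m.pairs
        missed += m.missed
        spurious += m.spurious
    return compute_errors(
        MatchResult(all_pairs, missed, spurious),
        config.optical.pixel_scale_um,
        z_bounds=(config.optical.z_min_um, config.optical.z_max_um),
        depth_bin_um=config.eval.depth_bin_um,
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    model: CenterXFNet
    history: pd.DataFrame
    best_checkpoint: Path | None
    best_report: EvalReport | None


def _eval_score(report: EvalReport) -> float:
    if report.horizontal_mae_um is None:
        return np.inf
    n_truth = report.n_matched + report.n_missed
    penalty = 10.0 * (report.n_missed + report.n_spurious) / max(n_truth, 1)
    return report.horizontal_mae_um + report.vertical_mae_um + penalty


def train(manifest: DatasetManifest, config: RunConfig, out_dir: str | Path | None = None) -> TrainResult:
    """Train on the manifest's train split; keep the best-on-eval model.

    Fully seeded: the same seed reproduces the same loss history on one
    device. Aborts (keeping the last finite state) if the loss goes
    non-finite.
    """
    tc = config.train
    train_ds = SceneDataset(manifest, "train", config.net.input_size_px)
    has_eval = len(manifest.splits.get("eval", [])) > 0
    if len(train_ds) == 0:
        raise ValueError("empty training split")
    rng = substream(tc.seed, "train-loop")
    model = CenterXFNet(
        len(config.beads),
        config.net.backbone,
        rng=substream(tc.seed, "init"),
        use_spp_csp=config.net.use_spp_csp,
        use_elan=config.net.use_elan,
    )
    opt = Adam(model.parameters(), lr=tc.lr)
    weights = LossWeights(tc.lambda_heat, tc.lambda_offset, tc.lambda_depth, tc.focal_alpha, tc.focal_beta)
    milestones = {max(1, int(f * tc.epochs)) for f in tc.lr_decay_at}
    size = config.net.input_size_px
    history_rows = []
    best_score = np.inf
    best_state = None
    best_report = None
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    aborted = False
    for epoch in range(1, tc.epochs + 1):
        if epoch in milestones:
            opt.lr *= tc.lr_decay_factor
        model.train()
        order = rng.permutation(len(train_ds))
        ep_losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            images, maps = [], []
            for i in idx:
                sample = train_ds[int(i)]
                if tc.flip_augment:
                    sample = _flip_sample(sample, bool(rng.integers(2)), bool(rng.integers(2)))
                images.append(_normalize(sample.image))
                maps.append(encode_targets(sample.truths, size, CenterXFNet.STRIDE, config.beads, config.optical))
            x = np.stack(images)[:, None]
            heat, offs, depth, mask, depth_mask = batch_targets(maps)
            opt.zero_grad()
            out = model(x)
            loss, parts = total_loss(out, heat, offs, depth, mask, weights, depth_mask)
            if not np.isfinite(parts["total"]):
                aborted = True
                break
            loss.backward()
            opt.step()
            ep_losses.append(parts)
        if aborted:
            break
        mean_losses = {k: float(np.mean([p[k] for p in ep_losses])) for k in ep_losses[0]}
        row = {"epoch": epoch, "lr": opt.lr, **{f"loss_{k}": v for k, v in mean_losses.items()}}
        if epoch % tc.eval_every == 0 or epoch == tc.epochs:
            report = evaluate(model, manifest, config, "eval") if has_eval else None
            if report is not None:
                row.update(
                    {
                        "eval_horizontal_mae_um": report.horizontal_mae_um,
                        "eval_vertical_mae_um": report.vertical_mae_um,
                        "eval_matched": report.n_matched,
                        "eval_missed": report.n_missed,
                        "eval_spurious": report.n_spurious,
                    }
                )
                score = _eval_score(report)
                if score < best_score:
                    best_score = score
                    best_state = model.state_dict()
                    best_report = report
        history_rows.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    history = pd.DataFrame(history_rows)
    best_path = None
    if out_dir is not None:
        history.to_csv(out_dir / "history.csv", index=False)
        meta = {
            "input_size": size,
            "classes": [b.label for b in config.beads],
            "z_min_um": config.optical.z_min_um,
            "z_max_um": config.optical.z_max_um,
            "seed": tc.seed,
        }
        best_path = save_checkpoint(model, out_dir / "model_best.npz", meta)
    return TrainResult(model=model, history=history, best_checkpoint=best_path, best_report=best_report)
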